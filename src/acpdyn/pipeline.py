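"""End-to-end orchestration and the local-vs-global stability comparison.

The central report compares per-residue local-unfolding free energies from
H/D exchange with the global unfolding free energy from chemical
denaturation.  Residues with dG_local above dG_global exchange only through
global unfolding-scale openings; those above 1.5 x dG_global anchor the
fold.  Both thresholds are also expressed on the logP axis as
dG / (ln10 * R * T) so they can be drawn on protection-factor plots.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import csp_titration as _csp
from . import hdx as _hdx
from . import relaxation as _relax
from . import synthdata as _synth
from . import thermostab as _thermo
from .chemdenat import LEMFit, fit_lem
from .hdx import ProtectionResult, dg_to_logp
from .io_tables import (PerResidueScore, SeriesTable, read_series, write_manifest,
                        write_scores)

logger = logging.getLogger("acpdyn")


@dataclass
class StabilityReport:
    dG_global: float
    m_value: float
    Cm: float
    T: float
    logp_threshold: float  # dG_global on the logP axis
    logp_threshold_1p5: float  # 1.5 x dG_global on the logP axis
    above_global: list[str] = field(default_factory=list)
    above_1p5_global: list[str] = field(default_factory=list)
    per_residue: dict[str, dict] = field(default_factory=dict)


def compare_stability(
    local: list[ProtectionResult], global_fit: LEMFit
) -> StabilityReport:
    """Build the stability comparison report (strict inequalities, ties excluded)."""
    if not local:
        raise ValueError("no per-residue protection results")
    temps = {round(r.T, 6) for r in local}
    if len(temps) > 1 or abs(next(iter(temps)) - global_fit.T) > 1.0:
        raise ValueError("temperature mismatch between local and global analyses")
    T = global_fit.T
    dG = global_fit.dG_H2O

    report = StabilityReport(
        dG_global=dG, m_value=global_fit.m_value, Cm=global_fit.Cm, T=T,
        logp_threshold=dg_to_logp(dG, T),
        logp_threshold_1p5=dg_to_logp(1.5 * dG, T),
    )
    for r in sorted(local, key=lambda r: r.rid.index):
        report.per_residue[r.rid.label] = {
            "logP": r.logP, "dG_local": r.dG_local, "lower_bound": r.lower_bound,
        }
        if r.dG_local > dG:
            report.above_global.append(r.rid.label)
        if r.dG_local > 1.5 * dG:
            report.above_1p5_global.append(r.rid.label)
    return report


# ---------------------------------------------------------------------------
# Stage runners (library surface used by both run() and the CLI)
# ---------------------------------------------------------------------------

def run_hdx_stage(table: pd.DataFrame, pD: float, T: float = _hdx.T_DEFAULT
                  ) -> list[ProtectionResult]:
    """Fit every residue's decay and convert to protection factors."""
    results = []
    seq = _synth.ECACP_SEQUENCE
    for (idx, aa), grp in table.groupby(["residue", "aa"], sort=True):
        idx = int(idx)
        series = SeriesTable(_synth.residue_id(idx),
                             grp["t_min"].to_numpy() * 60.0,
                             grp["intensity"].to_numpy(), x_unit="s")
        fit = _hdx.fit_exchange_decay(series)
        left = seq[idx - 2] if idx > 1 else "A"
        right = seq[idx] if idx < len(seq) else "A"
        position = "nterm" if idx == 2 else ("cterm" if idx == len(seq) else "internal")
        k_rc = _hdx.intrinsic_rate(str(aa), left, right, pD=pD, T=T, position=position)
        results.append(_hdx.protection(fit, k_rc, T))
    return results


def run_relaxation_stage(table: pd.DataFrame, kind: str) -> list[_relax.RelaxationFit]:
    fits = []
    for (idx, aa), grp in table.groupby(["residue", "aa"], sort=True):
        # acquisition order of the delay schedule is non-monotone; sort here
        # rather than tripping the SeriesTable warning for every residue
        order = np.argsort(grp["delay_s"].to_numpy(), kind="stable")
        series = SeriesTable(_synth.residue_id(int(idx)),
                             grp["delay_s"].to_numpy()[order],
                             grp["intensity"].to_numpy()[order], x_unit="s")
        fits.append(_relax.fit_relaxation(series, kind))
    return fits


def run(config_path: str | Path) -> dict:
    """Run the stages named in a YAML config; absent stages are skipped.

    Paths inside the config are resolved relative to the config file.  The
    hdx -> denaturation -> comparison chain runs when both inputs are
    present; csp, relaxation, melt, and dsc stages run independently.
    Outputs (CSVs plus a JSON manifest) land in the config's ``out`` dir.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text()) or {}
    base = config_path.parent
    out = base / cfg.get("out", "results")
    out.mkdir(parents=True, exist_ok=True)
    produced: dict = {}

    def _path(key_cfg):
        return base / key_cfg

    local_results = None
    if "hdx" in cfg:
        stage = cfg["hdx"]
        table = pd.read_csv(_path(stage["table"]))
        pD = float(stage.get("pD", 6.1 + _hdx.PD_METER_CORRECTION))
        try:
            local_results = run_hdx_stage(table, pD=pD)
        except Exception as exc:
            raise RuntimeError(f"hdx stage failed: {exc}") from exc
        write_scores(
            [PerResidueScore(r.rid, r.logP, flag=r.lower_bound) for r in local_results],
            out / "hdx_logp.csv",
        )
        produced["hdx"] = str(out / "hdx_logp.csv")

    global_fit = None
    if "denaturation" in cfg:
        stage = cfg["denaturation"]
        curves = read_series(_path(stage["table"]), x_unit=stage.get("x_unit", "M"))
        try:
            global_fit = fit_lem(curves[0])
        except Exception as exc:
            raise RuntimeError(f"denaturation stage failed: {exc}") from exc
        (out / "lem_fit.json").write_text(json.dumps(
            {k: v for k, v in dataclasses.asdict(global_fit).items() if k != "covariance"},
            indent=2) + "\n")
        produced["denaturation"] = str(out / "lem_fit.json")

    if cfg.get("comparison", "hdx" in cfg and "denaturation" in cfg):
        if local_results is None or global_fit is None:
            raise RuntimeError(
                "comparison requested but hdx and denaturation stages are not both configured")
        report = compare_stability(local_results, global_fit)
        (out / "stability_report.json").write_text(
            json.dumps(dataclasses.asdict(report), indent=2) + "\n")
        produced["comparison"] = str(out / "stability_report.json")

    if "melt" in cfg:
        curves = read_series(_path(cfg["melt"]["table"]), x_unit=cfg["melt"].get("x_unit", "K"))
        fit = _thermo.fit_melt(curves[0])
        (out / "melt_fit.json").write_text(json.dumps(dataclasses.asdict(fit), indent=2) + "\n")
        produced["melt"] = str(out / "melt_fit.json")

    if "dsc" in cfg:
        curves = read_series(_path(cfg["dsc"]["table"]), x_unit=cfg["dsc"].get("x_unit", "K"))
        res = _thermo.dsc_analyze(curves[0], baseline=cfg["dsc"].get("baseline", "linear"))
        (out / "dsc_result.json").write_text(json.dumps(dataclasses.asdict(res), indent=2) + "\n")
        produced["dsc"] = str(out / "dsc_result.json")

    write_manifest(out / "manifest.json", config=str(config_path), produced=produced,
                   seed=cfg.get("seed"))
    produced["manifest"] = str(out / "manifest.json")
    return produced


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.option("-v", "--verbose", is_flag=True)
def cli(verbose: bool) -> None:
    """Per-residue stability and dynamics analysis for acyl carrier protein."""
    logging.basicConfig(stream=sys.stderr,
                        level=logging.DEBUG if verbose else logging.INFO)


@cli.command()
@click.argument("stage", type=click.Choice(
    ["hdx", "denaturation", "melt", "dsc", "shifts", "relaxation", "trajectory"]))
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(file_okay=False), default="simulated")
def simulate(stage: str, seed: int, out: str) -> None:
    """Generate one stage's synthetic input files plus truth.json."""
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    if stage == "hdx":
        df, manifest = _synth.gen_hdx(seed)
        df.to_csv(out_dir / "hdx.csv", index=False)
    elif stage == "denaturation":
        table, manifest = _synth.gen_denaturation(seed)
        pd.DataFrame({"residue": 1, "aa": "S", "gdnhcl_M": table.x,
                      "signal": table.y}).to_csv(out_dir / "denaturation.csv", index=False)
    elif stage == "melt":
        table, manifest = _synth.gen_melt(seed)
        pd.DataFrame({"residue": 1, "aa": "S", "T_K": table.x,
                      "theta222": table.y}).to_csv(out_dir / "melt.csv", index=False)
    elif stage == "dsc":
        table, manifest = _synth.gen_dsc(seed)
        pd.DataFrame({"residue": 1, "aa": "S", "T_K": table.x,
                      "Cp": table.y}).to_csv(out_dir / "dsc.csv", index=False)
    elif stage == "shifts":
        ref, state, manifest = _synth.gen_shift_tables(seed)
        for name, recs in (("reference", ref), ("perturbed", state)):
            pd.DataFrame(
                [(r.rid.index, r.rid.aa, r.dH, r.dN, r.intensity) for r in recs],
                columns=["residue", "aa", "dH", "dN", "intensity"],
            ).to_csv(out_dir / f"shifts_{name}.csv", index=False)
    elif stage == "relaxation":
        df, manifest = _synth.gen_relaxation(seed)
        df.to_csv(out_dir / "relaxation_R2.csv", index=False)
    else:
        series, manifest = _synth.gen_trajectory(seed)
        rows = []
        for f in range(series.coords.shape[0]):
            for (res, name), xyz in zip(series.atoms, series.coords[f]):
                rows.append((f, res, name, *xyz))
        pd.DataFrame(rows, columns=["frame", "residue", "atom", "x", "y", "z"]).to_csv(
            out_dir / "trajectory.tsv", sep="\t", index=False)
    manifest.to_json(out_dir / "truth.json")
    click.echo(f"wrote {stage} inputs to {out_dir}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
def report(config_path: str) -> None:
    """Run all configured stages and write the reports."""
    produced = run(config_path)
    for stage, path in produced.items():
        click.echo(f"{stage}: {path}")


@cli.command("hdx")
@click.option("--table", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), default="hdx_logp.csv")
@click.option("--pd-value", "pd_value", type=float, default=6.5, show_default=True)
def hdx_cmd(table: str, out: str, pd_value: float) -> None:
    """Fit H/D-exchange decays and write per-residue logP."""
    results = run_hdx_stage(pd.read_csv(table), pD=pd_value)
    write_scores([PerResidueScore(r.rid, r.logP, flag=r.lower_bound) for r in results], out)
    click.echo(f"wrote {out}")


@cli.command("denat")
@click.option("--table", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), default="lem_fit.json")
def denat_cmd(table: str, out: str) -> None:
    """Fit a Gdn-HCl denaturation curve with the linear extrapolation model."""
    fit = fit_lem(read_series(table, x_unit="M")[0])
    payload = {k: v for k, v in dataclasses.asdict(fit).items() if k != "covariance"}
    Path(out).write_text(json.dumps(payload, indent=2) + "\n")
    click.echo(f"dG_H2O = {fit.dG_H2O:.2f} kcal/mol, m = {fit.m_value:.3f}, "
               f"Cm = {fit.Cm:.2f} M -> {out}")


@cli.command("relax")
@click.option("--table", type=click.Path(exists=True), required=True)
@click.option("--kind", type=click.Choice(["R1", "R2"]), default="R2")
@click.option("--out", type=click.Path(), default="relaxation.csv")
def relax_cmd(table: str, kind: str, out: str) -> None:
    """Fit relaxation decays and write per-residue rates."""
    fits = run_relaxation_stage(pd.read_csv(table), kind)
    write_scores([PerResidueScore(f.rid, f.rate, f.rate_err) for f in fits], out)
    click.echo(f"wrote {out}")


if __name__ == "__main__":  # pragma: no cover
    cli()
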