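# acpdyn

Per-residue stability and dynamics analysis for *Escherichia coli* acyl
carrier protein (ACP) — and for any small single-domain protein studied with
the same toolbox. The package turns the raw tabular observables of a
solution-NMR/biophysics study (HSQC peak lists, intensity decays,
denaturation and melt curves, DSC thermograms, coordinate series) into
per-residue stability and dynamics measures, and ships synthetic-data
generators with known ground truth so every stage is testable end to end.

## What it computes

**H/D exchange.** Peak-intensity decays are fitted to
`I(t) = I0·exp(−k_prot·t) + C`; the intrinsic random-coil rate `k_rc` is
predicted from sequence context (Bai et al., Proteins 17:75, 1993); the
protection factor and local-unfolding free energy follow as

    P = k_rc / k_prot,   logP = log10 P,   ΔG_local = ln(10)·R·T·logP

**Chemical denaturation.** Two-state linear extrapolation model (LEM):
`ΔG(D) = ΔG_H2O − m·D`, with linear native/unfolded baselines; reports
ΔG_H2O (= ΔG_global), the m-value and the midpoint Cm = ΔG_H2O/m.

**Thermal stability.** Two-state CD-melt fits (`ΔG(T) = ΔH_vH(1 − T/Tm)`)
and DSC analysis: calorimetric enthalpy ΔH_cal as the area under the excess
heat capacity, Tm as the peak position, plus the closed-form two-state
excess-Cp fit.

**CSP and metal titrations.** Weighted amide chemical-shift perturbations
`Δδ = sqrt(½[(ΔδH)² + (α·ΔδN)²])` (α = 0.2, glycine 0.14) with the
mean + SD significance rule; Ca²⁺ titration trajectories in fast exchange;
Mn²⁺ paramagnetic intensity ratios with vanished peaks scored 0.

**Backbone relaxation.** R₁/R₂ mono-exponential fits with duplicate-delay
noise estimation, hNOE ratios, and mean ± SD outlier classification
(exchange-broadened / flexible residues).

**Trajectory geometry.** χ1 torsions and rotamer-state switching, radius of
gyration, COM–atom distances (acyl-chain sequestration depth), and
hydrogen-bond occupancy at a 3.5 Å distance cutoff.

The pipeline's summary report compares ΔG_local against ΔG_global and
1.5×ΔG_global and expresses both thresholds on the logP axis
(ΔG / (ln10·R·T)), identifying the residues that anchor the global fold.

## Worked example

Simulate a Gdn-HCl denaturation experiment and refit it:

```sh
$ acpdyn simulate denaturation --seed 3 --out sim
wrote denaturation inputs to sim
$ acpdyn denat --table sim/denaturation.csv --out sim/fit.json
dG_H2O = 3.78 kcal/mol, m = 1.025, Cm = 3.69 M -> sim/fit.json
```

The generator's truth (recorded in `sim/truth.json`) is ΔG_H2O = 3.83
kcal/mol with midpoint 3.7 M; the refit recovers it within the 1% noise of
the simulated curve. The same pattern works for every stage (`simulate
hdx`, `melt`, `dsc`, `shifts`, `relaxation`, `trajectory`), and
`acpdyn report --config config.yaml` chains H/D exchange, denaturation and
the stability comparison in one run.

From Python:

```python
from acpdyn import synthdata, fit_lem
from acpdyn.pipeline import run_hdx_stage, compare_stability

hdx_df, truth = synthdata.gen_hdx(seed=1)
local = run_hdx_stage(hdx_df, pD=6.5)
curve, _ = synthdata.gen_denaturation(seed=1)
report = compare_stability(local, fit_lem(curve))
print(report.above_1p5_global)   # residues anchoring the fold, e.g. ['I11', 'I72']
```

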