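# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter.

## Units and conventions

Internal units are seconds, Kelvin, molar and kcal·mol⁻¹, with
R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹; conversions (minutes, °C, mM/µM) happen
only at I/O boundaries and are refused when the axis already carries the
canonical tag, so a min→s conversion can never be applied twice. Residues
use 1-based mature-protein numbering on the 77-residue *E. coli* ACP
sequence packaged in `synthdata` (Ser36 carries the 4′-phosphopantetheine).
A missing HSQC peak is encoded as absent intensity, never zero, so that
disappearance under paramagnetic broadening stays distinguishable.

## H/D exchange

The observed decay is `I(t) = I0·exp(−k_prot t) + C`, fitted by bounded
least squares with multi-start on k (10⁻⁶–10⁻³ s⁻¹ grid, lowest SSE wins).
The plateau C is bounded at zero: it represents residual protonation, and
an unbounded plateau admits a degenerate near-linear solution for decays at
the slow edge of the window. If the fitted decay over the observation
window is below 5%, the rate is censored and replaced by the 5%-decay upper
bound; the 1000-min default schedule makes that bound ≈ 8.5×10⁻⁷ s⁻¹.

Intrinsic random-coil rates follow the standard reference parameter set
(poly-DL-alanine reference rates with log-additive side-chain corrections
from the residue itself and its N-side neighbour, N/C-terminal corrections,
acid/base/water catalysis, Arrhenius scaling with Ea = 14/17/19 kcal·mol⁻¹;
Bai, Milne, Mayne & Englander, Proteins 17:75–86, 1993). The i+1 side chain
carries no correction in this set; the interface still accepts it for
symmetry. Defaults: pD = meter reading + 0.4 (glass-electrode correction;
the experiments read pH 6.1, so pD 6.5) and T = 298.15 K, both overridable —
the choice between nominal pH and corrected pD is exposed because the
convention is often unstated in primary reports.

Protection and local stability follow the EX2 identities
`P = k_rc/k_prot`, `ΔG_local = ln(10)·R·T·logP`, asserted in tests to
machine precision. No EX1/EX2 discrimination, proline/side-chain exchange
or back-exchange correction is attempted.

## Chemical denaturation (LEM)

`ΔG(D) = ΔG_H2O − m·D`; the observable mixes linear native/unfolded
baselines by the unfolded fraction. The fit is parameterised in
(Cm, m, baselines) for conditioning — so `Cm·m = ΔG_H2O` holds exactly by
construction — with a multi-start grid on Cm at 0.25 M spacing across the
data range. The fit refuses curves whose fitted unfolded fraction does not
pass from below 0.2 to above 0.8 within the data ("transition not
bracketed"), and cross-checks the fitted Cm against the baseline-normalised
signal's 0.5-crossing (monotonised against point noise); disagreement
beyond 2% is an error. ΔG_global is reported as the zero-denaturant
extrapolation m·Cm. With ΔG = 3.83 kcal·mol⁻¹ and Cm = 3.7 M the implied
m ≈ 1.035 kcal·mol⁻¹·M⁻¹, physically plausible for a ~9 kDa protein.

## Thermal stability

CD melts: `ΔG(T) = ΔH_vH(1 − T/Tm)` with linear baselines; ΔCp of
unfolding is neglected (no ΔCp is resolvable from a single melt channel) —
a documented limitation, adequate for Tm and useful ΔH_vH.

DSC: the model-free route subtracts a baseline and reports ΔH_cal as the
trapezoidal integral of the excess Cp, Tm as the (parabolically refined)
peak position, and the peak height. Baseline options: `none` (input already
excess Cp, as exported by vendor software), `linear` and `progress`
(pre/post lines fitted outside an iteratively detected transition window,
mixed linearly in T or by the unfolding progress). Finite-window baselines
absorb part of the broad two-state tails (ΔH_vH ≈ 57 kcal·mol⁻¹ gives a
~25 K-wide peak), biasing ΔH_cal low by 5–10% on a 20–100 °C scan; this is
inherent to the construction and is why the quantitative comparisons use
already-subtracted thermograms. The two-state route fits
`Cp_exc = ΔH_cal·ΔH_vH·K / (R T² (1+K)²)`, `K = exp(−(ΔH_vH/R)(1/T−1/Tm))`,
whose peak height is `ΔH_cal·ΔH_vH/(4 R Tm²)`. Tm from the model-free route
is the argmax of the excess Cp, which sits ~0.2 K below the thermodynamic
Tm of the two-state model — the presentation convention for thermograms.

## CSP and titrations

`Δδ = sqrt(½[(ΔδH)² + (α ΔδN)²])`, α = 0.2 (0.14 for glycine). The ½
factor sits inside the root by default; a switch provides the
outside-the-root variant since published formulas vary. Significance:
strictly above mean + one sample SD (n−1) of the compared cohort, so a flat
cohort flags nothing and the flag set is scale-invariant. Mn²⁺ ratios are
`I(c)/I(0)` with vanished peaks scored 0; no conversion to distances and no
Kd fitting anywhere — the two-site fast-exchange generator exists to test
monotonicity and endpoint behaviour, not to be inverted.

## Relaxation

`I(τ) = I0·exp(−rate·τ)` without a plateau (standard for peak-height R₁/R₂
decays). Per-point noise comes from duplicated delays (rms of paired
differences / √2) and rescales the covariance-based rate error. The
packaged delay schedules are the experiment's printed lists kept verbatim;
the R₂ list is non-monotone in its 8th/9th entries (an apparent
transcription anomaly in the source protocol) — analysis sorts delays, so
only the sampling design, not the fit, is affected. Classification uses
trimmed cohort statistics (5% per tail): R₂ > mean+SD marks exchange
broadening, hNOE < mean−SD marks fast flexibility. No model-free analysis,
spectral-density mapping or CPMG dispersion.

## Trajectory geometry

Dihedrals use the projection/atan2 formulation (IUPAC sign, anti = 180°),
validated against an independent normal-vector oracle and MDAnalysis. χ1
atom names for the 18 χ1-bearing residues are packaged; Ala/Gly are
rejected. The H-bond criterion is distance-only at 3.5 Å between the two
atoms the user names (no angle term, since occupancy is defined on a
distance threshold here); occupancy is monotone in the cutoff by
construction. State switching assigns frames to the nearest rotamer centre
on the circle within a tolerance, refuses overlapping windows, and counts
transitions between consecutive assigned frames. Rg and COM distances are
mass-weighted and rigid-motion invariant to 10⁻¹⁰ Å.

## Synthetic data

One root seed is split into fixed per-stage child streams
(`SeedSequence([seed, stage_key])`), so adding a table never perturbs
another and the same seed is byte-identical. Defaults reproduce the study
design: HDX every 10 min for 1000 min at 2% intensity noise, with
per-residue ΔG_local truths for the protected helix cohort (anchors Ile11 =
5.82, Ile72 = 6.01 kcal·mol⁻¹) and rates clipped to the observable
10⁻⁷–10⁻² s⁻¹ window; denaturation at ΔG = 3.83 kcal·mol⁻¹, Cm = 3.7 M
over 0–7 M (20 points, 1% noise) — the range that actually brackets the
unfolded baseline given the ~1.3 M transition half-width; melts at
54.5/55.9/65.6/67.4 °C for none/K⁺/Mg²⁺/Ca²⁺; DSC truths (66.4 °C, 71.2
kcal·mol⁻¹, 4.47 kcal·mol⁻¹·K⁻¹) and (57.5, 54.5, 3.21) for Ca²⁺/K⁺, with
ΔH_vH derived from the requested peak height; the printed relaxation delay
ladders with R₂ outliers Phe28 = 9.86 and Ile54 = 8.72 s⁻¹; Ca²⁺ 0–30 mM
and Mn²⁺ 0–0.1 mM titration ladders; and coordinate series realising the
scheduled χ1 states exactly with a 40%-occupancy donor–acceptor contact.

The generators emulate observables, not spectra: no line shapes, no peak
overlap, no back-exchange, no assignment errors, homoscedastic Gaussian
noise only. Passing tests therefore demonstrate estimator correctness and
calibration under clean sampling, not robustness to the pathologies of real
spectra.

## Problem sizes and calibration conditions

Monte-Carlo calibrations use 500 seeded replicates (rate-estimator
coverage and bias, midpoint recovery); the acceptance script summarises
stochastic stages as medians over 9 replicate experiments (5 for the R₂
outliers) because single-fit m-values and slow-edge exchange rates scatter
by several percent at the study noise levels. Trajectory metrics use 2000
frames (10⁴ for occupancy-convergence tests).
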