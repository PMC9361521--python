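# Methods

This note records the models implemented in `camdyn`, the defaults chosen
where the design was genuinely open, and what the synthetic data do and do
not establish about real measurements.

## SAXS

**Guinier analysis.** Weighted linear fit of ln I vs q² starting at the
smallest usable q; the upper end of the window is shrunk iteratively until
q_max·Rg ≤ 1.3, the conventional bound for globular particles.  Errors come
from the weighted-least-squares covariance scaled by the fit's reduced χ²,
so they reflect the actual scatter.  A non-negative slope anywhere in the
search raises "no Guinier region" rather than returning a nonsense radius.

**Dimensionless Kratky.** (qRg)²·I/I(0) against qRg.  For a curve obeying
the Guinier law exactly, the maximum sits at x = √3, y = 3/e ≈ 1.1036; this
analytic point is the globular reference used throughout.  The peak locator
refines the grid maximum by parabolic interpolation of the three
surrounding samples.

**P(r) by indirect Fourier transform.** I(q) = 4π∫₀^Dmax p(r) sinc(qr) dr is
discretised on a 101-point r-grid and solved as a linear least-squares
problem with a second-difference smoothness penalty and hard endpoint
constraints p(0) = p(Dmax) = 0.  p(r) is not constrained to be
non-negative; negative excursions are instead used as a diagnostic.  When
no penalty weight α is supplied it is chosen by a discrepancy-style rule:
the largest (smoothest) α whose misfit stays within 5 % of the best
attainable χ².  χ² is normalised by N − 1: with the smoothness penalty
active the effective number of parameters is far below the grid size, so
the nominal parameter count would be meaningless.  Rg and I(0) in real
space come from the moments of p(r).

**Dmax selection.** `estimate_dmax` scans a Dmax grid and scores each
transform by χ²_red plus three penalties: the fraction of |p| mass that is
negative (oscillating solutions, Dmax too large), the endpoint slope
(truncated distributions, Dmax too small) and a mild linear parsimony term
selecting the smallest support that still fits — the programmatic analogue
of the usual manual criterion.  On an analytic sphere of diameter 40 Å the
argmin lands on the true diameter to within one grid step.  The score
profile is returned; a multimodal profile triggers a warning rather than a
failure.

**Debye scattering.** Exact double sum over identical unit form factors
(shape-only modelling, no hydration shell); I(0) = (Σf)².  Above 400
scatterers a pair-distance histogram (0.1 Å bins) accelerates the sum; the
kernel is evaluated at each bin's weight-averaged distance, which keeps the
result within 0.1 % of the exact sum over the q-ranges used here.  Because
beads are points, synthetic curves flatten at the self-term plateau
I → Σf² at high q, much like a residual flat background in experimental
data; IFT fits of bead-pool curves are therefore best restricted to the
structured low/mid-q region, and absolute χ² values against experimental
curves are indicative only.

**Reduced χ².** χ²_red = (1/(N−k))·Σ((I_d − c·I_m − b)/σ)² with the scale c
solved analytically (and the offset b only behind a flag); k counts the
nuisance parameters actually fitted.  The statistic is invariant under
rescaling of the model curve.

**CorMap.** Frame similarity from the longest run of same-sign point-wise
differences.  The null survival P(longest run ≥ C) for n fair signs is
computed exactly: the number of length-n sign sequences with all runs ≤ m
equals twice the number of compositions of n into parts ≤ m, evaluated by
recursion in exact integer arithmetic.  Zero differences are broken as
alternating signs, which caps any run they sit in (conservative).

**Ensemble selection.** Chromosomes are fixed-size multisets of pool
indices (repetition supplies implicit weighting); fitness is the reduced χ²
of the equal-weight average after analytic scaling.  Tournament selection
(size 2), uniform crossover, per-gene mutation (default 0.1), elitism 2,
population 100.  Independent restarts return the overall best and the
distribution of selected-member Rg values.  On every instance small enough
to enumerate (pool ≤ 20, ensemble size 2) the GA result equals exhaustive
search.

## NMR

**TRACT.** The difference of the fast (Rβ) and slow (Rα) ¹⁵N doublet
relaxation rates for a rigid isotropic tumbler is 2·η_xy with

    η_xy = 2 p δ_N P₂(cos θ) (4J(0) + 3J(ω_N)),
    p   = μ₀ γ_H γ_N ħ / (16π√2 r³_NH),
    δ_N = γ_N B₀ Δσ_N / (3√2),
    J(ω) = (2/5)·τc / (1 + (ωτc)²).

Defaults r_NH = 1.02 Å, Δσ_N = −160 ppm, θ = 17° (the standard values of
the TRACT literature; configurable since instruments and force fields
differ).  The magnitude of 2η_xy is used — the sign of the DD/CSA
interference only fixes which doublet component is the fast one.  τc is
recovered by bounded scalar minimisation of |theoretical − measured| on
[0.1, 100] ns; the contract is the returned τc, not the optimiser.
Rβ − Rα is strictly increasing in τc over the relevant range, so the
inversion is well posed; the round trip through the forward model is the
identity to better than 10⁻³ ns.  Confidence intervals come from
Monte-Carlo resampling of the rate errors (default 1000 draws).

**Rate fitting.** A·exp(−Rt) by nonlinear least squares seeded from the
log-linear fit; errors are the SD of rates refitted to noise-perturbed
synthetic replicas.

**SED prediction.** r_dry = (3Mv̄/4πN_A)^(1/3); τc = 4πη(r_dry + h)³/(3k_BT)
with a hydration shell h (default 2.8 Å).  For a calmodulin-sized sphere
(M = 16706 g/mol, v̄ = 0.73 cm³/g) in water at 37 °C this gives 5.2 ns,
stable within [4.9, 5.5] ns for h ∈ [2.8, 3.2] Å.

**Viscosity extrapolation.** τc scales with solvent viscosity, so measured
values are multiplied by η_H₂O/η_mix.  Pure-component viscosities for
H₂O, D₂O and DMSO are embedded as 0–60 °C tables with linear interpolation
in temperature; mixtures use volume-fraction-weighted linear mixing — a
first-order model adequate for the few-percent co-solvent range it is used
in, and an acknowledged simplification at high DMSO fractions.

**CSP.** √((0.159·ΔδN)² + ΔδHN²) on ppm values; classification very strong
at CSP ≥ 0.14 ppm, strong in [0.07, 0.14).  Residues present in only one
shift table are carried through as explicit missing records, mirroring
unassigned resonances.  The three-region partition used for regional
summaries is N-lobe ≤ 74, linker and immediate neighbours 75–81, C-lobe
≥ 82 (the linker definition is configurable; published descriptions vary
between 76–81 and 77–81, and this default reproduces the reported
regional split of unassigned residues).

**nOe.** I_sat/I_unsat with first-order error propagation (validated
against Monte Carlo to 10 % at SNR ≥ 10).  Differences bound − free are
banded very-high at ≥ 0.18 and high within [0.10, 0.16]; values in the open
gap (0.16, 0.18) are reported as unclassified rather than silently
assigned, because the published banding leaves that interval undefined.

## HDX-MS

**Bookkeeping.** The deuterium fraction after sequential mixing steps is
the volume-weighted average; the study's printed volumes give ≈ 0.80
during labelling and 0.27 after quench.  Maximum exchangeable amides per
peptide follow the common processing-software convention
N − 1 − (prolines at positions 2..N).  Relative fractional uptake is
100·uptake/(max_d·d_fraction) with the labelling-mix excess (0.80) as the
default denominator correction (configurable); no back-exchange adjustment
is applied anywhere.

**Statistics.** Per peptide, replicate uptake is modelled by a
fixed-effects linear model in state and categorical labelling time.  The
magnitude test is the Wald test of the state main effect in the additive
model; the kinetics test is the F-test of the full state × time
interaction block.  A mixed model is unnecessary at three technical
replicates per cell; the fixed-effects simplification is deliberate and
its type-I behaviour is verified by simulation (100 null datasets of 40
peptides × 7 times × 3 replicates keep false positives below the nominal
5 %).  Benjamini–Hochberg runs across peptides separately per test family;
a peptide is significant when either family rejects.  Exact-tie data (zero
residual variance, detected relative to the response scale) report NaN
p-values with the peptide flagged rather than spurious certainty.

**Residue painting.** Peptide-level time-averaged differences are mapped to
residues by assigning each residue its shortest covering peptide;
overlapping peptides are not consolidated into residue-level exchange.

## ITC

One-site Wiseman isotherm with perfusion-cell bookkeeping: cumulative
injected volume dilutes both species ([M] and [X] carry the standard
(1 ∓ ΔV/2V₀)/(1 + ΔV/2V₀) factors), the bound fraction Θ solves the
one-site quadratic, and the observed injection heat is the difference of
cumulative heats plus the displaced-volume correction and an optional
constant dilution offset.  Units are µcal and cal/mol internally.  The fit
runs in log K_D (positivity, better conditioning), errors come from the
Jacobian covariance scaled by the residual variance, and the Wiseman
c-value n[M]/K_D is reported with a warning outside [1, 1000].  The
stoichiometry n is free by default.  First-injection exclusion is available
behind a flag, default off.  Blank titrations are subtracted point-wise
when given, in which case the offset is held at zero.

## Structure mapping

PDB input/output through biotite's fixed-width parser; the first altloc of
each atom is kept (deterministic policy).  Superposition uses the
closed-form least-squares (Kabsch) solution with reflections excluded;
atoms are matched by (chain, residue, atom name) intersection.  Coordinates
are stored in single precision, so "zero" RMSD means ≲ 10⁻⁶ Å.  Ligand
contacts are heavy-atom minimum distances with a 3.9 Å default cutoff, the
conventional non-bonded contact limit.  Painting writes per-residue scalars
into the B-factor column, clamped to the PDB field range [−99.99, 999.99].

## Synthetic data

Every generator is a pure function of (parameters, seed); one global seed
fans out deterministically to per-generator child seeds, and the ground
truth is returned with each dataset.

**Conformers.** Lobes are ~60 beads on a jittered FCC packing filling a
12 Å sphere; the linker is a 6-bead, 3.8 Å-step (Cα-like) self-avoiding
walk with mild directional persistence (native-like linkers are not fully
random coils).  Extended mode attaches the lobes to the walk ends pointing
outward, giving a population mean Rg of ≈ 22 Å; compact mode docks swollen
(1.5×) interpenetrating lobes at 1.2 lobe-radii separation, which makes
the bound state scatter like a single globule — Kratky peak at essentially
(√3, 3/e) — at a mean Rg of ≈ 16.7 Å.  The two defaults bracket the
experimentally observed 22.4 → 16.8 Å collapse.  The swelling in compact
mode is a shape-modelling device: matching both the globular scattering
profile and the complex's Rg with two rigid 12 Å spheres in contact is
geometrically impossible, and the bead model's job is to reproduce the
scattering shape, not the residue inventory.

**Noise.** Gaussian throughout.  SAXS: σ(q) = noise_scale·√(I(q)·I(0)),
floor-clipped — small relative error at low q growing toward high q, the
familiar shape of column-mode data; the default noise_scale 10⁻³ yields
self-fit χ²_red ≈ 1.  HDX: Gaussian centroid noise per replicate (0.05 Da
default).  ITC: Gaussian heat noise per injection.  Relaxation: Gaussian
on the decay points.  Poisson counting statistics, spectrometer artifacts,
isotope envelopes and peptide misassignment are deliberately not emulated:
passing tests demonstrate the estimators' correctness and calibration
under their stated noise models, not robustness to instrument pathology.

**HDX kinetics.** Residue-level two-state exchange 1 − exp(−k_int·t/PF)
with a single configurable intrinsic rate (default 1 s⁻¹, a typical
mid-sequence amide scale near pD 7.4 at room temperature) rather than full
sequence-dependent intrinsic-rate tables — sufficient for testing the
statistics, which only see relative differences between states.  The
N-terminal residue of each peptide and prolines are exchange-incompetent,
matching the max-uptake convention.

## Problem sizes and determinism

Simulation-based tests use pools of 12–30 conformers, 100-replicate noise
calibrations, 100 null HDX datasets and 100 ITC titrations — sizes at
which the checked statistics (means, false-positive rates, recovery bands)
are stable to well within their asserted tolerances.  All stochastic tests
fix seeds; the pipeline writes byte-identical summaries on reruns with the
same config and seed.

## Known limitations

- Vacuum Debye scattering of identical point beads: no hydration shell, no
  atomic form factors; absolute χ² against experimental curves is
  indicative only (rankings are meaningful).
- The IFT's regularisation choice is a stated substitute for perceptual
  quality scores used interactively in this field; its Dmax choice is
  validated on analytic shapes, not calibrated against those programs.
- Linear volume-fraction viscosity mixing under-represents the known excess
  viscosity of DMSO–water at intermediate compositions.
- The HDX significance model is fixed-effects; with many replicates or
  strong replicate structure a mixed model would be preferable.
- Bead conformers carry no side chains or sequence; structure-level
  analyses (contacts, RMSD) apply to atomic PDB inputs, not to the bead
  models.
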