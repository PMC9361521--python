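# camdyn

Quantitative analysis of ligand-induced calmodulin compaction.

Calmodulin (CaM) is a 148-residue, two-lobed calcium sensor whose lobes are
joined by a flexible linker.  The calcium-loaded protein is a dumbbell in
solution; binding of a single molecule of the antagonist calmidazolium (CDZ)
collapses it into a compact globule.  `camdyn` implements, as one tested
pipeline, the quantitative analyses with which that collapse is established
across four biophysical techniques, together with a synthetic-data generator
so every stage can be exercised end to end with no external downloads:

- **SAXS shape analysis** (`camdyn.saxs`) — Guinier fitting
  (ln I = ln I(0) − q²Rg²/3 with a self-consistent qRg ≤ 1.3 window), the
  dimensionless Kratky transform ((qRg)² I/I(0) vs qRg; globular particles
  peak at (√3, 3/e ≈ 1.104)), pair-distance distribution P(r) by regularised
  indirect Fourier transform with automatic Dmax selection, exact Debye
  forward scattering I(q) = Σᵢⱼ fᵢfⱼ sin(qrᵢⱼ)/(qrᵢⱼ) from bead or atomic
  coordinates, reduced-χ² model comparison, the CorMap longest-run
  frame-similarity test (exact survival probabilities via the Schilling
  recursion), and genetic-algorithm ensemble selection of conformer subsets
  whose averaged curve fits the data.
- **NMR dynamics** (`camdyn.nmr`) — exponential relaxation-rate fits with
  Monte-Carlo errors; TRACT rotational correlation times from the
  ¹⁵N DD/CSA cross-correlated rate η_xy (Rβ − Rα = 2η_xy inverted by bounded
  scalar minimisation); the Stokes–Einstein–Debye prediction
  τc = 4πη(r_dry + h)³/(3k_BT); viscosity extrapolation to 100 % H₂O;
  chemical-shift perturbations CSP = √((0.159·ΔδN)² + ΔδHN²) with the
  strong/very-strong classification; and heteronuclear nOe differences.
- **Differential HDX-MS** (`camdyn.hdx`) — deuterium-fraction bookkeeping
  through sequential mixing, maximum exchangeable amides (N − 1 − Pro),
  relative fractional uptake, per-time and time-averaged state differences,
  and two Wald tests per peptide (magnitude and kinetics) under
  Benjamini–Hochberg FDR control at 5 %.
- **ITC one-site binding** (`camdyn.itc`) — the Wiseman single-site isotherm
  with perfusion-cell bookkeeping, fitted by nonlinear least squares
  (`OneSiteBinding(titration).fit()` returns estimates, covariance errors,
  the Wiseman c-value and a `summary()` table).
- **Structure mapping** (`camdyn.structmap`) — PDB parsing, Kabsch
  superposition/RMSD, distance-based ligand contacts, and painting
  per-residue analysis values into the B-factor column.
- **Synthetic data** (`camdyn.synth`) — two-lobe bead conformers (extended
  dumbbell vs compact globule), noisy Debye curves, TRACT decay pairs,
  two-state HDX kinetics with per-residue protection factors, and one-site
  titrations, all pure functions of (parameters, seed) with ground truth
  emitted alongside.

## Worked example

```python
import numpy as np
from camdyn import synth, saxs
from camdyn.itc import OneSiteBinding

pool_free  = synth.make_two_lobe_conformers(12, compact=False, seed=1)
pool_bound = synth.make_two_lobe_conformers(12, compact=True,  seed=1)
q = np.linspace(1e-3, 0.45, 120)
for name, pool in [("free", pool_free), ("bound", pool_bound)]:
    curve, _ = synth.simulate_saxs(pool, q, noise_scale=0.001, seed=2)
    g = saxs.guinier_fit(curve)
    dmax, _ = saxs.estimate_dmax(curve, np.arange(30, 90, 4.0))
    x, y = saxs.kratky_peak(saxs.dimensionless_kratky(curve, g))
    print(f"{name:5s}  Rg = {g.Rg:5.1f} +/- {g.Rg_err:.1f} A   "
          f"Dmax = {dmax:4.0f} A   Kratky peak = ({x:.2f}, {y:.2f})")

tit, _ = synth.simulate_itc(kd=3e-6, n=1.2, dh=-8000.0, noise_sd=0.15, seed=3)
print(OneSiteBinding(tit).fit().summary())
```

prints

```
free   Rg =  22.2 +/- 0.1 A   Dmax =   70 A   Kratky peak = (3.95, 3.06)
bound  Rg =  17.5 +/- 0.0 A   Dmax =   54 A   Kratky peak = (1.72, 1.10)

One-site binding fit
--------------------------------------------
K_D                2.79 +/- 0.305 uM
n                  1.23 +/- 0.0267 sites
dH               -7.772 +/- 0.328 kcal/mol
offset           0.0167 +/- 0.0901 ucal
Wiseman c          3.54
chi2_red         0.0324
converged    True
```

The extended pool shows the dumbbell signature — larger Rg and Dmax and a
Kratky maximum displaced to high (x, y) — while the compact pool shows the
globular one: a Kratky peak at essentially (√3, 1.104) and the smaller
Rg/Dmax of the collapsed state.  The ITC fit recovers the planted
dissociation constant (3 µM) and stoichiometry (1.2) from the noisy
synthetic titration at the study's 8 µM cell / 200 µM syringe design.

A command-line interface mirrors the library
(`camdyn simulate | saxs | nmr | hdx | itc | struct | run`); `camdyn run
--seed 1 -o out/` executes the all-synthetic demonstration end to end and
writes a machine-readable `summary.json` of every headline statistic.

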