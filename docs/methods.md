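# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind halokin, and what the shipped tests do and do not
establish about real data.

## Michaelis–Menten fitting (`kinetics`)

The saturation model v = V_max·s/(K_M+s) is fitted by unweighted nonlinear
least squares (Levenberg–Marquardt). The initialization is deterministic —
V_max⁰ = 1.2·max(v), K_M⁰ = the sampled s whose velocity lies closest to
V_max⁰/2 — so repeated fits of the same data are bit-identical; no random
restarts are used. Whether measured initial velocities should be weighted
is an open experimental question; constant-CV error would argue for
relative weighting, but unweighted least squares is the common instrument
default and is what we adopt.

Standard errors come from the linearized covariance at the optimum
(`sqrt(diag((JᵀJ)⁻¹·s²))` as returned by the fitter). When a dataset
carries ≥ 2 replicates that are independently fittable, the SD of the
per-replicate estimates is reported alongside, mirroring the
"± SD of three independent measurements" convention of kinetic tables.

Degenerate data never return a silent estimate: all-zero velocities, a fit
leaving the positive domain, a singular covariance, or a fitted K_M more
than 100× beyond the sampled concentration range (the signature of
curvature-free data where K_M is unbounded) raise a diagnostic error. The
100× factor is a package choice: any fit that far outside the design range
is extrapolation, not estimation.

Units: s in mM, v in mM·min⁻¹ (≡ U·ml⁻¹). k_cat = V_max/[E] after
converting V_max to M·s⁻¹. Catalytic efficiency k_cat/K_M converts K_M to
molar only at that point and is rounded to two significant figures only at
reporting; full precision is kept internally.

## Coupled-assay design (`assay_design`)

The target enzyme is treated as a constant source v₁ of the intermediate B
(its own substrate depletion is neglected over the lag window) and the
auxiliary enzyme as Michaelis–Menten in B with saturating co-substrate:

    d[B]/dt = v₁ − V₂·[B]/(K_M2 + [B]),  [B](0) = 0.

The full ODE is integrated with fixed-step classical RK4, halving the step
until two refinements agree to 10⁻⁹ mM on the shared grid. The first-order
closed form v₂/v₁ = 1 − exp(−V₂t/K_M2) — exact in the regime
[B]ss ≪ K_M2 — is used only as an independent test oracle, never as the
implementation, so the sizing stays correct when V₂ is barely above v₁ and
the linearization fails.

Lag time is the first t with v₂/v₁ ≥ ρ, refined by bisection (with short
RK4 continuations from the bracketing grid point) to 10⁻⁴ min; this is
well-posed because [B](t) is monotone increasing. Sizing bisects on V₂ over
(v₁, upper], doubling the upper bound until feasible, to 10⁻⁶ U/ml, and
reports the result at one significant figure — the precision at which one
pipettes a commercial enzyme. With v₁ = 0.01 mM/min, K_M2 = 2.34 mM,
ρ = 0.99 and a 5 min budget this yields 2.17 → "2 U/ml". ρ = 0.99 and
t_max = 5 min are the defaults because they are the conservative ends of
the ranges practitioners quote (ρ 0.95–0.99, lag 1–5 min).

Background correction is plain subtraction v_interest = v_total − v_bg,
with a warning once the background exceeds half the total; the promiscuous
background itself is modeled first-order ((k_cat/K_M)·[E]·[S]), valid while
[S] ≪ K_M of the side reaction.

## SASA and shells (`structure_metrics`)

SASA is a from-scratch Shrake–Rupley implementation: each atom's sphere of
radius r_vdw + probe (probe 1.4 Å) carries n deterministic golden-spiral
test points (default 960); a point buried inside any neighbour's expanded
sphere is discounted and area = (exposed/n)·4π(r+probe)². Radii are a
Bondi-type element table (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å,
default 1.70). Hydrogens are excluded by default since homology models are
heavy-atom. Accuracy at 960 points is ~0.5% against analytic single-sphere
and two-sphere spherical-cap values; an independent library implementation
agrees within ~3% in the tests.

Rotation invariance: a fixed laboratory-frame point set makes SASA change
by up to ~2% under rotation of the structure. By default the point set is
therefore oriented in a frame built from the structure's principal axes
(signs fixed by atom-order-weighted projections, which co-rotate with the
structure), giving invariance to ≤ 10⁻⁹ relative. The frame falls back to
the identity for < 3 atoms or degenerate principal moments (e.g. symmetric
toys), where the 2% figure applies; `orient="fixed"` disables the feature,
which the occlusion-monotonicity test uses so that adding an atom cannot
move the frame.

Residues with SASA ≥ 20 Å² (boundary inclusive) are "exposed"/external
shell; below, "core"/internal shell. Whether that criterion should use the
whole residue or only its side chain is not standardized across surface
tools, so both modes exist (`sidechain_only`); the default is whole-residue.
Composition reports give per-shell residue-type percentages, the acidic
(D+E) percentage per shell, per-type exposure counts (e.g. "5/6" exposed
tryptophans), and the core fraction both by residue count and by summed
standard residue volume (Zamyatnin-style table; unknown residue names get
140 Å³). The volume-based figure is the natural reading of statements like
"the hydrophobic core represents X% of the protein volume"; the
hydrophobic subset {A,V,L,I,M,F,W,C,G} is configurable.

## Trajectory observables (`traj_analysis`)

Superposition is the Kabsch SVD solution with reflection correction via the
sign of the smallest singular value; collinear or coincident point sets
raise a rank-deficiency error rather than returning one of infinitely many
optima. RMSD series superpose every frame on the chosen reference over the
selection (default in the CLI: Cα atoms — the common mask when none is
stated). RMSF uses an iterated mean reference: frames are aligned to the
first frame, a mean structure is formed, frames are re-aligned to it and
the mean recomputed (two passes), then RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩ per atom,
averaged per residue. R_g is the mass-weighted second moment about the
selection's centre of mass.

Interaction energies are direct double sums over two disjoint selections:
k·q_iq_j/r (k = 332.0636 kcal·Å·mol⁻¹·e⁻²) plus 4ε_ij[(σ_ij/r)¹² −
(σ_ij/r)⁶] with Lorentz–Berthelot combination (σ arithmetic, ε geometric),
no cutoff unless requested, kcal/mol. An (A,B)-coefficient converter
(σ = (A/B)^{1/6}, ε = B²/4A) accepts force-field files in that form. This
is selection-pair analysis, not a total-system energy: there is no PME/
Ewald and no periodic imaging — input trajectories are assumed already
imaged and whole. Pairs closer than 0.1 Å raise a clash error.

Replicate statistics are pointwise mean and sample SD across series, plus a
windowed summary computed per replicate first ("last 10%" window mean ± SD
between replicates), the convention used when reporting trajectory-tail
averages.

## Synthetic data (`synthetic_data`)

Every generator is a pure function of (parameters, seed) using one
`numpy` Generator per call; identical seeds give identical outputs.

* Saturation data: multiplicative Gaussian noise v·(1+ε), ε ~ N(0, cv) —
  constant-CV error matches photometric assays. Defaults used in the tests
  (V_max = 49.1 mM/min, K_M = 2.34 mM, 7-point series from 0.5 to 30 mM,
  3 replicates, cv = 0.05) emulate a realistic high-salt G6P saturation
  experiment.
* Toy structures: an isolated atom, a pair at distance d, and a centre atom
  caged by an icosahedral shell — geometries whose burial is analytically
  known, used to validate SASA.
* Trajectories: frames = reference + isotropic per-coordinate N(0, σ_i)
  noise, optionally wrapped in per-frame uniform random rotations and
  Gaussian translations (rigid tumbling). The expectation E[RMSF] = σ√3
  makes amplitude recovery testable; 2000 frames keep the sampling error of
  the mean RMSF well under the 3% test tolerance.
* Progress curves: the ODE solution with additive Gaussian noise on v₂
  (detector noise on a derived rate signal).

What the synthetic data does **not** emulate: correlated (low-frequency)
protein motions, anisotropic fluctuations, force-field physics, substrate
depletion, pH/ionic-strength effects on the fitted constants, or real
assay drift. Passing tests therefore demonstrate the correctness of the
estimators and numerics on data satisfying the stated models — not that a
particular real enzyme or trajectory will satisfy those models.

## Problem sizes

The shipped tests and the acceptance script run at desk scale by design:
saturation fits of 21 points (200 seeded repetitions for the recovery
statistics), SASA on clusters of ≤ 250 atoms, trajectories of 2000 frames
× 100 atoms, and toy energy systems of ≤ 6 atoms. Published MD observables
from 100 ns production runs (specific RMSD/RMSF/R_g and loop–substrate
energy values) are not reproduction targets: such trajectories are not
redistributable inputs, so the trajectory module is validated against
analytic and brute-force oracles instead.

## Known limitations

* Single-substrate hyperbolic kinetics only — no Hill, substrate
  inhibition, or bi-substrate mechanisms.
* The coupled-assay model holds v₁ constant and assumes a saturating
  co-substrate; long incubations violate both.
* SASA point counts trade speed for precision; areas converge ~0.5% at 960
  points but residues sitting exactly at the 20 Å² boundary can flip labels
  between point densities.
* The principal-axes orientation of the SASA point set is undefined for
  perfectly symmetric structures (it falls back to a fixed frame).
* Energy sums are O(|A|·|B|) per frame; fine for a loop vs. a ligand, not
  for proteome-scale selections.
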