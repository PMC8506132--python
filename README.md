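# halokin

Analysis toolkit for the kinetic and structural characterization of
halophilic enzymes — built around glucose-6-phosphate dehydrogenase (G6PDH)
from haloarchaea, but applicable to any enzyme studied across salt
conditions. It covers five tasks that usually live in five different tools:

1. **Enzyme kinetics** — convert A340 slopes to rates (Beer–Lambert,
   ε_NADH = 6.22 mM⁻¹cm⁻¹), fit the Michaelis–Menten model
   v = V_max·s/(K_M+s) by nonlinear least squares, and report catalytic
   efficiencies k_cat/K_M in M⁻¹s⁻¹.
2. **Coupled-assay design** — integrate the intermediate balance
   d[B]/dt = v₁ − V₂[B]/(K_M2+[B]) of a two-enzyme coupled assay, extract
   the lag before v₂/v₁ reaches a target ratio ρ, size the minimal
   auxiliary activity V₂ for a lag budget, and subtract the auxiliary
   enzyme's promiscuous background activity.
3. **Surface shells** — Shrake–Rupley solvent-accessible surface area
   (1.4 Å probe) computed from scratch; residues with SASA ≥ 20 Å² form the
   exposed (external) shell, the rest the core; per-shell composition
   statistics quantify haloadaptation signatures (acidic surface, depleted
   core leucine, exposed tryptophans, shrunken hydrophobic core).
4. **Trajectory observables** — Kabsch superposition, RMSD series,
   per-residue RMSF, radius of gyration, and direct-sum Coulomb +
   Lennard-Jones interaction energies between selections (e.g. substrate
   vs. binding loop), with replicate averaging.
5. **Motif scanning** — wildcard-aware search for conserved loop motifs
   such as `NLTXXH` and `YERG` in FASTA sequences, 1-based positions.

A seeded synthetic-data module generates every input (saturation datasets,
toy structures with known burial, Gaussian-fluctuation trajectories,
progress curves), so the full pipeline runs without any external file.

## Worked example

```python
from halokin import (AssaySpec, catalytic_efficiency, fit_michaelis_menten,
                     lag_time, minimal_auxiliary_activity)
from halokin.synthetic_data import gen_mm_dataset

# a noisy saturation experiment: 7 G6P concentrations x 3 replicates, 5% CV
ds = gen_mm_dataset(49.1, 2.34, [0.5, 1, 2, 4, 8, 16, 30],
                    cv=0.05, replicates=3, seed=1)
fit = fit_michaelis_menten(ds, enzyme_conc_M=5e-9)
print(f"Vmax = {fit.Vmax:.2f} +/- {fit.se_Vmax:.2f} mM/min")
print(f"KM   = {fit.KM:.2f} +/- {fit.se_KM:.2f} mM")
print(f"kcat/KM = {catalytic_efficiency(14.8, 3.31, sig_figs=2):.3g} M^-1 s^-1")

sizing = minimal_auxiliary_activity(0.01, 2.34, rho=0.99, t_max=5.0)
print(f"minimal auxiliary activity = {sizing.exact:.3f} U/ml "
      f"-> report {sizing.reported:g} U/ml")
print(f"lag at 2 U/ml, rho=0.99: "
      f"{lag_time(AssaySpec(v1=0.01, V2=2.0, KM2=2.34, rho=0.99)):.2f} min")
```

prints

```
Vmax = 48.51 +/- 0.49 mM/min
KM   = 2.27 +/- 0.08 mM
kcat/KM = 4.5e+03 M^-1 s^-1
minimal auxiliary activity = 2.171 U/ml -> report 2 U/ml
lag at 2 U/ml, rho=0.99: 5.43 min
```

The fit recovers the generating parameters (V_max = 49.1 mM/min,
K_M = 2.34 mM) within the noise; the efficiency cell is the published-table
convention of two significant figures. The sizing result reads: to measure
a glucokinase velocity of 0.01 mM/min through a coupled dehydrogenase with
K_M = 2.34 mM for the intermediate, about 2 U/ml of auxiliary enzyme keeps
the lag to steady state (v₂/v₁ ≥ 0.99) within ~5 min.

The same operations are available from the shell:

```bash
halokin synth mm --seed 1 --out mm.csv
halokin fit-mm --input mm.csv --enzyme-nM 5 --out fits.tsv
halokin design-assay --config assay.json
halokin sasa model.pdb --probe 1.4 --out shells.tsv
halokin traj rmsf --traj traj.pdb --sel "name CA" --out rmsf.csv
halokin motif --fasta seqs.fa --pattern NLTXXH
```

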