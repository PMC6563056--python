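# glycoleus

Enhanced-sampling and NMR-observable analysis of O-glycopeptide dihedral
ensembles: local elevation with umbrella sampling (LEUS) on periodic dihedral
coordinates, exponential reweighting to unbiased free-energy maps, Karplus
³J-coupling and r⁻⁶ NOE back-calculation with virtual/pseudo hydrogen sites,
and conformational analyses (hydrogen bonds, secondary-structure propensities,
RMSD clustering, rotational correlation times).

## Who this is for

Researchers studying the conformational effect of mucin-type O-glycosylation
(GalNAc α/β-linked to Ser or Thr — systems such as the Tn antigen) who want a
tested, reusable implementation of the analysis chain that turns biased
dihedral ensembles into NMR-comparable observables. Molecular-dynamics engines
are deliberately out of scope: sampling runs on analytic periodic toy surfaces
(sums of wrapped 2D Gaussian wells) via a Metropolis chain, which makes every
stage checkable against quadrature and constructed-truth oracles.

## The method

**LEUS.** A biasing potential on a dihedral pair (φ, ψ) is grown on an
N_g × N_g grid (N_g = 36, basis width σ = 360°/N_g): whenever the walker
occupies a bin, a force-constant increment c = 0.005 kJ/mol is added to that
bin's basis weight (local elevation). The bias is the weight-scaled sum of
wrapped Gaussian basis functions, smooth and 360°-periodic. Frozen, it serves
as an umbrella for production sampling at 300 K, with the total bias energy
U(Q) recorded per frame.

**Reweighting.** Unbiased probabilities follow from the biased ensemble as

    P(Q) = ⟨δ(Q−Q′) exp(U(Q′)/k_B T)⟩ / ⟨exp(U(Q′)/k_B T)⟩,
    G(Q) = −k_B T ln P(Q),

with the global minimum of each map anchored at 0 kJ/mol and never-visited
bins masked. Uncertainties are four-block errors throughout.

**Observables.** ³J couplings use Karplus relations J(θ) = a cos²θ + b cosθ + c
evaluated per frame (never on the mean angle), e.g. for the backbone amide–Hα
coupling J = 6.51 cos²θ − 1.76 cosθ + 1.60 with θ = φ_P − 60°. NOE distances
are ensemble-averaged as ⟨r⁻⁶⟩^(−1/6) and scored against experimental upper
bounds; violations below 1 Å count as insignificant. United-atom carbons get
geometrically constructed CH/CH₂ virtual hydrogens and CH₃ pseudo-sites.
Hydrogen bonds use the geometric criterion d(H···A) < 0.25 nm and
∠(D−H···A) > 135°. Clustering is greedy largest-neighbourhood at a 0.1 nm
RMSD cutoff; rotational correlation times come from A·exp(−t/τ) + c fits to
Legendre-polynomial autocorrelation functions.

## Worked example

```python
from glycoleus.systems import two_basin_surface, basin_delta_g
from glycoleus.leus import BiasPotential, LEUSSchedule, le_build, us_sample
from glycoleus.reweight import compute_weights, free_energy_map

surface = two_basin_surface(3.0)          # quadrature-calibrated: ΔG = 3.0 kJ/mol
sched = LEUSSchedule(t_le=100_000, t_us=1_000_000, seed=1)
bias = le_build(surface, BiasPotential(surface.angle_names), sched)
traj = us_sample(surface, bias, sched)    # bias energy recorded per frame
weights = compute_weights(traj)           # ∝ exp(+U/kT), normalized
fmap = free_energy_map(traj, weights, surface.angle_names)
print(basin_delta_g(surface))             # 3.000  (quadrature oracle)
print(fmap.grid[fmap.visited_mask].min()) # 0.0    (anchoring contract)
```

With seed 1 this run recovers the basin free-energy difference as
3.054 ± 0.036 kJ/mol against the 3.000 kJ/mol quadrature value — agreement
within two block errors — and the reweighted map minimum is exactly 0.

The `analysis/` directory holds numbered narrative drivers
(`01_sample_and_flatten.py` … `05_stage_validation.py`) that run the full
chain on toy analogues of the four glycopeptide systems and write their
tables under `results/`.

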