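# Methods

## Scope and model

The package re-implements, as a tested pipeline, the analysis chain used to
characterise O-glycopeptide conformation from enhanced-sampling simulations:
local-elevation/umbrella-sampling (LEUS) on dihedral pairs, reweighting to
unbiased ensembles and free-energy maps, back-calculation of ³J couplings and
r⁻⁶-averaged NOE distances, and conformational analyses. The molecular
Hamiltonian is replaced by analytic toy surfaces, so the statistical machinery
— not a force field — is the object under test. Everything downstream of the
sampler is exactly the production analysis and is exercised on ensembles where
ground truth is available by quadrature or construction.

## Toy systems

A surface over one dihedral pair is a sum of wrapped 2D Gaussian wells
(nearest-image distance in both angles), plus optionally cosine torsional
terms k(1 + cos(mθ − θ₀)) on a single angle. Wrapped Gaussians were chosen
because they are smooth, 360°-periodic, and integrable on a 1° grid, giving a
cheap quadrature oracle for Boltzmann populations. The nearest-image form has
a slope discontinuity on the cut circle ±180° from each well centre; it is
exponentially small for the well widths used (≤ 40°) and irrelevant to any
oracle comparison, which uses the same function.

A multi-pair system is a list of surfaces over disjoint named pairs whose
energies add; the four glycopeptide analogues (`glycoleus.systems`) use three
pairs: glycosidic (φ_S, ψ_S), backbone (φ_P, ψ_P) and side-chain/N-acetyl
(χ_S, θ). Basin placements follow the qualitative picture for mucin-type
glycopeptides (α-linked sugars at φ_S ≈ +60°, β-linked additionally at −60°;
backbone β/P_II major with a minor α_R basin, deeper for the β-Thr analogue;
staggered χ_S rotamers). Depths (−9 to −16 kJ/mol) and widths (30–35°) are
fixed package choices made once for realism — deep enough that unbiased
sampling at 300 K is visibly metastable, shallow enough that a desk-scale LE
build flattens them. They are not fits to any published number.

The sampler is Metropolis with independent uniform per-angle proposals
(±step_size, default 30°) and wrap, the simplest correct periodic proposal.
Frames are recorded every `record_every` steps with a nominal 0.1 ps per
step. Identical seed and configuration give bit-identical trajectories.

Angles are canonically stored in [−180°, 180°). Presentation in a [0°, 360°]
frame is a display option, never a storage convention, which avoids wrap bugs.

## Model glycopeptide frames

`build_model_frame` places a reduced capped glycopeptide (acetyl/N-methylamide
caps, backbone N–Cα–C, Ser/Thr side chain, a GalNAc-like sugar fragment with
O1, C1, O5, C2, N2, C7, O7 and an O4–HO4 hydroxyl) by natural-extension
internal coordinates. Bond lengths are idealized (0.153 nm C−C, 0.147 C−N,
0.143 C−O, 0.100 X−H) with tetrahedral/planar angles; exact force-field
geometry is out of scope. The named dihedrals φ_P, ψ_P, χ_S, φ_S, ψ_S and the
N-acetyl orientation θ (C7−N2−C2−C1) reproduce requested values to ~1e−6 deg,
deterministically. The builder makes no attempt to avoid steric clashes at
extreme angle combinations — frames are geometric carriers for distance,
angle and RMSD measurements, not energy-minimized structures. Bonds come from
the template topology; frames read back from PDB re-infer bonds by distance,
which can add spurious contacts in clashed geometries (a documented
limitation of round-tripped frames only).

## LEUS

The bias on a pair is a 36 × 36 grid (σ = bin width = 10°) of basis weights;
one deposition adds c = 0.005 kJ/mol to the occupied bin. The continuous bias
energy is the separable product sum Σ w_ij f_i(φ) g_j(ψ) of 1D wrapped
Gaussians of width σ centred at bin centres — continuous and differentiable,
avoiding acceptance artifacts at bin edges. A piecewise-constant (hard-binned)
variant is available behind the `hard_binned` flag for sensitivity checks.
Deposition cadence defaults to one per sampler step and is configurable,
since a per-step or per-interval build-up is a free choice of the scheme. Two
biases on disjoint pairs compose additively; overlapping pairs are rejected.
During umbrella sampling the weights are frozen (verified by checksum) and
the summed bias energy is recorded per saved frame.

Desk-scale defaults keep the grid constants (36 bins, σ = 10°, c = 0.005
kJ/mol, 300 K) and scale step counts to 10⁴–10⁶, sizes chosen so the full
suite and the acceptance run complete in minutes on one core; the flattening
and closure checks hold at these sizes.

## Reweighting and free-energy maps

Unbiasing weights are w_i ∝ exp(+U_bias,i / k_B T) with
k_B = 0.0083144621 kJ/(mol·K), the maximum bias subtracted before
exponentiation (overflow guard; the common factor cancels). Free-energy maps
are weighted 2D histograms with bin j covering [−180 + jΔ, −180 + (j+1)Δ),
G = −k_B T ln P on visited bins, minimum shifted to exactly 0, and unvisited
bins carrying an infinite sentinel (exported as `NA`) — they are unsampled,
not iso-energetic with the minimum. Maps default to 36 bins; the 6°-binned
ln-occurrence export (`occurrence_map`, negative values clipped to zero) is a
display companion only and deliberately not a free energy.

Block errors split the trajectory into four equal contiguous blocks,
re-normalize weights within each block, and report the standard deviation of
the per-block means. With fewer than four frames the error is reported as
undefined (None), never silently zero.

Hamiltonian reweighting composes exp(−ΔU(θ)/k_B T) for a torsional
perturbation ΔU(θ) = Σ Δk (1 + cos(mθ − θ₀)) with the existing unbiasing
factor. Reliability is tracked by the Kish effective sample size; candidates
below a configurable floor warn (direct use) or score infeasible (search).

The Monte Carlo parameter search minimizes a weighted least-squares objective
over target observables: couplings enter in Hz² with weight 1 and propensity
targets with weight λ = 100 by default, making a 0.1 propensity error
comparable to a 1 Hz coupling error. The exact objective used in the original
reparametrization work is not recoverable, so this one is documented and
configurable rather than asserted as historical. The search is a random-walk
Metropolis on the Δk vector with a linearly annealed acceptance temperature,
tracking the best candidate; it is seed-reproducible, returns the objective
trace, and returns the null perturbation for an empty search space.

## NMR observables

Five Karplus presets ship with the package (coefficients in Hz, offsets in
deg applied to the raw heavy-atom dihedral): the backbone amide–Hα relation
(6.51, −1.76, 1.60; θ = φ_P − 60°), the GalNAc N-acetyl amide relation
(9.6, −1.51, 0.99; θ + 60°), and the Hα–Hβ relation (9.5, −1.6, 1.80) with
offsets −120° for Thr and 0°/−120° for the Ser Hβ2/Hβ3 stereo-pair. The
Hβ2/Hβ3 assignment is fixed by the prochiral-labelling convention of the
virtual-site constructor; an experimental stereo-assignment swap is a
configuration change (swap the two presets), not a code change. J is always
evaluated per frame and then averaged — the relation is quadratic in cosθ, so
the Karplus of a mean angle would be biased.

Virtual sites on united-atom carbons: CH places one H at 0.10 nm along the
negative resultant of the unit vectors to the three heavy neighbours; CH₂
places a prochiral pair in the plane of the heavy-neighbour bisector and
normal with a tetrahedral H–C–H angle (swapping neighbour order swaps only
the B1/B2 labels); CH₃ uses a pseudo-site at the carbon with a +0.3 Å
correction added to measured distances. The correction value is a package
default (the original geometric constants are not recoverable); the
explicit-rotor check in the tests shows the corrected pseudo-distance is a
conservative upper proxy of the rotor r⁻⁶ average within a bounded margin.

NOE averages are ⟨r⁻⁶⟩^(−1/6) with four-block errors; violations are
one-sided against upper bounds, max(0, computed − bound), significant at
1 Å. The significance comparison carries a 1e−9 Å tolerance so floating-point
round trips cannot flip the flag. Internally lengths are nm; NOE-facing
interfaces use Å, converted in one place.

## Conformational analyses

Hydrogen bonds: H···A distance < 0.25 nm and D−H···A angle > 135°; the 2%
reporting threshold is a report filter, not part of the computation.

Propensity regions (φ/ψ boxes, half-open edges): β: φ ∈ [−180°, −100°) with
ψ ∈ [50°, 180°) ∪ [−180°, −150°); P_II: φ ∈ [−100°, −20°), ψ ∈ [50°, 180°);
α: φ ∈ [−160°, −20°), ψ ∈ [−120°, 50°); everything else unclassified. The
exact region definitions used in the original study are in unavailable
supplementary material; these shipped defaults are the package's own
conventional choice, configurable, and consistent with the customary
three-column φ binning ([−180°, −100°], [−100°, 0°], [0°, 180°]). Labels
partition every ensemble: propensities sum to 1 under any weighting.

Clustering follows the greedy largest-neighbourhood algorithm: pairwise RMSD
after least-squares superposition on a fit selection (backbone plus sugar-core
atoms; the RMSD itself is evaluated over a possibly different calc selection),
then repeatedly take the frame with the most unassigned neighbours within the
cutoff (ties to the lowest frame index) as a medoid and remove its
neighbourhood. Coverage curves restrict the full clustering's memberships to
frames up to each time point, re-rank by restricted size, and count the
clusters needed to reach each coverage level. Whether the original analysis
re-clusters each prefix or restricts one full clustering is ambiguous; the
restricted reading is implemented (and flagged here) because it makes the
curves a property of one clustering rather than of n re-runs.

Rotational correlation: origin-averaged autocorrelation of the Legendre
polynomial (order 2 by default, the NMR-relevant choice; order 1 available)
of the angle between v(t₀) and v(t₀+t), fitted to A·exp(−t/τ) + c by
bounded least squares, initialized at the first 1/e crossing. The fit form is
read with t as the lag time. A non-decaying ACF is reported as unresolvable,
never as a number. The synthetic rotational-diffusion generator applies
per-step random rotations with per-axis angular variance 2 D_r dt, for which
the order-2 ACF decays analytically as exp(−6 D_r t).

## Determinism and seeds

A single global seed expands to per-stage seeds by a fixed counter scheme
(seed × 7919 + stage, mod 2³¹), so any stage can be re-run in isolation.
All stochastic entry points take explicit seeds; identical seeds give
bit-identical outputs.

## What the toy setting does and does not show

Passing tests demonstrate that the estimators are correct: the LE build
flattens what it should, exponential reweighting closes against quadrature
within stated errors, Hamiltonian reweighting is equivalent to direct
simulation for moderate perturbations, the observable arithmetic (Karplus,
r⁻⁶, violations, propensities, clustering, ACF fits) matches independent
oracles, and the published violation table is reproduced from its printed
inputs. They do not validate any force field, solvent model, or the
dynamical realism of the ensembles: toy surfaces have no coupling between
dihedral pairs beyond what the builder's shared geometry induces, no solvent,
no kinetics beyond Metropolis mixing, and Cartesian frames are idealized
geometric reconstructions. Conclusions about real glycopeptides require real
trajectories; this package supplies the audited analysis to run on them.

## Known limitations

* The LE memory function of the original simulation engine may use a
  different (e.g. truncated-polynomial) basis; the published description
  fixes only the binning, width and increment, so the wrapped-Gaussian basis
  here is a documented choice, with a hard-binned variant for sensitivity.
* Water-bridged hydrogen bonds require explicit solvent and are out of scope.
* Multi-window estimators (WHAM/MBAR) are not implemented; reweighting is
  single-window exponential, as in the method being reproduced.
* `read_frames` re-infers bonds from distances and can mis-assign them for
  sterically clashed toy geometries; built frames carry exact topology.
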