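"""Reweighting of biased ensembles and free-energy map construction.

Unbiased expectations are recovered from umbrella-sampled trajectories by the
exponential estimator

    <A>_unbiased = <A exp(+U_bias/kB T)> / <exp(+U_bias/kB T)>,

i.e. per-frame weights proportional to exp(+U_bias/kB T). Free energies follow
from weighted histograms as G = -kB T ln P, anchored so the visited-bin
minimum is exactly 0. Hamiltonian reweighting evaluates the effect of a
perturbed torsional potential ΔU(θ) = Σ Δk (1 + cos(m θ - θ0)) without
re-sampling, and a Monte Carlo search over such perturbations fits target
observables (J-couplings, secondary-structure propensities).

Uncertainties are block errors: the trajectory is split into four equally long
contiguous blocks and the standard deviation of the per-block (re-normalized)
weighted means is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from glycoleus.constants import DEFAULT_TEMPERATURE, KB
from glycoleus.toy_system import DihedralTrajectory

N_BLOCKS = 4

#: sentinel stored in FreeEnergyMap.grid for never-visited bins
UNVISITED = np.inf


@dataclass
class FrameWeights:
    """Normalized per-frame statistical weights of a (possibly biased) ensemble."""

    weights: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        s = self.weights.sum()
        if not np.isfinite(s) or s <= 0:
            raise ValueError("weights must have a positive finite sum")
        self.weights = self.weights / s

    @property
    def n_frames(self) -> int:
        return len(self.weights)

    @property
    def effective_sample_size(self) -> float:
        """Kish effective sample size, in (0, n_frames]."""
        return float(1.0 / np.sum(self.weights**2))

    @classmethod
    def uniform(cls, n: int, temperature: float = DEFAULT_TEMPERATURE) -> "FrameWeights":
        return cls(np.full(n, 1.0 / n), temperature)


def compute_weights(
    traj: DihedralTrajectory, temperature: float = DEFAULT_TEMPERATURE
) -> FrameWeights:
    """Unbiasing weights exp(+U_bias/kB T) from a biased trajectory.

    The maximum bias energy is subtracted before exponentiation to guard
    against overflow; the common factor cancels on normalization.
    """
    if traj.bias_energy is None:
        raise ValueError("trajectory carries no bias_energy; nothing to reweight")
    u = traj.bias_energy
    w = np.exp((u - u.max()) / (KB * temperature))
    return FrameWeights(w, temperature)


def _block_slices(n: int) -> list[slice]:
    edges = np.linspace(0, n, N_BLOCKS + 1).astype(int)
    return [slice(edges[k], edges[k + 1]) for k in range(N_BLOCKS)]


def weighted_expectation(
    values, weights: FrameWeights
) -> tuple[float, Optional[float]]:
    """Weighted ensemble mean and its four-block error.

    The block error is the standard deviation of the per-block weighted means,
    with weights re-normalized within each block. With fewer than four frames
    the block error is undefined and reported as None.
    """
    values = np.asarray(values, dtype=float)
    w = weights.weights
    if len(values) != len(w):
        raise ValueError("values and weights length mismatch")
    mean = float(np.dot(w, values))
    if len(values) < N_BLOCKS:
        return mean, None
    block_means = []
    for sl in _block_slices(len(values)):
        bw = w[sl]
        block_means.append(np.dot(bw / bw.sum(), values[sl]))
    return mean, float(np.std(block_means))


@dataclass
class FreeEnergyMap:
    """2D periodic free-energy surface over a dihedral pair.

    ``grid[i, j]`` is the free energy (kJ/mol) of bin (i, j); bins never
    visited hold the ``UNVISITED`` sentinel and are flagged False in
    ``visited_mask``. The minimum over visited bins is exactly 0.
    """

    angle_pair: tuple[str, str]
    grid: np.ndarray
    visited_mask: np.ndarray
    bin_width: float
    temperature: float = DEFAULT_TEMPERATURE
    contour_spacing: float = 5.0

    def __post_init__(self):
        self.angle_pair = tuple(self.angle_pair)
        self.grid = np.asarray(self.grid, dtype=float)
        self.visited_mask = np.asarray(self.visited_mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.grid.shape[0]

    @property
    def bin_centers(self) -> np.ndarray:
        return -180.0 + (np.arange(self.n_bins) + 0.5) * self.bin_width

    def value_at(self, phi: float, psi: float) -> float:
        i = int((phi + 180.0) // self.bin_width) % self.n_bins
        j = int((psi + 180.0) // self.bin_width) % self.n_bins
        return float(self.grid[i, j])


def free_energy_map(
    traj: DihedralTrajectory,
    weights: FrameWeights,
    pair: Sequence[str],
    n_bins: int = 36,
    contour_spacing: float = 5.0,
) -> FreeEnergyMap:
    """Weighted 2D dihedral histogram converted to free energies.

    G = -kB T ln P on visited bins, shifted so the global minimum is 0;
    unvisited bins carry the ``UNVISITED`` sentinel (they are unsampled, not
    iso-energetic with the minimum).
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    pair = tuple(pair)
    phi = traj.column(pair[0])
    psi = traj.column(pair[1])
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    hist, _, _ = np.histogram2d(phi, psi, bins=[edges, edges], weights=weights.weights)
    visited = hist > 0
    g = np.full_like(hist, UNVISITED)
    kt = KB * weights.temperature
    g[visited] = -kt * np.log(hist[visited])
    g[visited] -= g[visited].min()
    return FreeEnergyMap(
        pair, g, visited, 360.0 / n_bins, weights.temperature, contour_spacing
    )


def occurrence_map(
    traj: DihedralTrajectory,
    weights: FrameWeights,
    pair: Sequence[str],
    bin_width: float = 6.0,
) -> np.ndarray:
    """Binned ln-occurrence surface for presentation-style colouring.

    Uses the stated occurrence convention: ln P relative to the least-occupied
    visited bin, with negative values clipped to zero; a display companion to
    :func:`free_energy_map`, not a free energy.
    """
    n_bins = int(round(360.0 / bin_width))
    pair = tuple(pair)
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    hist, _, _ = np.histogram2d(
        traj.column(pair[0]), traj.column(pair[1]), bins=[edges, edges], weights=weights.weights
    )
    out = np.zeros_like(hist)
    visited = hist > 0
    out[visited] = np.maximum(np.log(hist[visited] / hist[visited].min()), 0.0)
    return out


@dataclass(frozen=True)
class DihedralTermPerturbation:
    """Change of a cosine torsional potential on one named dihedral.

    ``terms`` are (delta_k kJ/mol, phase deg, multiplicity) triples; the
    perturbation energy is ΔU(θ) = Σ Δk (1 + cos(m θ - θ0)).
    """

    angle_name: str
    terms: tuple[tuple[float, float, int], ...] = ()

    def __post_init__(self):
        for dk, phase, m in self.terms:
            if int(m) != m or m <= 0:
                raise ValueError("multiplicities must be positive integers")

    def energy(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        du = np.zeros_like(theta)
        for dk, phase, m in self.terms:
            du += dk * (1.0 + np.cos(np.radians(m * theta - phase)))
        return du

    @property
    def is_null(self) -> bool:
        return all(dk == 0 for dk, _, _ in self.terms) or not self.terms


def hamiltonian_reweight(
    traj: DihedralTrajectory,
    perturbation: DihedralTermPerturbation,
    temperature: float = DEFAULT_TEMPERATURE,
    ess_floor: float = 10.0,
) -> FrameWeights:
    """Per-frame weights for a perturbed torsional Hamiltonian.

    weight_i ∝ exp(-ΔU(θ_i)/kB T), composed with the unbiasing factor
    exp(+U_bias/kB T) when the trajectory was sampled under a bias. Warns when
    the Kish effective sample size falls below ``ess_floor``.
    """
    theta = traj.column(perturbation.angle_name)
    log_w = -perturbation.energy(theta) / (KB * temperature)
    if traj.bias_energy is not None:
        log_w = log_w + traj.bias_energy / (KB * temperature)
    w = np.exp(log_w - log_w.max())
    fw = FrameWeights(w, temperature)
    if fw.effective_sample_size < ess_floor:
        import warnings

        warnings.warn(
            f"effective sample size {fw.effective_sample_size:.1f} below floor "
            f"{ess_floor}; reweighting unreliable",
            stacklevel=2,
        )
    return fw


@dataclass(frozen=True)
class ObservableTarget:
    """One term of the parameter-search objective.

    ``func(traj, weights) -> float`` evaluates the observable under candidate
    weights; the objective accumulates ``weight * (value - target)**2``.
    J-coupling targets conventionally get weight 1 (Hz^2 scale) and propensity
    targets weight ``lambda_prop`` (default 100), making a 0.1 propensity
    error comparable to a 1 Hz coupling error.
    """

    func: Callable[[DihedralTrajectory, FrameWeights], float]
    target: float
    weight: float = 1.0


@dataclass(frozen=True)
class TermSearchSpace:
    """Bounds for one cosine-term force constant in the MC search."""

    angle_name: str
    multiplicity: int
    phase: float = 0.0
    k_min: float = -5.0
    k_max: float = 5.0


@dataclass
class SearchResult:
    best: DihedralTermPerturbation
    best_objective: float
    trace: list = field(default_factory=list)


def _objective(traj, targets, perturbation, temperature, ess_floor):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fw = hamiltonian_reweight(traj, perturbation, temperature, ess_floor=0.0)
    if fw.effective_sample_size < ess_floor:
        return np.inf
    return sum(t.weight * (t.func(traj, fw) - t.target) ** 2 for t in targets)


def parameter_search(
    traj: DihedralTrajectory,
    targets: Sequence[ObservableTarget],
    search_space: Sequence[TermSearchSpace],
    temperature: float = DEFAULT_TEMPERATURE,
    n_iter: int = 300,
    seed: int = 0,
    ess_floor: float = 20.0,
    step_frac: float = 0.1,
) -> SearchResult:
    """Monte Carlo search for torsional-term changes matching target observables.

    A random-walk Metropolis search on the Δk vector (one component per entry
    of ``search_space``, all on the same angle) minimizing the weighted
    squared deviation of reweighted observables from their targets. Candidates
    whose effective sample size falls below ``ess_floor`` score infeasible.
    Seed-reproducible; returns the best candidate and the objective trace.
    An empty search space returns the null perturbation.
    """
    for t in targets:
        if not np.isfinite(t.target):
            raise ValueError("targets must be finite")
    if not search_space:
        null = DihedralTermPerturbation(angle_name="", terms=())
        obj = sum(
            t.weight * (t.func(traj, _uniform_or_unbias(traj, temperature)) - t.target) ** 2
            for t in targets
        )
        return SearchResult(null, float(obj), [float(obj)])
    angle = search_space[0].angle_name
    if any(s.angle_name != angle for s in search_space):
        raise ValueError("all search-space terms must perturb the same angle")

    rng = np.random.default_rng(seed)
    lo = np.array([s.k_min for s in search_space])
    hi = np.array([s.k_max for s in search_space])
    step = step_frac * (hi - lo)

    def make(ks):
        return DihedralTermPerturbation(
            angle, tuple((float(k), s.phase, s.multiplicity) for k, s in zip(ks, search_space))
        )

    ks = np.zeros(len(search_space))
    obj = _objective(traj, targets, make(ks), temperature, ess_floor)
    best_ks, best_obj = ks.copy(), obj
    trace = [obj]
    # greedy-with-escapes annealed acceptance on the objective
    for it in range(n_iter):
        prop = np.clip(ks + rng.normal(0.0, step), lo, hi)
        obj_p = _objective(traj, targets, make(prop), temperature, ess_floor)
        t_anneal = max(1e-3, 1.0 * (1.0 - it / n_iter))
        if obj_p < obj or (
            np.isfinite(obj_p) and rng.random() < np.exp(-(obj_p - obj) / t_anneal)
        ):
            ks, obj = prop, obj_p
            if obj < best_obj:
                best_ks, best_obj = ks.copy(), obj
        trace.append(obj)
    return SearchResult(make(best_ks), float(best_obj), trace)


def _uniform_or_unbias(traj, temperature):
    if traj.bias_energy is not None:
        return compute_weights(traj, temperature)
    return FrameWeights.uniform(traj.n_frames, temperature)
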