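"""Conformational analyses: hydrogen bonds, propensities, clustering, tumbling.

Hydrogen bonds use the geometric criterion (H...acceptor distance below
0.25 nm and donor-H-acceptor angle above 135 degrees). Secondary-structure
propensities classify backbone (phi, psi) points into alpha / beta /
polyproline-II boxes (everything else unclassified); the shipped box
boundaries are a documented package choice. Conformational clustering is the
greedy largest-neighbourhood algorithm on a pairwise RMSD matrix computed
after least-squares superposition on a fit selection. Rotational correlation
times come from exponential fits to Legendre-polynomial autocorrelation
functions of molecule-fixed vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from glycoleus.geometry import measure_angle, superposed_rmsd
from glycoleus.reweight import FrameWeights
from glycoleus.toy_system import CartesianFrame, DihedralTrajectory


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition (distances nm, angles deg)."""

    max_ha_distance: float = 0.25
    min_dha_angle: float = 135.0

    def __post_init__(self):
        if self.max_ha_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0.0 < self.min_dha_angle <= 180.0:
            raise ValueError("angle cutoff must be in (0, 180]")

    def is_hbond(self, d_pos, h_pos, a_pos) -> bool:
        if np.linalg.norm(np.asarray(h_pos) - np.asarray(a_pos)) >= self.max_ha_distance:
            return False
        return measure_angle(d_pos, h_pos, a_pos) > self.min_dha_angle


def detect_hbonds(
    frames: Sequence[CartesianFrame],
    weights: FrameWeights,
    donors: Sequence[tuple[str, str]],
    acceptors: Sequence[str],
    criterion: HBondCriterion = HBondCriterion(),
    report_threshold: float = 2.0,
) -> dict[str, float]:
    """Weighted hydrogen-bond occurrence percentages per donor/acceptor pair.

    ``donors`` are (donor, hydrogen) atom-name pairs; every donor is tested
    against every acceptor except itself. Returns a dict keyed
    ``"H-A"`` (hydrogen-acceptor labels) with occurrences in percent,
    filtered at ``report_threshold`` (set it to 0 to keep everything).
    """
    if len(frames) != weights.n_frames:
        raise ValueError("frames and weights length mismatch")
    for d, h in donors:
        if h not in frames[0].names:
            raise KeyError(f"donor hydrogen {h!r} missing from frames")
        if d not in frames[0].names:
            raise KeyError(f"donor atom {d!r} missing from frames")
    occ: dict[str, float] = {}
    w = weights.weights
    for d, h in donors:
        for a in acceptors:
            if a in (d, h):
                continue
            total = 0.0
            for k, fr in enumerate(frames):
                if criterion.is_hbond(fr.position(d), fr.position(h), fr.position(a)):
                    total += w[k]
            occ[f"{h}-{a}"] = 100.0 * total
    return {k: v for k, v in occ.items() if v >= report_threshold}


# --------------------------------------------------------------------------
# Secondary-structure propensities
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Box:
    """Half-open (phi, psi) box; psi may wrap across the periodic seam."""

    phi: tuple[float, float]
    psi_intervals: tuple[tuple[float, float], ...]

    def contains(self, phi: float, psi: float) -> bool:
        if not self.phi[0] <= phi < self.phi[1]:
            return False
        return any(lo <= psi < hi for lo, hi in self.psi_intervals)


@dataclass(frozen=True)
class PropensityRegions:
    """Named Ramachandran boxes for alpha, beta and polyproline-II.

    The shipped defaults are the package's own choice of conventional regions
    (configurable); membership order beta -> P_II -> alpha keeps the label
    sets disjoint, and everything else is unclassified (UC).
    """

    beta: Box = Box((-180.0, -100.0), ((50.0, 180.0), (-180.0, -150.0)))
    p_ii: Box = Box((-100.0, -20.0), ((50.0, 180.0),))
    alpha: Box = Box((-160.0, -20.0), ((-120.0, 50.0),))

    def classify(self, phi: float, psi: float) -> str:
        if self.beta.contains(phi, psi):
            return "beta"
        if self.p_ii.contains(phi, psi):
            return "P_II"
        if self.alpha.contains(phi, psi):
            return "alpha"
        return "UC"


def classify_backbone(
    phi: float, psi: float, regions: PropensityRegions = PropensityRegions()
) -> str:
    """Label one backbone point as alpha, beta, P_II or UC (half-open edges)."""
    return regions.classify(float(phi), float(psi))


def propensities(
    traj: DihedralTrajectory,
    weights: FrameWeights,
    phi_name: str = "phi_P",
    psi_name: str = "psi_P",
    regions: PropensityRegions = PropensityRegions(),
) -> dict[str, float]:
    """Weighted secondary-structure propensities; the four labels sum to 1."""
    phi = traj.column(phi_name)
    psi = traj.column(psi_name)
    out = {"alpha": 0.0, "beta": 0.0, "P_II": 0.0, "UC": 0.0}
    for p, s, w in zip(phi, psi, weights.weights):
        out[regions.classify(p, s)] += w
    return out


def phi_bin_preferences(
    traj: DihedralTrajectory,
    weights: FrameWeights,
    angle_name: str = "phi_P",
    bin_edges: Sequence[float] = (-180.0, -100.0, 0.0, 180.0),
) -> list[float]:
    """Weighted percentage of frames per angle bin; sums to 100.

    Edges must be ordered; bins are half-open except the last, which includes
    its upper edge so the full circle is covered.
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    x = traj.column(angle_name)
    w = weights.weights
    fracs = []
    for k, (lo, hi) in enumerate(zip(edges, edges[1:])):
        if k == len(edges) - 2:
            mask = (x >= lo) & (x <= hi)
        else:
            mask = (x >= lo) & (x < hi)
        fracs.append(100.0 * w[mask].sum())
    return fracs


# --------------------------------------------------------------------------
# Conformational clustering
# --------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """Greedy largest-neighbourhood clustering of a frame set.

    ``clusters`` is rank-ordered by size (non-increasing); each entry holds
    the member frame indices with the medoid (the neighbourhood centre) first.
    """

    clusters: list[list[int]]
    medoids: list[int]
    cutoff: float
    rmsd_matrix: Optional[np.ndarray] = None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> np.ndarray:
        n = sum(len(c) for c in self.clusters)
        m = np.empty(n, dtype=int)
        for rank, members in enumerate(self.clusters):
            m[members] = rank
        return m


def rmsd_matrix(
    frames: Sequence[CartesianFrame],
    fit_selection: Sequence[str],
    calc_selection: Sequence[str],
) -> np.ndarray:
    """Pairwise RMSD (nm) over ``calc_selection`` after superposition on ``fit_selection``."""
    if not frames:
        raise ValueError("need at least one frame")
    if not fit_selection or not calc_selection:
        raise ValueError("selections must be nonempty")
    fit_idx = np.array([frames[0].index(n) for n in fit_selection])
    calc_idx = np.array([frames[0].index(n) for n in calc_selection])
    coords = np.array([f.coords for f in frames])
    n = len(frames)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = superposed_rmsd(coords[i], coords[j], fit_idx, calc_idx)
    return mat


def cluster_conformations(
    frames: Sequence[CartesianFrame],
    fit_selection: Sequence[str],
    calc_selection: Sequence[str],
    cutoff: float = 0.1,
    precomputed_rmsd: Optional[np.ndarray] = None,
) -> ClusterResult:
    """Greedy largest-neighbourhood clustering at an RMSD cutoff (nm).

    Repeatedly takes the unassigned frame with the most unassigned neighbours
    within ``cutoff`` (ties broken by lowest frame index) as a medoid, removes
    it and its neighbours as one cluster, and iterates until all frames are
    assigned. Clusters partition the frames and are returned largest first.
    """
    mat = precomputed_rmsd if precomputed_rmsd is not None else rmsd_matrix(
        frames, fit_selection, calc_selection
    )
    n = mat.shape[0]
    neighbor = mat <= cutoff
    np.fill_diagonal(neighbor, True)
    unassigned = np.ones(n, dtype=bool)
    clusters, medoids = [], []
    while unassigned.any():
        counts = (neighbor & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        medoid = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbor[medoid] & unassigned)
        members = [medoid] + [int(i) for i in members if i != medoid]
        clusters.append(members)
        medoids.append(medoid)
        unassigned[members] = False
    order = sorted(range(len(clusters)), key=lambda k: (-len(clusters[k]), k))
    return ClusterResult(
        [clusters[k] for k in order], [medoids[k] for k in order], cutoff, mat
    )


def coverage_curves(
    result: ClusterResult,
    times: Sequence[float],
    coverage_levels: Sequence[float] = (0.99, 0.95, 0.75, 0.50),
) -> dict[float, list[int]]:
    """Clusters needed to cover a fraction of the trajectory sampled up to t.

    For each time point the full-trajectory cluster memberships are restricted
    to frames at or before that time, re-ranked by restricted size, and the
    minimal number of clusters whose cumulative restricted size reaches
    ``level * n(t)`` is reported. Returns {level: counts aligned with times}.
    """
    membership = result.membership()
    times = np.asarray(times, dtype=float)
    n = len(membership)
    if len(times) != n:
        raise ValueError("times must align with clustered frames")
    out = {level: [] for level in coverage_levels}
    for t in times:
        prefix = membership[times <= t]
        sizes = np.sort(np.bincount(prefix, minlength=result.n_clusters))[::-1]
        sizes = sizes[sizes > 0]
        cum = np.cumsum(sizes)
        for level in coverage_levels:
            need = level * len(prefix)
            out[level].append(int(np.searchsorted(cum, need - 1e-9) + 1))
    return out


# --------------------------------------------------------------------------
# Rotational correlation times
# --------------------------------------------------------------------------


def _legendre(order: int, x: np.ndarray) -> np.ndarray:
    if order == 1:
        return x
    if order == 2:
        return 1.5 * x**2 - 0.5
    raise ValueError("Legendre order must be 1 or 2")


def vector_autocorrelation(
    vectors: np.ndarray, order: int = 2, max_lag: Optional[int] = None
) -> np.ndarray:
    """Origin-averaged Legendre ACF of a unit-vector time series.

    C_l(t) = < P_l( u(t0) . u(t0+t) ) >_{t0}; lag 0 gives exactly 1.
    """
    v = np.asarray(vectors, dtype=float)
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    n = len(v)
    if max_lag is None:
        max_lag = n // 4
    acf = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        dots = np.einsum("ij,ij->i", v[: n - lag], v[lag:])
        acf[lag] = _legendre(order, dots).mean()
    return acf


@dataclass(frozen=True)
class RotationalFit:
    """Exponential fit A exp(-t/tau) + c to a Legendre ACF."""

    tau_ps: Optional[float]
    amplitude: Optional[float]
    offset: Optional[float]
    resolvable: bool


def rotational_tau(
    vectors: np.ndarray,
    dt_ps: float,
    order: int = 2,
    max_lag: Optional[int] = None,
) -> RotationalFit:
    """Rotational correlation time from an exponential ACF fit.

    Requires at least 100 frames at uniform time spacing ``dt_ps``. The ACF of
    the order-``order`` Legendre polynomial of the angle between v(t0) and
    v(t0+t) is fitted to A exp(-t/tau) + c by least squares. A non-decaying
    ACF (static vector) is reported as unresolvable rather than a number.
    """
    v = np.asarray(vectors, dtype=float)
    if len(v) < 100:
        raise ValueError("need at least 100 frames for a correlation-time fit")
    acf = vector_autocorrelation(v, order=order, max_lag=max_lag)
    if np.ptp(acf) < 1e-6:
        return RotationalFit(None, None, None, resolvable=False)
    t = dt_ps * np.arange(len(acf))

    def model(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    # initial tau from the first 1/e crossing, if any
    below = np.flatnonzero(acf < acf[0] / np.e)
    tau0 = t[below[0]] if len(below) else t[-1] / 2.0
    tau0 = max(tau0, dt_ps)
    try:
        popt, _ = curve_fit(
            model,
            t,
            acf,
            p0=(acf[0], tau0, acf[-1]),
            bounds=([0.0, dt_ps * 1e-3, -0.5], [2.0, np.inf, 1.0]),
            maxfev=10000,
        )
    except RuntimeError:
        return RotationalFit(None, None, None, resolvable=False)
    a, tau, c = popt
    return RotationalFit(float(tau), float(a), float(c), resolvable=True)
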