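"""Synthetic toy systems standing in for the molecular-dynamics engine.

Three generators live here:

* analytic periodic energy surfaces over dihedral pairs (sums of wrapped 2D
  Gaussian wells), which are smooth, 360-degree periodic and cheap enough to
  integrate by quadrature for oracle checks;
* a Metropolis sampler producing Boltzmann-distributed dihedral ensembles at a
  given temperature, optionally under frozen biasing potentials with the bias
  energy recorded per saved frame;
* an internal-coordinate builder of small Cartesian glycopeptide-like frames
  (peptide backbone with N-acetyl / N-methylamide caps, a GalNAc-like sugar
  fragment) whose named dihedrals are set exactly to requested values, plus a
  rotational-diffusion vector generator for correlation-time tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from glycoleus.constants import DEFAULT_TEMPERATURE, KB
from glycoleus.geometry import (
    angular_difference,
    measure_dihedral,
    place_atom,
    wrap_angle,
)


@dataclass(frozen=True)
class GaussianWell:
    """One periodic-Gaussian well of an analytic surface.

    ``depth`` is the (usually negative) energy at the well centre in kJ/mol;
    ``width`` is the Gaussian standard deviation in degrees. Distances to the
    centre are nearest-image (wrapped) in both angles.
    """

    center_phi: float
    center_psi: float
    depth: float
    width: float


@dataclass(frozen=True)
class AnalyticSurface:
    """Sum of wrapped Gaussian wells over one named dihedral pair.

    ``torsion_terms`` optionally adds cosine torsional potentials
    k (1 + cos(m θ - phase)) on one of the two angles (axis 0 or 1), entries
    (k kJ/mol, phase deg, multiplicity, axis) — the analytic analogue of a
    force-field dihedral term, used to plant known perturbations.
    """

    terms: tuple[GaussianWell, ...] = ()
    offset: float = 0.0
    angle_names: tuple[str, str] = ("phi", "psi")
    torsion_terms: tuple[tuple[float, float, int, int], ...] = ()

    def energy(self, phi, psi):
        """Energy in kJ/mol at (phi, psi) degrees; vectorized; 360-periodic."""
        phi = np.asarray(phi, dtype=float)
        psi = np.asarray(psi, dtype=float)
        e = np.full(np.broadcast(phi, psi).shape, self.offset, dtype=float)
        for t in self.terms:
            dphi = angular_difference(phi, t.center_phi)
            dpsi = angular_difference(psi, t.center_psi)
            e += t.depth * np.exp(-(dphi**2 + dpsi**2) / (2.0 * t.width**2))
        for k, phase, m, axis in self.torsion_terms:
            theta = phi if axis == 0 else psi
            e += k * (1.0 + np.cos(np.radians(m * theta - phase)))
        return e if e.shape else float(e)

    def boltzmann_grid(self, temperature: float = DEFAULT_TEMPERATURE, spacing: float = 1.0):
        """Normalized Boltzmann density on a square grid (quadrature oracle).

        Returns (grid_angles, density) where density sums to 1 over the grid.
        """
        g = np.arange(-180.0, 180.0, spacing)
        pp, ss = np.meshgrid(g, g, indexing="ij")
        e = self.energy(pp, ss)
        w = np.exp(-(e - e.min()) / (KB * temperature))
        return g, w / w.sum()


def surface_energy(surface: AnalyticSurface, phi, psi):
    """Functional alias for :meth:`AnalyticSurface.energy`."""
    return surface.energy(phi, psi)


@dataclass(frozen=True)
class SamplerConfig:
    """Metropolis sampler settings.

    ``step_size`` is the half-width (deg) of the uniform per-angle proposal;
    every ``record_every``-th step is saved as a frame, with frame times spaced
    at ``dt_ps`` per sampler step.
    """

    n_steps: int
    temperature: float = DEFAULT_TEMPERATURE
    step_size: float = 30.0
    seed: int = 0
    record_every: int = 10
    dt_ps: float = 0.1

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be nonnegative")
        if not 0.0 < self.step_size <= 180.0:
            raise ValueError("step_size must be in (0, 180] degrees")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass
class DihedralTrajectory:
    """Per-frame values of named periodic dihedral angles.

    ``angles`` is an (n_frames, n_angles) array in canonical degrees;
    ``bias_energy`` (kJ/mol per frame) is present iff the ensemble was produced
    under a biasing potential.
    """

    angle_names: tuple[str, ...]
    angles: np.ndarray
    times: np.ndarray
    bias_energy: Optional[np.ndarray] = None

    def __post_init__(self):
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        self.angle_names = tuple(self.angle_names)
        if self.angles.shape[1] != len(self.angle_names):
            raise ValueError("angle column count does not match angle_names")
        if self.angles.shape[0] != len(self.times):
            raise ValueError("times length does not match frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.angles >= 180.0) or np.any(self.angles < -180.0):
            raise ValueError("angles must lie in [-180, 180)")
        if self.bias_energy is not None:
            self.bias_energy = np.asarray(self.bias_energy, dtype=float)
            if len(self.bias_energy) != len(self.times):
                raise ValueError("bias_energy length does not match frame count")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.angles[:, self.angle_names.index(name)]


def _normalize_surfaces(surface) -> tuple[AnalyticSurface, ...]:
    if isinstance(surface, AnalyticSurface):
        return (surface,)
    return tuple(surface)


def _surface_params(s: AnalyticSurface):
    """Vectorized per-term parameters for the fast scalar energy path."""
    if not s.terms and not s.torsion_terms:
        return None
    cphi = np.array([t.center_phi for t in s.terms])
    cpsi = np.array([t.center_psi for t in s.terms])
    depth = np.array([t.depth for t in s.terms])
    inv2w2 = 1.0 / (2.0 * np.array([t.width for t in s.terms]) ** 2)
    return cphi, cpsi, depth, inv2w2, s.torsion_terms


def _fast_energy(params, offset, phi, psi):
    if params is None:
        return offset
    cphi, cpsi, depth, inv2w2, torsions = params
    e = offset
    if len(depth):
        dphi = (phi - cphi + 180.0) % 360.0 - 180.0
        dpsi = (psi - cpsi + 180.0) % 360.0 - 180.0
        e += float(np.sum(depth * np.exp(-(dphi * dphi + dpsi * dpsi) * inv2w2)))
    for k, phase, m, axis in torsions:
        theta = phi if axis == 0 else psi
        e += k * (1.0 + np.cos(np.radians(m * theta - phase)))
    return e


def sample_dihedrals(
    surface,
    config: SamplerConfig,
    bias=None,
) -> DihedralTrajectory:
    """Metropolis-sample dihedral ensembles from one or more analytic surfaces.

    ``surface`` may be a single :class:`AnalyticSurface` or a sequence of
    surfaces over disjoint angle pairs (their energies add). ``bias`` may be a
    single frozen bias potential or a sequence; each bias must act on the
    angle pair of one of the surfaces. The chain targets
    ``exp(-[U_surface + U_bias]/kB T)``; when biases are supplied the summed
    bias energy is recorded for every saved frame. Identical seed and config
    give a bit-identical trajectory.
    """
    surfaces = _normalize_surfaces(surface)
    names: list[str] = []
    for s in surfaces:
        for n in s.angle_names:
            if n in names:
                raise ValueError(f"duplicate angle name {n!r} across surfaces")
            names.append(n)

    biases = []
    if bias is not None:
        biases = [bias] if not isinstance(bias, (list, tuple)) else list(bias)
        for b in biases:
            if b.angle_pair[0] not in names or b.angle_pair[1] not in names:
                raise ValueError(f"bias pair {b.angle_pair} not among sampled angles")
        pairs = [tuple(b.angle_pair) for b in biases]
        flat = [a for p in pairs for a in p]
        if len(set(flat)) != len(flat):
            raise ValueError("bias potentials must act on disjoint angle pairs")

    surf_idx = [
        (_surface_params(s), s.offset, names.index(s.angle_names[0]), names.index(s.angle_names[1]))
        for s in surfaces
    ]
    bias_idx = [
        (b, names.index(b.angle_pair[0]), names.index(b.angle_pair[1])) for b in biases
    ]

    def total_energy(x):
        e = 0.0
        for params, off, i, j in surf_idx:
            e += _fast_energy(params, off, x[i], x[j])
        for b, i, j in bias_idx:
            e += b.energy(x[i], x[j])
        return e

    def bias_only(x):
        return sum(b.energy(x[i], x[j]) for b, i, j in bias_idx)

    rng = np.random.default_rng(config.seed)
    beta = 1.0 / (KB * config.temperature)
    x = wrap_angle(rng.uniform(-180.0, 180.0, size=len(names)))
    e = total_energy(x)
    if not np.isfinite(e):
        raise FloatingPointError("non-finite energy at sampler start")

    n_saved = config.n_steps // config.record_every
    frames = np.empty((n_saved, len(names)))
    bias_e = np.empty(n_saved) if biases else None
    k = 0
    # pre-drawn random streams keep the chain sequential but cheap per step
    chunk = 65536
    for start in range(0, config.n_steps, chunk):
        m = min(chunk, config.n_steps - start)
        moves = rng.uniform(-config.step_size, config.step_size, size=(m, len(names)))
        accept_u = rng.random(m)
        for t in range(m):
            step = start + t + 1
            prop = (x + moves[t] + 180.0) % 360.0 - 180.0
            e_prop = total_energy(prop)
            if not np.isfinite(e_prop):
                raise FloatingPointError(f"non-finite energy at step {step}")
            if e_prop <= e or accept_u[t] < np.exp(-beta * (e_prop - e)):
                x, e = prop, e_prop
            if step % config.record_every == 0:
                frames[k] = x
                if bias_e is not None:
                    bias_e[k] = bias_only(x)
                k += 1
    times = config.dt_ps * config.record_every * np.arange(1, n_saved + 1)
    return DihedralTrajectory(tuple(names), frames, times, bias_e)


# --------------------------------------------------------------------------
# Cartesian model frames
# --------------------------------------------------------------------------

# Idealized internal coordinates (nm / deg); exact force-field values are out
# of scope, the builder only needs chemically sensible, self-consistent
# geometry with exactly reproducible named dihedrals.
_B_CC = 0.153
_B_CN = 0.147
_B_CO = 0.143
_B_C_DOUBLE_O = 0.123
_B_NH = 0.100
_TET = 109.471
_SP2 = 120.0


@dataclass
class CartesianFrame:
    """Atom names, elements, positions (nm) and bonds of a model glycopeptide."""

    names: list[str]
    elements: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int]] = field(default_factory=list)
    united_atoms: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if len(set(self.names)) != len(self.names):
            raise ValueError("atom names must be unique within a frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("positions must be finite")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def position(self, name: str) -> np.ndarray:
        return self.coords[self.index(name)]

    def bonded_to(self, name: str) -> list[str]:
        i = self.index(name)
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(self.names[b])
            elif b == i:
                out.append(self.names[a])
        return out

    def dihedral(self, a: str, b: str, c: str, d: str) -> float:
        return measure_dihedral(*(self.position(n) for n in (a, b, c, d)))

    def copy(self) -> "CartesianFrame":
        return CartesianFrame(
            list(self.names),
            list(self.elements),
            self.coords.copy(),
            list(self.bonds),
            set(self.united_atoms),
        )


# Template rows: (name, element, united, parents (p1, p2, p3), bond nm,
# angle deg, torsion) where torsion is a number or the name of a requested
# dihedral; the placed dihedral is name-p3-p2-p1. The first three atoms carry
# special placement. United-atom carbons have no explicit aliphatic H.
_PEPTIDE_CORE = [
    # acetyl cap: CM-CX(=OX)-N, then backbone N-CA-C(=O)-NT-CMT; trans amides
    ("CM", "C", True, None, None, None, None),
    ("CX", "C", False, ("CM",), _B_CC, None, None),
    ("OX", "O", False, ("CM", "CX"), _B_C_DOUBLE_O, _SP2, None),
    ("N", "N", False, ("OX", "CM", "CX"), _B_CN, _SP2, 180.0),
    ("H", "H", False, ("CM", "CX", "N"), _B_NH, _SP2, 0.0),
    ("CA", "C", True, ("CM", "CX", "N"), _B_CN, _SP2, 180.0),
    ("C", "C", False, ("CX", "N", "CA"), _B_CC, _TET, "phi_P"),
    ("O", "O", False, ("N", "CA", "C"), _B_C_DOUBLE_O, _SP2, "_psi_P_O"),
    ("NT", "N", False, ("N", "CA", "C"), _B_CN, _SP2, "psi_P"),
    ("HT", "H", False, ("CA", "C", "NT"), _B_NH, _SP2, 0.0),
    ("CMT", "C", True, ("CA", "C", "NT"), _B_CN, _SP2, 180.0),
    ("CB", "C", True, ("CX", "N", "CA"), _B_CC, _TET, "_cb_branch"),
]

# Sugar fragment attached at CB via O1: glycosidic O1-C1, ring-like C1
# substituents O5 and C2, N-acetyl N2-C7(=O7)-C8 on C2, hydroxyl O4-HO4.
_SUGAR_FRAGMENT = [
    ("O1", "O", False, ("N", "CA", "CB"), _B_CO, _TET, "chi_S"),
    ("C1", "C", True, ("CA", "CB", "O1"), _B_CO, _TET, "psi_S"),
    ("O5", "O", False, ("CB", "O1", "C1"), _B_CO, _TET, "phi_S"),
    ("C2", "C", True, ("CB", "O1", "C1"), _B_CC, _TET, "_c2_branch"),
    ("N2", "N", False, ("O1", "C1", "C2"), _B_CN, _TET, -60.0),
    ("C7", "C", False, ("C1", "C2", "N2"), _B_CN, _SP2, "theta_amide"),
    ("HN2", "H", False, ("C1", "C2", "N2"), _B_NH, _SP2, "_hn2"),
    ("O7", "O", False, ("C2", "N2", "C7"), _B_C_DOUBLE_O, _SP2, 0.0),
    ("C8", "C", True, ("C2", "N2", "C7"), _B_CC, _SP2, 180.0),
    ("O4", "O", False, ("O1", "C1", "C2"), _B_CO, _TET, 60.0),
    ("HO4", "H", False, ("C1", "C2", "O4"), _B_NH, _TET, 180.0),
]

_THR_METHYL = [("CG", "C", True, ("N", "CA", "CB"), _B_CC, _TET, "_cg_branch")]

_SER_OH = [
    ("OG", "O", False, ("N", "CA", "CB"), _B_CO, _TET, "chi_S"),
    ("HG", "H", False, ("CA", "CB", "OG"), _B_NH, _TET, 180.0),
]

TEMPLATES = {
    "ser_glyco": _PEPTIDE_CORE + _SUGAR_FRAGMENT,
    "thr_glyco": _PEPTIDE_CORE + _SUGAR_FRAGMENT + _THR_METHYL,
    "ser": _PEPTIDE_CORE + _SER_OH,
    "thr": _PEPTIDE_CORE + _SER_OH + _THR_METHYL,
}

#: angles every template accepts; unset ones default to these values
DEFAULT_DIHEDRALS = {
    "phi_P": -100.0,
    "psi_P": 140.0,
    "chi_S": 60.0,
    "phi_S": 60.0,
    "psi_S": 120.0,
    "theta_amide": 180.0,
}


def _resolve_torsion(spec, dihedrals):
    if isinstance(spec, str):
        if spec == "_psi_P_O":
            return wrap_angle(dihedrals["psi_P"] + 180.0)
        if spec == "_cb_branch":
            # CB is the other tetrahedral substituent of CA next to C
            return wrap_angle(dihedrals["phi_P"] + 120.0)
        if spec == "_c2_branch":
            return wrap_angle(dihedrals["phi_S"] - 120.0)
        if spec == "_hn2":
            # amide H anti to the acetyl carbon across N2
            return wrap_angle(dihedrals["theta_amide"] + 180.0)
        if spec == "_cg_branch":
            return wrap_angle(dihedrals["chi_S"] + 120.0)
        return dihedrals[spec]
    return float(spec)


def build_model_frame(
    dihedrals: Mapping[str, float], template: str = "ser_glyco"
) -> CartesianFrame:
    """Build a Cartesian model-glycopeptide frame with prescribed dihedrals.

    ``dihedrals`` maps names among ``phi_P, psi_P, chi_S, phi_S, psi_S,
    theta_amide`` to degree values; unspecified angles take
    :data:`DEFAULT_DIHEDRALS`. The construction is deterministic and the named
    dihedrals measured on the output reproduce the request to ~1e-6 deg.
    """
    if template not in TEMPLATES:
        raise KeyError(f"unknown template {template!r}")
    unknown = set(dihedrals) - set(DEFAULT_DIHEDRALS)
    if unknown:
        raise KeyError(f"unknown dihedral(s): {sorted(unknown)}")
    full = dict(DEFAULT_DIHEDRALS)
    full.update({k: float(v) for k, v in dihedrals.items()})

    rows = TEMPLATES[template]
    names, elements, coords = [], [], []
    united: set[str] = set()
    bonds: list[tuple[int, int]] = []
    pos: dict[str, np.ndarray] = {}
    for row in rows:
        name, element, is_united, parents, bond, angle, torsion = row
        if parents is None:
            p = np.zeros(3)
        elif len(parents) == 1:
            p = pos[parents[0]] + np.array([bond, 0.0, 0.0])
        elif len(parents) == 2:
            a, b = (pos[q] for q in parents)
            theta = np.radians(angle)
            p = b + bond * np.array([-np.cos(theta), np.sin(theta), 0.0])
        else:
            tor = _resolve_torsion(torsion, full)
            p = place_atom(*(pos[q] for q in parents), bond, angle, tor)
        pos[name] = p
        if parents is not None:
            # bonded to the last parent (the chain attachment point)
            bonds.append((names.index(parents[-1]), len(names)))
        names.append(name)
        elements.append(element)
        coords.append(p)
        if is_united:
            united.add(name)

    return CartesianFrame(names, elements, np.array(coords), bonds, united)


def _infer_bonds(frame: CartesianFrame) -> list[tuple[int, int]]:
    """Distance-based bond inference (deterministic, adequate for templates)."""
    n = len(frame.names)
    bonds = []
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(frame.coords[i] - frame.coords[j])
            is_h = "H" in (frame.elements[i], frame.elements[j])
            cutoff = 0.125 if is_h else 0.175
            if d < cutoff:
                bonds.append((i, j))
    return bonds


def sample_rotational_diffusion(
    d_r: float, dt_ps: float, n_steps: int, seed: int = 0
) -> np.ndarray:
    """Unit-vector time series under isotropic rotational diffusion.

    ``d_r`` is the rotational diffusion constant in 1/ps. Each step applies a
    small random rotation with per-axis angular variance ``2 d_r dt``; the
    order-2 Legendre autocorrelation of the result decays as exp(-6 d_r t).
    Returns an (n_steps, 3) array of unit vectors.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(2.0 * d_r * dt_ps)
    v = np.array([0.0, 0.0, 1.0])
    out = np.empty((n_steps, 3))
    for i in range(n_steps):
        rotvec = rng.normal(0.0, sigma, size=3)
        v = Rotation.from_rotvec(rotvec).apply(v)
        v /= np.linalg.norm(v)
        out[i] = v
    return out
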