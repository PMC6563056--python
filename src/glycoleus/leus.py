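"""Local-elevation bias build-up and frozen-bias umbrella sampling.

The biasing potential for a dihedral pair is a 2D grid of basis-function
weights: dihedral space is binned into ``n_bins`` bins per dimension
(36 by default, bin width and basis width sigma = 360/n_bins degrees) and each
local-elevation deposition adds a fixed increment ``c`` (0.005 kJ/mol by
default) to the weight of the currently occupied bin. The continuous bias
energy is the weight-scaled sum of wrapped Gaussian basis functions centred at
the bin centres, which is separable in the two angles and 360-degree periodic.

In the LE phase the bias grows while the walker explores; in the US phase the
accumulated potentials are frozen and sampling proceeds under them, recording
the total bias energy per saved frame so that ensemble averages can later be
reweighted to the unbiased ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from glycoleus.constants import KB
from glycoleus.toy_system import (
    AnalyticSurface,
    DihedralTrajectory,
    SamplerConfig,
    _fast_energy,
    _normalize_surfaces,
    _surface_params,
)


@dataclass
class BiasPotential:
    """Accumulated local-elevation biasing potential on one dihedral pair."""

    angle_pair: tuple[str, str]
    n_bins: int = 36
    increment_c: float = 0.005
    weights: np.ndarray = None
    visit_counts: np.ndarray = None
    #: if True, evaluate the bias as piecewise-constant over bins instead of
    #: the smooth wrapped-Gaussian interpolation (sensitivity variant)
    hard_binned: bool = False

    def __post_init__(self):
        self.angle_pair = tuple(self.angle_pair)
        if self.weights is None:
            self.weights = np.zeros((self.n_bins, self.n_bins))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        if self.visit_counts is None:
            self.visit_counts = np.zeros((self.n_bins, self.n_bins), dtype=np.int64)
        if self.weights.shape != (self.n_bins, self.n_bins):
            raise ValueError("weights shape must be (n_bins, n_bins)")
        if np.any(self.weights < 0):
            raise ValueError("bias weights must be nonnegative")
        self._centers = -180.0 + (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def sigma(self) -> float:
        """Basis-function width in degrees (= 360/n_bins)."""
        return 360.0 / self.n_bins

    @property
    def bin_width(self) -> float:
        return 360.0 / self.n_bins

    @property
    def n_depositions(self) -> int:
        return int(self.visit_counts.sum())

    def bin_of(self, phi: float, psi: float) -> tuple[int, int]:
        i = int((phi + 180.0) // self.bin_width) % self.n_bins
        j = int((psi + 180.0) // self.bin_width) % self.n_bins
        return i, j

    def _basis_1d(self, angle: float) -> np.ndarray:
        d = (angle - self._centers + 180.0) % 360.0 - 180.0
        return np.exp(-(d * d) / (2.0 * self.sigma**2))

    def energy(self, phi: float, psi: float) -> float:
        """Bias energy in kJ/mol at (phi, psi) degrees; periodic; >= 0."""
        if self.hard_binned:
            i, j = self.bin_of(float(phi), float(psi))
            return float(self.weights[i, j])
        f = self._basis_1d(float(phi))
        g = self._basis_1d(float(psi))
        return float(f @ self.weights @ g)

    def energy_grid(self, phi_vals, psi_vals) -> np.ndarray:
        """Bias energy on the outer grid of the given angle vectors."""
        phi_vals = np.atleast_1d(np.asarray(phi_vals, dtype=float))
        psi_vals = np.atleast_1d(np.asarray(psi_vals, dtype=float))
        if self.hard_binned:
            out = np.empty((len(phi_vals), len(psi_vals)))
            for a, p in enumerate(phi_vals):
                for b, q in enumerate(psi_vals):
                    i, j = self.bin_of(p, q)
                    out[a, b] = self.weights[i, j]
            return out
        dphi = (phi_vals[:, None] - self._centers[None, :] + 180.0) % 360.0 - 180.0
        dpsi = (psi_vals[:, None] - self._centers[None, :] + 180.0) % 360.0 - 180.0
        f = np.exp(-(dphi**2) / (2.0 * self.sigma**2))
        g = np.exp(-(dpsi**2) / (2.0 * self.sigma**2))
        return f @ self.weights @ g.T

    def deposit(self, phi: float, psi: float) -> None:
        i, j = self.bin_of(phi, psi)
        self.weights[i, j] += self.increment_c
        self.visit_counts[i, j] += 1

    def copy(self) -> "BiasPotential":
        return BiasPotential(
            self.angle_pair,
            self.n_bins,
            self.increment_c,
            self.weights.copy(),
            self.visit_counts.copy(),
            self.hard_binned,
        )


def bias_energy(bias: BiasPotential, phi, psi) -> float:
    """Functional alias for :meth:`BiasPotential.energy`."""
    return bias.energy(phi, psi)


@dataclass(frozen=True)
class LEUSSchedule:
    """Step counts and seeds for the two LEUS phases.

    ``deposit_every`` sets the LE deposition cadence in sampler steps (the
    build-up interval is a free choice of the scheme; one per step by default).
    """

    t_le: int
    t_us: int
    record_every: int = 10
    deposit_every: int = 1
    seed: int = 0
    temperature: float = 300.0
    step_size: float = 30.0
    dt_ps: float = 0.1

    def __post_init__(self):
        if self.t_le < 0:
            raise ValueError("t_le must be >= 0")
        if self.t_us <= 0:
            raise ValueError("t_us must be > 0")


def le_build(
    surface,
    proto: BiasPotential,
    schedule: LEUSSchedule,
) -> BiasPotential:
    """Local-elevation build-up: grow the bias while sampling under it.

    Runs a Metropolis chain on ``surface`` (a single :class:`AnalyticSurface`
    or a sequence over disjoint pairs) under the evolving bias; every
    ``deposit_every`` steps the increment is added to the weight of the bin
    currently occupied on the bias's angle pair. Returns the final, frozen
    potential. ``t_le == 0`` returns an untouched copy (valid no-op).
    """
    if np.any(proto.weights != 0):
        raise ValueError("le_build expects a zero-weight prototype bias")
    bias = proto.copy()
    surfaces = _normalize_surfaces(surface)
    names = [n for s in surfaces for n in s.angle_names]
    if bias.angle_pair[0] not in names or bias.angle_pair[1] not in names:
        raise ValueError(f"bias pair {bias.angle_pair} not among surface angles")
    if schedule.t_le == 0:
        return bias

    surf_idx = [
        (_surface_params(s), s.offset, names.index(s.angle_names[0]), names.index(s.angle_names[1]))
        for s in surfaces
    ]
    bi, bj = names.index(bias.angle_pair[0]), names.index(bias.angle_pair[1])

    def total_energy(x):
        e = bias.energy(x[bi], x[bj])
        for params, off, i, j in surf_idx:
            e += _fast_energy(params, off, x[i], x[j])
        return e

    rng = np.random.default_rng(schedule.seed)
    beta = 1.0 / (KB * schedule.temperature)
    x = (rng.uniform(-180.0, 180.0, size=len(names)) + 180.0) % 360.0 - 180.0
    e = total_energy(x)
    chunk = 65536
    for start in range(0, schedule.t_le, chunk):
        m = min(chunk, schedule.t_le - start)
        moves = rng.uniform(-schedule.step_size, schedule.step_size, size=(m, len(names)))
        accept_u = rng.random(m)
        for t in range(m):
            step = start + t + 1
            prop = (x + moves[t] + 180.0) % 360.0 - 180.0
            e_prop = total_energy(prop)
            if not np.isfinite(e_prop):
                raise FloatingPointError(f"non-finite energy at LE step {step}")
            if e_prop <= e or accept_u[t] < np.exp(-beta * (e_prop - e)):
                x, e = prop, e_prop
            if step % schedule.deposit_every == 0:
                i, j = bias.bin_of(x[bi], x[bj])
                bias.weights[i, j] += bias.increment_c
                bias.visit_counts[i, j] += 1
                # incremental update of the current-state energy: one basis term
                if bias.hard_binned:
                    e += bias.increment_c
                else:
                    e += bias.increment_c * (
                        bias._basis_1d(x[bi])[i] * bias._basis_1d(x[bj])[j]
                    )
    return bias


def us_sample(
    surface,
    biases,
    schedule: LEUSSchedule,
) -> DihedralTrajectory:
    """Umbrella-sampling phase under frozen local-elevation potentials.

    ``biases`` is one :class:`BiasPotential` or a sequence over disjoint angle
    pairs; the per-frame recorded ``bias_energy`` is the sum of all supplied
    potentials evaluated on their own pairs. Bias weights are never mutated.
    """
    from glycoleus.toy_system import sample_dihedrals

    if isinstance(biases, BiasPotential):
        biases = [biases]
    biases = list(biases)
    checksums = [b.weights.sum() for b in biases]
    config = SamplerConfig(
        n_steps=schedule.t_us,
        temperature=schedule.temperature,
        step_size=schedule.step_size,
        seed=schedule.seed + 1,
        record_every=schedule.record_every,
        dt_ps=schedule.dt_ps,
    )
    traj = sample_dihedrals(surface, config, bias=biases)
    for b, c in zip(biases, checksums):
        if b.weights.sum() != c:
            raise RuntimeError("bias weights mutated during US sampling")
    return traj
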