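"""Toy-system presets emulating the four model glycopeptides.

Each preset defines analytic free-energy-like surfaces over the three
dihedral pairs of a capped GalNAc-Ser/Thr glycopeptide: the glycosidic
linkage (phi_S, psi_S), the peptide backbone (phi_P, psi_P) and the side
chain / N-acetyl pair (chi_S, theta_amide). Basin placement follows the
qualitative conformational picture of mucin-type O-glycopeptides:

* alpha-linked sugars (systems 1, 2) prefer phi_S ~ +60 (g+, the exo-anomeric
  orientation); beta-linked ones (systems 3, 4) additionally populate
  phi_S ~ -60 (g-) as the lowest state;
* the backbone populates beta / polyproline-II basins with a minor
  alpha-helical basin (more pronounced for the beta-Thr analogue);
* chi_S populates the three staggered rotamers with Thr-like systems biased
  towards +60, and the N-acetyl amide dihedral stays near anti.

Well depths and widths are fixed package choices (kJ/mol, deg), not fits.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from glycoleus.constants import KB
from glycoleus.toy_system import AnalyticSurface, GaussianWell

#: basin split for the calibrated two-basin surface: basin A is the phi
#: window around the deep well at -60, basin B the complement (well at +100)
TWO_BASIN_SPLIT = (-160.0, 20.0)


def basin_delta_g(
    surface: AnalyticSurface,
    temperature: float = 300.0,
    split: tuple[float, float] = TWO_BASIN_SPLIT,
    spacing: float = 1.0,
) -> float:
    """Quadrature free-energy difference G(B) - G(A) between the two basins.

    Basin populations come from 1-degree-grid numerical integration of the
    Boltzmann factor; A is the phi window ``split``, B its complement.
    """
    g, dens = surface.boltzmann_grid(temperature, spacing)
    phi_marg = dens.sum(axis=1)
    in_a = (g >= split[0]) & (g < split[1])
    p_a, p_b = phi_marg[in_a].sum(), phi_marg[~in_a].sum()
    return float(-KB * temperature * np.log(p_b / p_a))


def two_basin_surface(
    delta_g: float = 3.0,
    temperature: float = 300.0,
    angle_names: tuple[str, str] = ("phi", "psi"),
) -> AnalyticSurface:
    """Two-basin surface calibrated so the quadrature basin ΔG equals ``delta_g``.

    The deep well sits at (-60, 0) with depth -12 kJ/mol; the minor well at
    (+100, 0) has its depth solved by root finding against the quadrature
    oracle. Deterministic; no sampling involved.
    """

    def make(minor_depth):
        return AnalyticSurface(
            (
                GaussianWell(-60.0, 0.0, -12.0, 30.0),
                GaussianWell(100.0, 0.0, minor_depth, 30.0),
            ),
            angle_names=angle_names,
        )

    depth = brentq(
        lambda d: basin_delta_g(make(d), temperature) - delta_g, -12.0, -0.5, xtol=1e-10
    )
    return make(depth)

GLYCO_TEMPLATES = {1: "ser_glyco", 2: "thr_glyco", 3: "ser_glyco", 4: "thr_glyco"}
SYSTEM_LABELS = {
    1: "alpha-GalNAc-Ser",
    2: "alpha-GalNAc-Thr",
    3: "beta-GalNAc-Ser",
    4: "beta-GalNAc-Thr",
}


def _backbone_surface(alpha_depth: float) -> AnalyticSurface:
    return AnalyticSurface(
        terms=(
            GaussianWell(-120.0, 150.0, -14.0, 35.0),   # beta
            GaussianWell(-70.0, 150.0, -15.0, 30.0),    # P_II
            GaussianWell(-70.0, -40.0, alpha_depth, 30.0),  # alpha_R
        ),
        angle_names=("phi_P", "psi_P"),
    )


def _sidechain_surface(plus_depth: float) -> AnalyticSurface:
    return AnalyticSurface(
        terms=(
            GaussianWell(60.0, 180.0, plus_depth, 30.0),
            GaussianWell(-60.0, 180.0, -10.0, 30.0),
            GaussianWell(180.0, 180.0, -10.0, 30.0),
        ),
        angle_names=("chi_S", "theta_amide"),
    )


def _glycosidic_surface(system: int) -> AnalyticSurface:
    if system in (1, 2):
        psi = 60.0 if system == 1 else 120.0
        terms = (
            GaussianWell(60.0, psi, -16.0, 35.0),
            GaussianWell(60.0, 180.0, -10.0, 35.0),
        )
    else:
        terms = (
            GaussianWell(-60.0, 120.0, -16.0, 35.0),
            GaussianWell(60.0, 120.0, -12.0, 35.0),
        )
    return AnalyticSurface(terms=terms, angle_names=("phi_S", "psi_S"))


def toy_surfaces(system: int) -> list[AnalyticSurface]:
    """The three analytic surfaces of one glycopeptide analogue (1-4)."""
    if system not in GLYCO_TEMPLATES:
        raise KeyError(f"unknown system {system!r}; choose 1-4")
    alpha_depth = -12.0 if system == 4 else -9.0
    chi_plus = -14.0 if system in (2, 4) else -11.0
    return [
        _glycosidic_surface(system),
        _backbone_surface(alpha_depth),
        _sidechain_surface(chi_plus),
    ]


#: NOE proton pairs measured per template (label -> atom pair)
NOE_PAIRS = {
    "ser_glyco": {
        "d(HT,H)": ("HT", "H"),
        "d(HA,HT)": ("HA", "HT"),
        "d(HA,H)": ("HA", "H"),
        "d(HT,HB1)": ("HT", "HB1"),
        "d(HT,HB2)": ("HT", "HB2"),
        "d(H1,HA)": ("H1", "HA"),
    },
    "thr_glyco": {
        "d(HT,H)": ("HT", "H"),
        "d(HA,HT)": ("HA", "HT"),
        "d(HA,H)": ("HA", "H"),
        "d(HT,HB)": ("HT", "HB"),
        "d(H,HB)": ("H", "HB"),
        "d(H,HN2)": ("H", "HN2"),
    },
}

#: hydrogen-bond donors (donor, hydrogen) and acceptors shared by the
#: glycopeptide templates
HBOND_DONORS = [("N", "H"), ("NT", "HT"), ("N2", "HN2"), ("O4", "HO4")]
HBOND_ACCEPTORS = ["O", "OX", "O5", "O7", "O1", "O4"]

#: Karplus presets evaluated per template
KARPLUS_BY_TEMPLATE = {
    "ser_glyco": ["3J_HN_HA", "3J_HN2_H2", "3J_HA_HB2_ser", "3J_HA_HB3_ser"],
    "thr_glyco": ["3J_HN_HA", "3J_HN2_H2", "3J_HA_HB_thr"],
    "ser": ["3J_HN_HA", "3J_HA_HB2_ser", "3J_HA_HB3_ser"],
    "thr": ["3J_HN_HA", "3J_HA_HB_thr"],
}
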