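"""End-to-end driver: toy sampling -> LE build -> US -> reweight -> observables.

The pipeline chains every stage of the analysis on one toy glycopeptide
analogue: local-elevation build-up on the configured dihedral pairs, frozen-
bias umbrella sampling, exponential reweighting to the unbiased ensemble,
free-energy maps, ensemble J-couplings, Cartesian model-frame reconstruction
for NOE distances, hydrogen bonds, clustering coverage and rotational
correlation, and a tabular report. Everything is deterministic given the
global seed, which is expanded by a fixed counter scheme so stages are
independently re-runnable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from glycoleus import io as gio
from glycoleus.conformation import (
    HBondCriterion,
    PropensityRegions,
    cluster_conformations,
    coverage_curves,
    detect_hbonds,
    phi_bin_preferences,
    propensities,
    rotational_tau,
)
from glycoleus.leus import BiasPotential, LEUSSchedule, le_build, us_sample
from glycoleus.nmr import (
    KARPLUS_PRESETS,
    VirtualSiteRule,
    distance_distribution,
    ensemble_j,
    noe_report,
    proton_distances,
)
from glycoleus.reweight import FrameWeights, compute_weights, free_energy_map
from glycoleus.systems import (
    GLYCO_TEMPLATES,
    HBOND_ACCEPTORS,
    HBOND_DONORS,
    KARPLUS_BY_TEMPLATE,
    NOE_PAIRS,
    toy_surfaces,
)
from glycoleus.toy_system import AnalyticSurface, build_model_frame

_SEED_MOD = 2**31


def stage_seed(global_seed: int, stage: int) -> int:
    """Deterministic per-stage seed: (global * 7919 + stage) mod 2^31."""
    return (int(global_seed) * 7919 + stage) % _SEED_MOD


#: virtual-site rules per template (united carbons -> constructed protons)
VIRTUAL_RULES = {
    "ser_glyco": [
        VirtualSiteRule("CA", "CH1", ("HA",)),
        VirtualSiteRule("CB", "CH2", ("HB1", "HB2")),
        VirtualSiteRule("C1", "CH1", ("H1",)),
        VirtualSiteRule("C2", "CH1", ("H2",)),
    ],
    "thr_glyco": [
        VirtualSiteRule("CA", "CH1", ("HA",)),
        VirtualSiteRule("CB", "CH1", ("HB",)),
        VirtualSiteRule("C1", "CH1", ("H1",)),
        VirtualSiteRule("C2", "CH1", ("H2",)),
        VirtualSiteRule("CG", "CH3", ("HG_pseudo",)),
    ],
}

#: clustering selections: peptide backbone plus sugar-fragment core
CLUSTER_FIT = ["N", "CA", "C", "O1", "C1", "O5", "C2"]

_SUGAR_ATOMS = ["O1", "C1", "O5", "C2", "N2", "C7", "O7", "C8", "O4"]


@dataclass
class PipelineConfig:
    """Configuration of one toy-glycopeptide pipeline run."""

    system: int = 1
    surfaces: Optional[list[AnalyticSurface]] = None
    biased_pairs: Sequence[tuple[str, str]] = (("phi_S", "psi_S"), ("phi_P", "psi_P"))
    t_le: int = 30000
    t_us: int = 100000
    record_every: int = 10
    seed: int = 0
    temperature: float = 300.0
    n_structure_frames: int = 200
    noe_bounds: Optional[dict[str, float]] = None
    outdir: Optional[Path] = None

    def resolve(self):
        surfaces = self.surfaces if self.surfaces is not None else toy_surfaces(self.system)
        template = GLYCO_TEMPLATES[self.system]
        if self.noe_bounds is None:
            from glycoleus.reference_data import load_reference_noe_table

            tbl = load_reference_noe_table()
            bounds = dict(
                zip(tbl.loc[tbl.system == self.system, "pair"],
                    tbl.loc[tbl.system == self.system, "exp_A"])
            )
        else:
            bounds = dict(self.noe_bounds)
        return surfaces, template, bounds


@dataclass
class RunReport:
    """All tables produced by one pipeline run."""

    system: int
    template: str
    trajectory: object
    weights: FrameWeights
    biases: list[BiasPotential]
    maps: dict[tuple[str, str], object]
    j_table: pd.DataFrame
    noe_table: pd.DataFrame
    hbonds: dict[str, float]
    propensity_table: pd.DataFrame
    cluster_coverage: dict[float, list[int]]
    n_clusters: int
    rotational: pd.DataFrame
    distance_distribution_HT_H: tuple
    flags: list[str] = field(default_factory=list)


def run_pipeline(config: PipelineConfig) -> RunReport:
    surfaces, template, bounds = config.resolve()
    flags = []

    # LE phase: grow one bias per configured pair, then freeze
    biases = []
    for k, pair in enumerate(config.biased_pairs):
        proto = BiasPotential(pair)
        sched = LEUSSchedule(
            t_le=config.t_le,
            t_us=config.t_us,
            record_every=config.record_every,
            seed=stage_seed(config.seed, k),
            temperature=config.temperature,
        )
        biases.append(le_build(surfaces, proto, sched))
    if config.t_le == 0:
        flags.append("t_le=0: biases are empty, sampling is unflattened")

    # US phase under frozen biases
    us_sched = LEUSSchedule(
        t_le=config.t_le,
        t_us=config.t_us,
        record_every=config.record_every,
        seed=stage_seed(config.seed, 100),
        temperature=config.temperature,
    )
    traj = us_sample(surfaces, biases, us_sched)
    weights = compute_weights(traj, config.temperature)

    maps = {
        tuple(pair): free_energy_map(traj, weights, pair) for pair in config.biased_pairs
    }

    # J couplings
    rows = []
    for preset in KARPLUS_BY_TEMPLATE[template]:
        rel = KARPLUS_PRESETS[preset]
        if rel.angle_name not in traj.angle_names:
            continue
        j, err = ensemble_j(traj, weights, rel)
        rows.append({"relation": preset, "J_Hz": j, "block_error_Hz": err})
    j_table = pd.DataFrame(rows)

    # Cartesian reconstruction on a uniform frame subsample
    n_sub = min(config.n_structure_frames, traj.n_frames)
    idx = np.linspace(0, traj.n_frames - 1, n_sub).round().astype(int)
    sub_w = FrameWeights(weights.weights[idx], config.temperature)
    frames = []
    for i in idx:
        dih = {
            name: traj.angles[i, c]
            for c, name in enumerate(traj.angle_names)
        }
        frames.append(build_model_frame(dih, template))

    rules = VIRTUAL_RULES[template]
    pairs = NOE_PAIRS[template]
    dists = proton_distances(frames, pairs, rules)
    records = noe_report(dists, {p: b for p, b in bounds.items() if p in dists}, sub_w)
    noe_table = pd.DataFrame(
        [
            {
                "pair": r.pair,
                "bound_A": r.bound_A,
                "computed_A": r.computed_A,
                "block_error_A": r.block_error_A,
                "violation_A": r.violation_A,
                "significant": r.significant,
            }
            for r in records
        ]
    )
    dist_hist = distance_distribution(dists["d(HT,H)"], sub_w)

    hbonds = detect_hbonds(
        frames, sub_w, HBOND_DONORS, HBOND_ACCEPTORS, HBondCriterion(), report_threshold=0.0
    )
    hbonds = {k: v for k, v in hbonds.items() if v >= 2.0}

    prop = propensities(traj, weights)
    prefs = phi_bin_preferences(traj, weights)
    propensity_table = pd.DataFrame(
        [
            {
                **prop,
                "phi_-180_-100_pct": prefs[0],
                "phi_-100_0_pct": prefs[1],
                "phi_0_180_pct": prefs[2],
            }
        ]
    )

    heavy = [n for n, e in zip(frames[0].names, frames[0].elements) if e != "H"]
    clustering = cluster_conformations(frames, CLUSTER_FIT, heavy, cutoff=0.1)
    coverage = coverage_curves(clustering, traj.times[idx])

    rot_rows = []
    sugar_idx = [frames[0].index(a) for a in _SUGAR_ATOMS if a in frames[0].names]
    coords = np.array([f.coords for f in frames])
    v1 = coords[:, sugar_idx].mean(axis=1) - coords[:, frames[0].index("CA")]
    v2 = coords[:, frames[0].index("C")] - coords[:, frames[0].index("N")]
    v3 = np.cross(v1, v2)
    dt = float(traj.times[idx][1] - traj.times[idx][0]) if n_sub > 1 else 1.0
    for label, v in (("CA->sugar", v1), ("N->C", v2), ("cross", v3)):
        try:
            fit = rotational_tau(v, dt_ps=dt)
        except ValueError:
            fit = None
        rot_rows.append(
            {
                "vector": label,
                "tau_ps": None if fit is None or not fit.resolvable else fit.tau_ps,
                "resolvable": bool(fit and fit.resolvable),
            }
        )
    rotational = pd.DataFrame(rot_rows)

    report = RunReport(
        system=config.system,
        template=template,
        trajectory=traj,
        weights=weights,
        biases=biases,
        maps=maps,
        j_table=j_table,
        noe_table=noe_table,
        hbonds=hbonds,
        propensity_table=propensity_table,
        cluster_coverage=coverage,
        n_clusters=clustering.n_clusters,
        rotational=rotational,
        distance_distribution_HT_H=dist_hist,
        flags=flags,
    )
    if config.outdir is not None:
        _write_report(report, traj, biases, maps, Path(config.outdir))
    return report


def _write_report(report: RunReport, traj, biases, maps, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    gio.write_trajectory(traj, outdir / "us_trajectory.tsv")
    for b in biases:
        gio.write_bias(b, outdir / f"bias_{b.angle_pair[0]}_{b.angle_pair[1]}.leus")
    for pair, fmap in maps.items():
        gio.write_map(fmap, outdir / f"map_{pair[0]}_{pair[1]}.txt")
    report.j_table.to_csv(outdir / "jcouplings.tsv", sep="\t", index=False)
    report.noe_table.to_csv(outdir / "noe.tsv", sep="\t", index=False)
    report.propensity_table.to_csv(outdir / "propensities.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"hbond": k, "occurrence_pct": v} for k, v in report.hbonds.items()]
    ).to_csv(outdir / "hbonds.tsv", sep="\t", index=False)
    pd.DataFrame(report.cluster_coverage).to_csv(
        outdir / "cluster_coverage.tsv", sep="\t", index=False
    )
    report.rotational.to_csv(outdir / "rotational.tsv", sep="\t", index=False)
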