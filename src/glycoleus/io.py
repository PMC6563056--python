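"""File formats: trajectories (TSV), bias potentials and free-energy maps
(matrix text), Cartesian frames (PDB via MDAnalysis), and YAML configs.

Angles are stored in degrees; trajectories read from disk are normalized to
the canonical [-180, 180) range (a note is logged when wrapping was needed).
PDB files are in Angstrom and converted to nm on read.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from glycoleus.geometry import wrap_angle
from glycoleus.leus import BiasPotential
from glycoleus.reweight import UNVISITED, FreeEnergyMap
from glycoleus.toy_system import (
    AnalyticSurface,
    CartesianFrame,
    DihedralTrajectory,
    GaussianWell,
    _infer_bonds,
)

logger = logging.getLogger("glycoleus")

_BIAS_COL = "bias_kJmol"


def write_trajectory(traj: DihedralTrajectory, path: Union[str, Path]) -> None:
    """Tab-separated text: header ``time_ps <angles...> [bias_kJmol]``, one frame/line."""
    cols = ["time_ps", *traj.angle_names]
    data = [traj.times, *(traj.angles[:, k] for k in range(len(traj.angle_names)))]
    if traj.bias_energy is not None:
        cols.append(_BIAS_COL)
        data.append(traj.bias_energy)
    arr = np.column_stack(data)
    np.savetxt(path, arr, delimiter="\t", header="\t".join(cols), comments="", fmt="%.10g")


def read_trajectory(path: Union[str, Path]) -> DihedralTrajectory:
    """Read a trajectory TSV; angles outside [-180, 180) are wrapped with a log note."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
    if not header or header[0] != "time_ps":
        raise ValueError(f"{path}: first column must be time_ps")
    try:
        arr = np.loadtxt(path, skiprows=1, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed data line ({exc})") from exc
    if arr.shape[1] != len(header):
        raise ValueError(f"{path}: column count does not match header")
    has_bias = header[-1] == _BIAS_COL
    angle_names = tuple(header[1 : len(header) - (1 if has_bias else 0)])
    angles = arr[:, 1 : 1 + len(angle_names)]
    if np.any(angles >= 180.0) or np.any(angles < -180.0):
        logger.info("%s: input angles outside [-180, 180) normalized to canonical range", path)
        angles = wrap_angle(angles)
    bias = arr[:, -1] if has_bias else None
    return DihedralTrajectory(angle_names, angles, arr[:, 0], bias)


def write_trajectory_h5(traj: DihedralTrajectory, path: Union[str, Path]) -> None:
    """Binary container variant for large runs (HDF5)."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["angle_names"] = list(traj.angle_names)
        h5.create_dataset("angles", data=traj.angles, compression="gzip")
        h5.create_dataset("times", data=traj.times)
        if traj.bias_energy is not None:
            h5.create_dataset("bias_energy", data=traj.bias_energy)


def read_trajectory_h5(path: Union[str, Path]) -> DihedralTrajectory:
    import h5py

    with h5py.File(path, "r") as h5:
        names = tuple(str(n) for n in h5.attrs["angle_names"])
        bias = h5["bias_energy"][:] if "bias_energy" in h5 else None
        return DihedralTrajectory(names, h5["angles"][:], h5["times"][:], bias)


def write_bias(bias: BiasPotential, path: Union[str, Path]) -> None:
    """Text serialization: metadata header plus the weight and count matrices."""
    with open(path, "w") as fh:
        fh.write(f"# angle_pair\t{bias.angle_pair[0]}\t{bias.angle_pair[1]}\n")
        fh.write(f"# n_bins\t{bias.n_bins}\n")
        fh.write(f"# sigma_deg\t{bias.sigma:.10g}\n")
        fh.write(f"# increment_c_kJmol\t{bias.increment_c:.10g}\n")
        fh.write(f"# n_depositions\t{bias.n_depositions}\n")
        fh.write(f"# hard_binned\t{int(bias.hard_binned)}\n")
        np.savetxt(fh, bias.weights, delimiter="\t", fmt="%.17g")
        fh.write("# visit_counts\n")
        np.savetxt(fh, bias.visit_counts, delimiter="\t", fmt="%d")


def read_bias(path: Union[str, Path]) -> BiasPotential:
    meta = {}
    rows: list[list[float]] = []
    counts: list[list[int]] = []
    target = rows
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if parts[0] == "visit_counts":
                    target = counts
                else:
                    meta[parts[0]] = parts[1:]
                continue
            target.append([float(x) for x in line.split("\t")])
    n_bins = int(meta["n_bins"][0])
    bias = BiasPotential(
        tuple(meta["angle_pair"]),
        n_bins=n_bins,
        increment_c=float(meta["increment_c_kJmol"][0]),
        weights=np.array(rows),
        visit_counts=np.array(counts, dtype=np.int64),
        hard_binned=bool(int(meta.get("hard_binned", ["0"])[0])),
    )
    return bias


_NA = "NA"


def write_map(fmap: FreeEnergyMap, path: Union[str, Path]) -> None:
    """Matrix text with header; never-visited bins exported as the NA sentinel."""
    with open(path, "w") as fh:
        fh.write(f"# angle_pair\t{fmap.angle_pair[0]}\t{fmap.angle_pair[1]}\n")
        fh.write(f"# n_bins\t{fmap.n_bins}\n")
        fh.write(f"# temperature_K\t{fmap.temperature:.10g}\n")
        fh.write(f"# contour_spacing_kJmol\t{fmap.contour_spacing:.10g}\n")
        for i in range(fmap.n_bins):
            cells = [
                f"{fmap.grid[i, j]:.10g}" if fmap.visited_mask[i, j] else _NA
                for j in range(fmap.n_bins)
            ]
            fh.write("\t".join(cells) + "\n")


def read_map(path: Union[str, Path]) -> FreeEnergyMap:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                meta[parts[0]] = parts[1:]
                continue
            rows.append([np.nan if c == _NA else float(c) for c in line.split("\t")])
    grid = np.array(rows)
    visited = ~np.isnan(grid)
    grid[~visited] = UNVISITED
    n_bins = int(meta["n_bins"][0])
    return FreeEnergyMap(
        tuple(meta["angle_pair"]),
        grid,
        visited,
        360.0 / n_bins,
        float(meta["temperature_K"][0]),
        float(meta["contour_spacing_kJmol"][0]),
    )


# --------------------------------------------------------------------------
# PDB frames via MDAnalysis
# --------------------------------------------------------------------------


def write_frames(frames: Sequence[CartesianFrame], path: Union[str, Path]) -> None:
    """Write frames as a multi-MODEL PDB (coordinates nm -> Angstrom).

    United-atom carbons carry no constructed-H records unless sites were
    placed beforehand; atom names are preserved verbatim.
    """
    import MDAnalysis as mda

    first = frames[0]
    n = len(first.names)
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("names", first.names)
    u.add_TopologyAttr("elements", first.elements)
    u.add_TopologyAttr("resnames", ["GPL"])
    u.add_TopologyAttr("resids", [1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n, multiframe=True) as pdb:
            for fr in frames:
                if fr.names != first.names:
                    raise ValueError("all frames must share the same atom list")
                u.atoms.positions = fr.coords * 10.0
                pdb.write(u.atoms)


def read_frames(path: Union[str, Path]) -> list[CartesianFrame]:
    """Read one CartesianFrame per PDB MODEL (Angstrom -> nm).

    Bonds are re-inferred from distances; united-atom carbons are flagged as
    those with no bonded hydrogen and fewer than four neighbours. Duplicate
    atom names within a model are rejected.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        names = [str(n) for n in u.atoms.names]
        if len(set(names)) != len(names):
            raise ValueError(f"{path}: duplicate atom names within a model")
        try:
            elements = [str(e).capitalize() for e in u.atoms.elements]
        except (AttributeError, mda.exceptions.NoDataError):
            elements = [n[0] for n in names]
        frames = []
        for _ in u.trajectory:
            fr = CartesianFrame(list(names), list(elements), u.atoms.positions / 10.0)
            fr.bonds = _infer_bonds(fr)
            fr.united_atoms = _flag_united(fr)
            frames.append(fr)
    return frames


def _flag_united(frame: CartesianFrame) -> set[str]:
    united = set()
    for i, (name, el) in enumerate(zip(frame.names, frame.elements)):
        if el != "C":
            continue
        neigh = frame.bonded_to(name)
        has_h = any(frame.elements[frame.index(n)] == "H" for n in neigh)
        if not has_h and len(neigh) < 4:
            united.add(name)
    return united


# --------------------------------------------------------------------------
# Config files
# --------------------------------------------------------------------------


def surface_from_dict(d: dict) -> AnalyticSurface:
    terms = tuple(
        GaussianWell(t["center_phi"], t["center_psi"], t["depth"], t["width"])
        for t in d.get("terms", [])
    )
    return AnalyticSurface(
        terms, d.get("offset", 0.0), tuple(d.get("angle_names", ("phi", "psi")))
    )


def surface_to_dict(s: AnalyticSurface) -> dict:
    return {
        "angle_names": list(s.angle_names),
        "offset": s.offset,
        "terms": [
            {
                "center_phi": t.center_phi,
                "center_psi": t.center_psi,
                "depth": t.depth,
                "width": t.width,
            }
            for t in s.terms
        ],
    }


def read_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_config(cfg: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
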