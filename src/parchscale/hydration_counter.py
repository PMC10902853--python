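"""Per-residue water counting over annealing trajectories.

For each protein residue and each trajectory frame, counts the distinct
water molecules whose counting site (the water oxygen by default) lies
within `d_water` of any atom of the residue. Distances use the minimum
image convention when periodic boundaries are on. A water near two
residues contributes to both residues' counts. The default cutoff,
0.315 nm, is the first hydration shell distance seen in protein-water
radial distribution functions; it is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Frame, ProteinStructure
from .system_builder import AnnealingSchedule

__all__ = [
    "CountParams",
    "WaterCountSeries",
    "count_waters_frame",
    "count_waters_trajectory",
    "read_count_table",
    "write_count_table",
]


@dataclass
class CountParams:
    """Water-counting parameters.

    d_water : cutoff distance, nm; a water counts for a residue when its
        counting site is <= d_water from any residue atom.
    use_pbc : apply the minimum image convention (requires a frame box).
    water_site : "oxygen" counts from the water oxygen; "any-atom" counts
        a water if any of its atoms is within the cutoff.
    method : "tree" (periodic KD-tree) or "brute" (all-pairs minimum
        image); both give identical counts.
    """

    d_water: float = 0.315
    use_pbc: bool = True
    water_site: str = "oxygen"
    method: str = "tree"

    def __post_init__(self):
        if self.d_water <= 0:
            raise ValueError("d_water must be positive")
        if self.water_site not in ("oxygen", "any-atom"):
            raise ValueError("water_site must be 'oxygen' or 'any-atom'")
        if self.method not in ("tree", "brute"):
            raise ValueError("method must be 'tree' or 'brute'")


@dataclass
class WaterCountSeries:
    """Ordered per-residue water counts w_i(t) along the annealing axis."""

    times_ps: np.ndarray  # (n_frames,)
    counts: np.ndarray  # (n_residues, n_frames), non-negative ints
    temperatures_K: Optional[np.ndarray] = None
    residue_labels: Optional[list[str]] = None
    residue_names: Optional[list[str]] = None  # 3-letter codes, when known

    def __post_init__(self):
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (residues x frames)")
        if self.counts.shape[1] != self.times_ps.size:
            raise ValueError("counts frame axis must match times")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite and non-negative")
        if self.times_ps.size > 1 and np.any(np.diff(self.times_ps) <= 0):
            raise ValueError("times must strictly increase")
        if self.residue_labels is None:
            self.residue_labels = [f"res_{i + 1}" for i in range(self.counts.shape[0])]

    @property
    def n_residues(self) -> int:
        return self.counts.shape[0]

    @property
    def n_frames(self) -> int:
        return self.counts.shape[1]


def _water_sites(structure: ProteinStructure, coords: np.ndarray, params: CountParams):
    """(positions, molecule ids) for the counting sites of all waters."""
    pos, mol = [], []
    for res in structure.water_residues():
        for i in range(res.atom_span.start, res.atom_span.stop):
            atom = structure.atoms[i]
            if params.water_site == "oxygen" and atom.element.upper() != "O" \
                    and len(res.atom_span) > 1:
                continue
            pos.append(coords[i])
            mol.append(res.index)
    if not pos:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    return np.asarray(pos), np.asarray(mol, dtype=int)


def _residue_atom_indices(structure: ProteinStructure):
    return [np.arange(r.atom_span.start, r.atom_span.stop)
            for r in structure.protein_residues()]


def count_waters_frame(
    structure: ProteinStructure, frame: Frame, params: Optional[CountParams] = None
) -> np.ndarray:
    """Count waters within d_water of each protein residue in one frame."""
    params = params or CountParams()
    coords = np.asarray(frame.coordinates, dtype=float)
    if coords.shape[0] != structure.n_atoms:
        raise ValueError(
            f"frame has {coords.shape[0]} atoms but structure has {structure.n_atoms}"
        )
    box = frame.box if frame.box is not None else structure.box
    if params.use_pbc and box is None:
        raise ValueError("use_pbc requires a simulation box on the frame or structure")

    water_pos, water_mol = _water_sites(structure, coords, params)
    res_indices = _residue_atom_indices(structure)
    counts = np.zeros(len(res_indices), dtype=int)
    if water_pos.shape[0] == 0:
        return counts

    if params.method == "brute":
        return _count_brute(coords, res_indices, water_pos, water_mol, params,
                            box if params.use_pbc else None)

    if params.use_pbc:
        box = np.asarray(box, dtype=float)
        water_wrapped = np.mod(water_pos, box)
        tree = cKDTree(water_wrapped, boxsize=box)
        query = lambda pts: tree.query_ball_point(np.mod(pts, box), params.d_water)
    else:
        tree = cKDTree(water_pos)
        query = lambda pts: tree.query_ball_point(pts, params.d_water)

    for i, idx in enumerate(res_indices):
        hits = query(coords[idx])
        mols = {water_mol[j] for lst in hits for j in lst}
        counts[i] = len(mols)
    return counts


def _count_brute(coords, res_indices, water_pos, water_mol, params, box):
    """All-pairs minimum-image counting; the oracle for the tree path."""
    counts = np.zeros(len(res_indices), dtype=int)
    for i, idx in enumerate(res_indices):
        delta = water_pos[None, :, :] - coords[idx][:, None, :]
        if box is not None:
            delta -= np.round(delta / box) * box
        dist = np.sqrt((delta**2).sum(axis=2))
        near = (dist <= params.d_water).any(axis=0)
        counts[i] = len(set(water_mol[near]))
    return counts


def count_waters_trajectory(
    structure: ProteinStructure,
    frames: Iterable[Frame],
    params: Optional[CountParams] = None,
    schedule: Optional[AnnealingSchedule] = None,
) -> WaterCountSeries:
    """Stack per-frame counts into a :class:`WaterCountSeries`.

    When an annealing schedule is supplied, the temperature axis
    T(t) = t_start + rate * t is attached.
    """
    params = params or CountParams()
    times, columns = [], []
    for frame in frames:
        times.append(frame.time_ps)
        columns.append(count_waters_frame(structure, frame, params))
    if len(times) == 0:
        raise ValueError("trajectory has no frames")
    counts = np.stack(columns, axis=1)
    temps = schedule.temperature_at(np.asarray(times)) if schedule is not None else None
    protein = structure.protein_residues()
    labels = [f"res_{r.seq_number}" for r in protein]
    names = [r.name for r in protein]
    return WaterCountSeries(
        times_ps=np.asarray(times), counts=counts, temperatures_K=temps,
        residue_labels=labels, residue_names=names,
    )


def write_count_table(series: WaterCountSeries, path, header_comment: Optional[str] = None) -> None:
    """Write a count series as CSV: time_ps, temp_K, then one column per residue."""
    temp = (series.temperatures_K if series.temperatures_K is not None
            else np.full(series.n_frames, np.nan))
    data = {"time_ps": series.times_ps, "temp_K": temp}
    for label, row in zip(series.residue_labels, series.counts):
        data[label] = row
    df = pd.DataFrame(data)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_count_table(path) -> WaterCountSeries:
    """Read a CSV count table written by :func:`write_count_table`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed count table: {exc}") from exc
    if df.empty or "time_ps" not in df.columns:
        raise ValueError(f"{path}: empty or headerless count table")
    res_cols = [c for c in df.columns if c not in ("time_ps", "temp_K")]
    if not res_cols:
        raise ValueError(f"{path}: no residue columns")
    counts = df[res_cols].to_numpy().T
    if not np.all(np.isfinite(counts)):
        raise ValueError(f"{path}: non-finite water counts (ragged rows?)")
    temps = None
    if "temp_K" in df.columns and not df["temp_K"].isna().all():
        temps = df["temp_K"].to_numpy(dtype=float)
    return WaterCountSeries(
        times_ps=df["time_ps"].to_numpy(dtype=float),
        counts=counts.astype(int) if np.allclose(counts, np.round(counts)) else counts,
        temperatures_K=temps,
        residue_labels=res_cols,
    )
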