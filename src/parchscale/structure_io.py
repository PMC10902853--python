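"""Structure and trajectory I/O for the parch pipeline.

Reads and writes fixed-column PDB and GRO files, iterates multi-frame
trajectories lazily, and annotates structures with parch values through
the PDB occupancy column. All coordinates are held in nanometres
internally (GROMACS convention); PDB files are converted from/to
angstroms at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "Frame",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "write_parch_pdb",
    "write_parch_table",
    "read_frames",
    "write_frames",
    "register_frame_reader",
]

#: residue names recognised as water (configurable via read_structure)
WATER_RESNAMES = frozenset({"HOH", "SOL", "TIP3", "WAT"})
#: residue names recognised as monatomic ions
ION_RESNAMES = frozenset({"NA", "CL", "NA+", "CL-", "SOD", "CLA", "K", "POT"})

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

ANGSTROM_PER_NM = 10.0


class StructureParseError(ValueError):
    """Raised when a structure or trajectory file is malformed."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_index: int
    coordinates: np.ndarray  # shape (3,), nm
    occupancy: float = 1.0
    b_factor: float = 0.0


@dataclass
class Residue:
    index: int
    name: str
    chain_id: str
    seq_number: int
    atom_span: range
    kind: str = "protein"  # protein | water | ion
    standard: bool = True


@dataclass
class ProteinStructure:
    atoms: list[Atom]
    residues: list[Residue]
    box: Optional[np.ndarray] = None  # (3,) edge lengths, nm

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        """All atom coordinates as an (n_atoms, 3) array in nm."""
        return np.array([a.coordinates for a in self.atoms], dtype=float).reshape(-1, 3)

    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.kind == "protein"]

    def water_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.kind == "water"]

    def ion_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.kind == "ion"]


@dataclass
class Frame:
    time_ps: float
    coordinates: np.ndarray  # (n_atoms, 3), nm
    box: Optional[np.ndarray] = None  # (3,), nm


def _classify(resname: str, water_names: frozenset, ion_names: frozenset) -> tuple[str, bool]:
    up = resname.upper()
    if up in water_names:
        return "water", True
    if up in ion_names:
        return "ion", True
    return "protein", up in STANDARD_AA


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "NA", "MG", "ZN", "FE", "BR"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


# ---------------------------------------------------------------------------
# readers


def read_structure(
    path,
    format: Optional[str] = None,
    water_names: Iterable[str] = WATER_RESNAMES,
    ion_names: Iterable[str] = ION_RESNAMES,
) -> ProteinStructure:
    """Read a PDB or GRO file into a :class:`ProteinStructure`.

    Water and ion residues are tagged by residue name; everything else is
    treated as protein (non-standard names are retained with a warning).
    PDB coordinates (angstrom) are converted to nm; GRO files are already nm.

    Parameters
    ----------
    path : str or Path
    format : {"pdb", "gro"}, optional
        Inferred from the file suffix when omitted.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    water_names = frozenset(n.upper() for n in water_names)
    ion_names = frozenset(n.upper() for n in ion_names)
    if fmt == "pdb":
        return _read_pdb(path, water_names, ion_names)
    if fmt == "gro":
        return _read_gro(path, water_names, ion_names)
    raise ValueError(f"unsupported structure format: {fmt!r}")


def _finish_structure(raw_atoms, box) -> ProteinStructure:
    """Group parsed (resname, chain, resseq, atom) records into residues."""
    atoms: list[Atom] = []
    residues: list[Residue] = []
    current_key = None
    for resname, chain, resseq, kind, standard, atom in raw_atoms:
        key = (resname, chain, resseq)
        if key != current_key:
            start = len(atoms)
            residues.append(
                Residue(
                    index=len(residues),
                    name=resname,
                    chain_id=chain,
                    seq_number=resseq,
                    atom_span=range(start, start),
                    kind=kind,
                    standard=standard,
                )
            )
            current_key = key
        atom.residue_index = len(residues) - 1
        atoms.append(atom)
        res = residues[-1]
        res.atom_span = range(res.atom_span.start, len(atoms))
    return ProteinStructure(atoms=atoms, residues=residues, box=box)


def _read_pdb(path: Path, water_names, ion_names) -> ProteinStructure:
    raw = []
    box = None
    seen_endmdl = False
    warned_altloc = False
    warned_nonstd: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    box = np.array(
                        [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                    ) / ANGSTROM_PER_NM
                except ValueError as exc:
                    raise StructureParseError(
                        f"{path}:{lineno}: malformed CRYST1 record"
                    ) from exc
            elif rec == "ENDMDL":
                if not seen_endmdl:
                    seen_endmdl = True
            elif rec in ("ATOM  ", "HETATM"):
                if seen_endmdl:
                    continue  # first model only
                altloc = line[16]
                if altloc not in (" ", "A"):
                    if not warned_altloc:
                        warnings.warn(
                            f"{path}: dropping alternate locations other than 'A'"
                        )
                        warned_altloc = True
                    continue
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    resname = line[17:20].strip()
                    chain = line[21] if line[21] != " " else "A"
                    resseq = int(line[22:26])
                    xyz = np.array(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    ) / ANGSTROM_PER_NM
                    occ = float(line[54:60]) if line[54:60].strip() else 1.0
                    bf = float(line[60:66]) if line[60:66].strip() else 0.0
                except (ValueError, IndexError) as exc:
                    raise StructureParseError(
                        f"{path}:{lineno}: malformed {rec.strip()} record"
                    ) from exc
                element = line[76:78].strip() or _element_from_name(name)
                kind, standard = _classify(resname, water_names, ion_names)
                if kind == "protein" and not standard and resname not in warned_nonstd:
                    warnings.warn(f"{path}: non-standard residue name {resname!r} retained")
                    warned_nonstd.add(resname)
                raw.append(
                    (resname, chain, resseq, kind, standard,
                     Atom(serial, name, element, -1, xyz, occ, bf))
                )
    if seen_endmdl:
        warnings.warn(f"{path}: multi-model file; only the first model was read")
    return _finish_structure(raw, box)


def _read_gro(path: Path, water_names, ion_names) -> ProteinStructure:
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 3:
        raise StructureParseError(f"{path}:1: GRO file too short")
    try:
        n_atoms = int(lines[1])
    except ValueError as exc:
        raise StructureParseError(f"{path}:2: malformed atom count") from exc
    if len(lines) < n_atoms + 3:
        raise StructureParseError(f"{path}:{len(lines)}: truncated GRO file")
    raw = []
    warned_nonstd: set[str] = set()
    for i in range(n_atoms):
        lineno = i + 3
        line = lines[2 + i]
        try:
            resseq = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            serial = int(line[15:20])
            xyz = np.array([float(line[20:28]), float(line[28:36]), float(line[36:44])])
        except (ValueError, IndexError) as exc:
            raise StructureParseError(f"{path}:{lineno}: malformed GRO atom line") from exc
        kind, standard = _classify(resname, water_names, ion_names)
        if kind == "protein" and not standard and resname not in warned_nonstd:
            warnings.warn(f"{path}: non-standard residue name {resname!r} retained")
            warned_nonstd.add(resname)
        raw.append(
            (resname, "A", resseq, kind, standard,
             Atom(serial, name, _element_from_name(name), -1, xyz))
        )
    box_fields = lines[2 + n_atoms].split()
    box = np.array([float(v) for v in box_fields[:3]]) if len(box_fields) >= 3 else None
    return _finish_structure(raw, box)


# ---------------------------------------------------------------------------
# writers


def _pdb_atom_line(atom: Atom, res: Residue, occupancy: float) -> str:
    xyz = atom.coordinates * ANGSTROM_PER_NM
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    occ = min(max(occupancy, 0.0), 999.99)
    return (
        f"ATOM  {atom.serial % 100000:5d} {name:<4.4s} {res.name:<3.3s} {res.chain_id}"
        f"{res.seq_number % 10000:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{atom.b_factor:6.2f}"
        f"          {atom.element:>2.2s}\n"
    )


def write_structure(structure: ProteinStructure, path, format: Optional[str] = None) -> None:
    """Write a structure as PDB (angstrom) or GRO (nm), by suffix or `format`."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        with open(path, "w") as fh:
            if structure.box is not None:
                b = structure.box * ANGSTROM_PER_NM
                fh.write(
                    f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
                    f"  90.00  90.00  90.00 P 1           1\n"
                )
            for atom in structure.atoms:
                res = structure.residues[atom.residue_index]
                fh.write(_pdb_atom_line(atom, res, atom.occupancy))
            fh.write("END\n")
    elif fmt == "gro":
        with open(path, "w") as fh:
            _write_gro_block(fh, structure, title="parchscale structure", time_ps=None)
    else:
        raise ValueError(f"unsupported structure format: {fmt!r}")


def _write_gro_block(fh, structure: ProteinStructure, title: str, time_ps: Optional[float],
                     coordinates: Optional[np.ndarray] = None) -> None:
    if time_ps is not None:
        title = f"{title} t= {time_ps:.3f}"
    fh.write(title + "\n")
    fh.write(f"{structure.n_atoms:5d}\n")
    coords = structure.coordinates() if coordinates is None else coordinates
    for atom, xyz in zip(structure.atoms, coords):
        res = structure.residues[atom.residue_index]
        fh.write(
            f"{res.seq_number % 100000:5d}{res.name:<5.5s}{atom.name:>5.5s}"
            f"{atom.serial % 100000:5d}{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}\n"
        )
    box = structure.box if structure.box is not None else np.zeros(3)
    fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")


def write_parch_table(structure: ProteinStructure, result, path) -> None:
    """Write the per-residue parch table: chain resSeq resName cbar parch."""
    with open(path, "w") as fh:
        fh.write("# chain resSeq resName cbar parch_value\n")
        for res, cbar, pv in zip(
            structure.protein_residues(), result.cbar, result.parch_values
        ):
            fh.write(f"{res.chain_id} {res.seq_number} {res.name} {cbar:.6f} {pv:.4f}\n")


def write_parch_pdb(structure: ProteinStructure, result, path, table_path=None) -> None:
    """Write a PDB with parch values in the occupancy column (cols 55-60).

    Every atom of a protein residue carries that residue's parch value to
    2 decimals; water and ion atoms get occupancy 0.00. A companion text
    table (chain, seq number, residue name, mean autocorrelation, parch
    value) is written next to it.
    """
    path = Path(path)
    protein = structure.protein_residues()
    if len(result.parch_values) != len(protein):
        raise ValueError(
            f"result covers {len(result.parch_values)} residues but structure has "
            f"{len(protein)} protein residues"
        )
    pv_by_residue = {res.index: pv for res, pv in zip(protein, result.parch_values)}
    if any(pv > 999.99 for pv in result.parch_values):
        warnings.warn("parch value exceeds PDB occupancy field width; clamped to 999.99")
    with open(path, "w") as fh:
        if structure.box is not None:
            b = structure.box * ANGSTROM_PER_NM
            fh.write(
                f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
                f"  90.00  90.00  90.00 P 1           1\n"
            )
        for atom in structure.atoms:
            res = structure.residues[atom.residue_index]
            occ = pv_by_residue.get(res.index, 0.0)
            fh.write(_pdb_atom_line(atom, res, occ))
        fh.write("END\n")
    table = Path(table_path) if table_path is not None else path.with_suffix(".parch.txt")
    write_parch_table(structure, result, table)


# ---------------------------------------------------------------------------
# trajectories

_FRAME_READERS: dict[str, Callable[..., Iterator[Frame]]] = {}


def register_frame_reader(name: str, reader: Callable[..., Iterator[Frame]]) -> None:
    """Register a trajectory backend.

    `reader(path)` must yield :class:`Frame` objects in file order. This is
    the adapter hook for binary trajectory formats (XTC/DCD readers from
    MDAnalysis or mdtraj can be wrapped here) without changing any
    downstream code.
    """
    _FRAME_READERS[name] = reader


def read_frames(path, format: Optional[str] = None) -> Iterator[Frame]:
    """Lazily yield trajectory frames from a multi-frame GRO or PDB file.

    Frames must share an atom count and have strictly increasing times;
    violations raise before any downstream statistic sees the frame.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt in ("gro", "multi-gro"):
        gen = _iter_gro_frames(path)
    elif fmt in ("pdb", "multi-pdb"):
        gen = _iter_pdb_frames(path)
    elif fmt in _FRAME_READERS:
        gen = _FRAME_READERS[fmt](path)
    else:
        raise ValueError(f"unsupported trajectory format: {fmt!r}")
    return _validate_frames(gen, path)


def _validate_frames(gen: Iterable[Frame], path) -> Iterator[Frame]:
    n_atoms = None
    last_t = None
    for i, frame in enumerate(gen):
        if n_atoms is None:
            n_atoms = len(frame.coordinates)
        elif len(frame.coordinates) != n_atoms:
            raise StructureParseError(
                f"{path}: frame {i} has {len(frame.coordinates)} atoms, expected {n_atoms}"
            )
        if last_t is not None and frame.time_ps <= last_t:
            raise StructureParseError(
                f"{path}: frame times must strictly increase "
                f"({frame.time_ps} ps after {last_t} ps)"
            )
        last_t = frame.time_ps
        yield frame


def _title_time(title: str, default: float) -> float:
    if "t=" in title:
        try:
            return float(title.split("t=")[1].split()[0])
        except (ValueError, IndexError):
            pass
    return default


def _iter_gro_frames(path: Path) -> Iterator[Frame]:
    with open(path) as fh:
        index = 0
        while True:
            title = fh.readline()
            if not title:
                return
            if not title.strip():
                continue
            count_line = fh.readline()
            try:
                n = int(count_line)
            except ValueError as exc:
                raise StructureParseError(
                    f"{path}: malformed frame atom count {count_line!r}"
                ) from exc
            coords = np.empty((n, 3))
            for i in range(n):
                line = fh.readline()
                try:
                    coords[i] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
                except (ValueError, IndexError) as exc:
                    raise StructureParseError(
                        f"{path}: malformed atom line in frame {index}"
                    ) from exc
            box_fields = fh.readline().split()
            box = np.array([float(v) for v in box_fields[:3]]) if len(box_fields) >= 3 else None
            yield Frame(time_ps=_title_time(title, float(index)), coordinates=coords, box=box)
            index += 1


def _iter_pdb_frames(path: Path) -> Iterator[Frame]:
    coords: list[list[float]] = []
    box = None
    index = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "CRYST1":
                box = np.array(
                    [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                ) / ANGSTROM_PER_NM
            elif rec.startswith("MODEL"):
                in_model, saw_model, coords = True, True, []
            elif rec in ("ATOM  ", "HETATM"):
                coords.append(
                    [float(line[30:38]) / 10, float(line[38:46]) / 10, float(line[46:54]) / 10]
                )
            elif rec == "ENDMDL":
                yield Frame(time_ps=float(index), coordinates=np.array(coords), box=box)
                index += 1
                in_model, coords = False, []
    if coords and not saw_model:
        yield Frame(time_ps=0.0, coordinates=np.array(coords), box=box)


def write_frames(structure: ProteinStructure, frames: Iterable[Frame], path,
                 title: str = "parchscale trajectory") -> None:
    """Write frames as a concatenated multi-frame GRO trajectory."""
    with open(path, "w") as fh:
        for frame in frames:
            box = frame.box if frame.box is not None else structure.box
            snapshot = ProteinStructure(structure.atoms, structure.residues, box)
            _write_gro_block(fh, snapshot, title, frame.time_ps, coordinates=frame.coordinates)
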