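"""Topology and trajectory input/output.

Internal conventions: coordinates in Angstrom, time in picoseconds, masses in
amu.  Multi-model PDB files are parsed natively; DCD and XTC go through
MDAnalysis' coordinate readers (which already deliver Angstrom).

Role flags are inferred from atom/residue names by the rule table documented
in :data:`ROLE_RULES` below.  Topologies built programmatically (e.g. by the
synthetic generator) may set flags directly and bypass inference.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    FormatError,
    ShapeError,
    UnsupportedFormatError,
)

ROLE_NAMES = (
    "alpha_carbon",
    "backbone",
    "ligand",
    "water",
    "apolar_carbon",
    "hbond_donor_heavy",
    "hbond_acceptor",
    "charged_positive",
    "charged_negative",
)

WATER_RESNAMES = {"HOH", "WAT", "TIP3", "TIP3P", "SPC", "T3P", "SOL"}

#: Name-based chemistry dictionary.  The rules are deliberately simple and
#: fully overridable by constructing a Topology with explicit flags:
#:
#: ======================  =====================================================
#: flag                    rule
#: ======================  =====================================================
#: water                   residue name in WATER_RESNAMES
#: ligand                  HETATM record that is not water
#: alpha_carbon            atom name ``CA`` on a non-ligand, non-water residue
#: backbone                atom name in {N, CA, C, O, OXT} on a protein residue
#: hbond_acceptor          element N or O
#: hbond_donor_heavy       element N; or hydroxyl/water oxygen
#:                         (names OG, OG1, OH, OW or water O)
#: charged_positive        LYS NZ, ARG NH1/NH2, or any ligand nitrogen
#: charged_negative        ASP OD1/OD2, GLU OE1/OE2, OXT, or ligand O1/O2
#: apolar_carbon           carbon whose name is not ``C`` or ``CA``
#:                         (side-chain carbons), or any ligand carbon named
#:                         ``C*`` other than the carboxyl ``C``
#: ======================  =====================================================
ROLE_RULES = "see module docstring table"

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}
_HYDROXYL_O = {"OG", "OG1", "OH", "OW"}
_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "ZN": 65.38, "FE": 55.845,
}


@dataclasses.dataclass
class Topology:
    """Per-atom static description of a system.

    Parallel arrays indexed by 0-based atom position; serial numbers are
    1-based and contiguous.  ``flags`` maps each role name to a boolean array.
    """

    names: np.ndarray            # str per atom
    elements: np.ndarray         # str per atom
    resids: np.ndarray           # int, 1-based, taken verbatim from source
    resnames: np.ndarray         # str
    chains: np.ndarray           # str
    masses: np.ndarray           # float, amu
    flags: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.names)
        for arr in (self.elements, self.resids, self.resnames, self.chains, self.masses):
            if len(arr) != n:
                raise ShapeError("topology arrays have inconsistent lengths")
        if n and np.any(np.asarray(self.masses) <= 0):
            raise ValueError("all atom masses must be positive")
        for role in ROLE_NAMES:
            self.flags.setdefault(role, np.zeros(n, dtype=bool))

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def flag(self, role: str) -> np.ndarray:
        return self.flags[role]

    def residue_numbers(self) -> np.ndarray:
        """Unique residue numbers of non-water, non-ligand residues, in order."""
        mask = ~(self.flags["water"] | self.flags["ligand"])
        seen, out = set(), []
        for r in self.resids[mask]:
            if r not in seen:
                seen.add(r)
                out.append(r)
        return np.asarray(out, dtype=int)


@dataclasses.dataclass
class Ensemble:
    """A stack of F frames of N atoms with replicate provenance.

    ``replicate_boundaries`` lists the frame index at which each source
    replicate starts (always beginning with 0).
    """

    coordinates: np.ndarray                  # (F, N, 3), Angstrom
    frame_interval: float = 100.0            # ps between saved frames
    replicate_boundaries: tuple[int, ...] = (0,)
    system_label: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ShapeError(
                f"coordinates must be (F, N, 3), got {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] < 1:
            raise ShapeError("ensemble needs at least one frame")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        b = tuple(self.replicate_boundaries)
        if b[0] != 0 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("replicate boundaries must start at 0 and strictly increase")
        if b[-1] >= self.n_frames and self.n_frames > 0 and b != (0,):
            raise ValueError("replicate boundary beyond last frame")
        self.replicate_boundaries = b

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def split(self) -> list["Ensemble"]:
        """Undo :func:`concatenate`: one ensemble per replicate."""
        edges = list(self.replicate_boundaries) + [self.n_frames]
        return [
            Ensemble(
                self.coordinates[a:b].copy(),
                frame_interval=self.frame_interval,
                system_label=self.system_label,
            )
            for a, b in zip(edges[:-1], edges[1:])
        ]


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "C"
    if stripped[0] == "H":
        return "H"
    if len(stripped) >= 2 and stripped[:2].upper() in _MASSES and stripped[:2].upper() not in ("CA", "NA"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _infer_flags(names, elements, resnames, hetatm) -> dict[str, np.ndarray]:
    n = len(names)
    f = {role: np.zeros(n, dtype=bool) for role in ROLE_NAMES}
    for i in range(n):
        name, elem, resn = names[i].strip(), elements[i].upper(), resnames[i].strip()
        water = resn in WATER_RESNAMES
        ligand = bool(hetatm[i]) and not water
        protein = not water and not ligand
        f["water"][i] = water
        f["ligand"][i] = ligand
        f["alpha_carbon"][i] = protein and name == "CA"
        f["backbone"][i] = protein and name in _BACKBONE_NAMES
        f["hbond_acceptor"][i] = elem in ("N", "O")
        f["hbond_donor_heavy"][i] = elem == "N" or (
            elem == "O" and (name in _HYDROXYL_O or water)
        )
        f["charged_positive"][i] = (
            (resn == "LYS" and name == "NZ")
            or (resn == "ARG" and name in ("NH1", "NH2"))
            or (ligand and elem == "N")
        )
        f["charged_negative"][i] = (
            (resn == "ASP" and name in ("OD1", "OD2"))
            or (resn == "GLU" and name in ("OE1", "OE2"))
            or name == "OXT"
            or (ligand and name in ("O1", "O2"))
        )
        f["apolar_carbon"][i] = elem == "C" and name not in ("C", "CA") or (
            ligand and elem == "C" and name != "C"
        )
    return f


def _parse_pdb_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        resname = line[17:21].strip()
        chain = line[21].strip() or "A"
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"unparseable PDB record at line {lineno}: {line.rstrip()!r}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _element_from_name(name)
    return name, resname, chain, resid, (x, y, z), element.upper()


def read_topology(path: str | Path) -> Topology:
    """Read a PDB file's first model into a :class:`Topology`.

    Raises :class:`FormatError` naming the line number on a malformed record
    and :class:`EmptyInputError` if the file holds no atoms.
    """
    names, elements, resids, resnames, chains, hetatm = [], [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "ENDMDL":
                break  # topology comes from the first model only
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise FormatError(f"truncated PDB record at line {lineno}")
            name, resn, chain, resid, _, elem = _parse_pdb_atom_line(line, lineno)
            names.append(name)
            elements.append(elem)
            resids.append(resid)
            resnames.append(resn)
            chains.append(chain)
            hetatm.append(rec == "HETATM")
    if not names:
        raise EmptyInputError(f"no ATOM/HETATM records in {path}")
    elements_arr = np.asarray(elements, dtype=object)
    masses = np.array([_MASSES.get(e.upper(), 12.011) for e in elements], dtype=float)
    flags = _infer_flags(names, elements, resnames, hetatm)
    return Topology(
        names=np.asarray(names, dtype=object),
        elements=elements_arr,
        resids=np.asarray(resids, dtype=int),
        resnames=np.asarray(resnames, dtype=object),
        chains=np.asarray(chains, dtype=object),
        masses=masses,
        flags=flags,
    )


def _read_pdb_frames(path: str | Path, n_atoms_expected: int | None) -> np.ndarray:
    frames: list[list] = []
    current: list | None = None
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                current = []
            elif rec == "ENDMDL":
                if current:
                    frames.append(current)
                current = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    if saw_model:
                        continue  # stray atoms between models
                    current = []
                *_ignored, xyz, _e = _parse_pdb_atom_line(line, lineno)
                current.append(xyz)
    if current:
        frames.append(current)
    if not frames:
        raise EmptyInputError(f"no coordinates in {path}")
    counts = {len(f) for f in frames}
    if len(counts) != 1:
        raise ShapeError(f"models in {path} have differing atom counts: {sorted(counts)}")
    return np.asarray(frames, dtype=float)


def read_trajectory(
    path: str | Path,
    topology: Topology,
    fmt: str | None = None,
    frame_interval: float = 100.0,
    system_label: str = "",
) -> Ensemble:
    """Read a multi-model PDB, DCD or XTC trajectory as an :class:`Ensemble`.

    The format is taken from ``fmt`` or the file extension.  Coordinates are
    returned in Angstrom regardless of on-disk units.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        coords = _read_pdb_frames(path, topology.n_atoms)
    elif fmt in ("dcd", "xtc"):
        import MDAnalysis as mda
        from MDAnalysis.coordinates.DCD import DCDReader
        from MDAnalysis.coordinates.XTC import XTCReader

        reader_cls = DCDReader if fmt == "dcd" else XTCReader
        frames = []
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", DeprecationWarning)
            reader = reader_cls(str(path))
            try:
                for ts in reader:
                    frames.append(ts.positions.astype(float).copy())
            finally:
                reader.close()
        coords = np.asarray(frames)
    else:
        raise UnsupportedFormatError(f"unknown trajectory format {fmt!r}")
    if coords.shape[1] != topology.n_atoms:
        raise ShapeError(
            f"trajectory has {coords.shape[1]} atoms but topology has {topology.n_atoms}"
        )
    return Ensemble(coords, frame_interval=frame_interval, system_label=system_label)


def write_pdb(
    path: str | Path,
    topology: Topology,
    ensemble: Ensemble | None = None,
    coordinates: np.ndarray | None = None,
) -> None:
    """Write a (multi-model, if F > 1) PDB file."""
    if ensemble is not None:
        coords = ensemble.coordinates
    elif coordinates is not None:
        coords = np.asarray(coordinates, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
    else:
        raise ValueError("provide ensemble or coordinates")
    if coords.shape[1] != topology.n_atoms:
        raise ShapeError("coordinate/topology atom count mismatch")
    multi = coords.shape[0] > 1
    with open(path, "w") as fh:
        for m, frame in enumerate(coords, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for i in range(topology.n_atoms):
                rec = "HETATM" if topology.flags["ligand"][i] or topology.flags["water"][i] else "ATOM"
                name = topology.names[i]
                pad_name = f" {name:<3s}" if len(name) < 4 else name[:4]
                x, y, z = frame[i]
                fh.write(
                    f"{rec:<6s}{(i + 1) % 100000:5d} {pad_name:<4s}"
                    f"{topology.resnames[i][:4]:<4s}{topology.chains[i][:1]:1s}"
                    f"{int(topology.resids[i]) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {topology.elements[i][:2]:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_trajectory(path: str | Path, ensemble: Ensemble, fmt: str | None = None) -> None:
    """Write an ensemble to DCD or XTC via MDAnalysis."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("dcd", "xtc"):
        raise UnsupportedFormatError(f"unknown trajectory format {fmt!r}")
    import warnings as _warnings

    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    with _warnings.catch_warnings():
        # vacuum-boundary synthetic data has no unit cell to write
        _warnings.filterwarnings("ignore", message=".*unitcell.*")
        _warnings.simplefilter("ignore", DeprecationWarning)
        u = mda.Universe.empty(ensemble.n_atoms, trajectory=True)
        u.load_new(ensemble.coordinates.astype(np.float32), format=MemoryReader)
        with mda.Writer(str(path), n_atoms=ensemble.n_atoms) as w:
            for _ts in u.trajectory:
                w.write(u.atoms)


def concatenate(ensembles: Sequence[Ensemble]) -> Ensemble:
    """Join replicate ensembles along the frame axis, recording boundaries."""
    if not ensembles:
        raise EmptyInputError("nothing to concatenate")
    if len(ensembles) == 1:
        return ensembles[0]
    n = ensembles[0].n_atoms
    dt = ensembles[0].frame_interval
    for e in ensembles[1:]:
        if e.n_atoms != n:
            raise ShapeError(f"atom count mismatch: {e.n_atoms} != {n}")
        if e.frame_interval != dt:
            raise ShapeError("frame interval mismatch between replicates")
    boundaries: list[int] = []
    offset = 0
    for e in ensembles:
        boundaries.extend(b + offset for b in e.replicate_boundaries)
        offset += e.n_frames
    return Ensemble(
        np.concatenate([e.coordinates for e in ensembles], axis=0),
        frame_interval=dt,
        replicate_boundaries=tuple(boundaries),
        system_label=ensembles[0].system_label,
    )
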