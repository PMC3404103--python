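"""Structure and trajectory data model with fixed-column PDB I/O.

The in-memory model is deliberately small: an ordered list of
:class:`AtomRecord` plus a ``(frames, atoms, 3)`` coordinate block for
trajectories, all in Angstrom and picoseconds.  Multi-model PDB is the
interchange trajectory format; binary formats can be converted externally
(e.g. with MDAnalysis) into multi-model PDB before analysis.

Atom order is canonical and deterministic: chains in order of first
appearance, residues by number, atoms ranked N, CA, C, O then side chain
alphabetically.  Every downstream analysis relies on this ordering to map
atoms between structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    FitError,
    LookupAtomError,
    PDBParseError,
    SelectionError,
    TopologyError,
)

__all__ = [
    "AtomRecord",
    "StructureModel",
    "AtomSelection",
    "Trajectory",
    "Superposition",
    "read_pdb",
    "read_structure",
    "read_trajectory",
    "write_pdb",
    "select",
    "superpose",
    "pair_distance",
    "pair_distance_by_chain",
]

# Backbone atoms come first in a residue, in this order; side-chain atoms
# follow alphabetically.  Gives a stable flattened coordinate vector.
_BACKBONE_RANK = {"N": 0, "CA": 1, "C": 2, "O": 3}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a protein model (coordinates in Angstrom)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity of the atom within a model: (chain, residue number, name)."""
        return (self.chain_id, self.residue_number, self.atom_name)


def _atom_rank(name: str) -> tuple[int, str]:
    return (_BACKBONE_RANK.get(name, 4), name)


@dataclass
class StructureModel:
    """Ordered atoms of a (possibly multi-chain) protein model."""

    atoms: list[AtomRecord]
    chain_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chain_order:
            seen: dict[str, None] = {}
            for a in self.atoms:
                seen.setdefault(a.chain_id, None)
            self.chain_order = list(seen)
        self._sort_canonical()
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise TopologyError(f"duplicate atom {dup!r} in model")
        self._index = {k: i for i, k in enumerate(keys)}

    def _sort_canonical(self) -> None:
        pos = {c: i for i, c in enumerate(self.chain_order)}
        self.atoms.sort(
            key=lambda a: (pos[a.chain_id], a.residue_number, _atom_rank(a.atom_name))
        )

    # -- accessors -------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise TopologyError(
                f"coordinate block {coords.shape} does not match {self.n_atoms} atoms"
            )
        atoms = [replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return StructureModel(atoms, list(self.chain_order))

    def index_of(self, chain_id: str | None, residue_number: int, atom_name: str) -> int:
        """Index of an atom; ``chain_id=None`` requires a unique match."""
        if chain_id is not None:
            try:
                return self._index[(chain_id, residue_number, atom_name)]
            except KeyError:
                raise LookupAtomError(
                    f"no atom chain={chain_id!r} residue={residue_number} name={atom_name!r}"
                ) from None
        hits = [
            i
            for i, a in enumerate(self.atoms)
            if a.residue_number == residue_number and a.atom_name == atom_name
        ]
        if not hits:
            raise LookupAtomError(f"no atom residue={residue_number} name={atom_name!r}")
        if len(hits) > 1:
            raise LookupAtomError(
                f"atom residue={residue_number} name={atom_name!r} is ambiguous "
                f"({len(hits)} chains); give a chain id"
            )
        return hits[0]


@dataclass(frozen=True)
class AtomSelection:
    """Ordered atom indices into a :class:`StructureModel` plus the expression."""

    indices: np.ndarray
    expression: str

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class Trajectory:
    """Frames x atoms coordinate block with timestamps (ps) and its topology."""

    topology: StructureModel
    times: np.ndarray
    coords: np.ndarray  # (n_frames, n_atoms, 3), Angstrom

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TopologyError("trajectory coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] != self.times.shape[0]:
            raise TopologyError("times and frames differ in length")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyError("frame atom count does not match topology")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise TopologyError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame_model(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.coords[i])


@dataclass(frozen=True)
class Superposition:
    """Proper rigid transform minimizing RMSD of mobile onto reference."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord | None:
    """Parse one ATOM record; returns None for dropped altlocs."""
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: ATOM record shorter than 54 columns")
    altloc = line[16]
    if altloc not in (" ", "A"):
        return None
    icode = line[26]
    if icode != " ":
        raise PDBParseError(f"line {lineno}: insertion codes are not supported")
    try:
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resnum = int(line[22:26])
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])], dtype=float
        )
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM record ({exc})") from None
    if not np.all(np.isfinite(xyz)):
        raise PDBParseError(f"line {lineno}: non-finite coordinates")
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = name[:1]  # PDB v2 files: infer from the name's first letter
    return AtomRecord(chain, resnum, resname, name, element, xyz)


def read_pdb(path: str | Path):
    """Read a PDB file.

    Returns a :class:`StructureModel` for a single-model file, or a
    ``(StructureModel, Trajectory)`` pair for a multi-model file (frame times
    default to 0, 1, 2, ... ps).  HETATM records are ignored; altlocs other
    than blank/'A' are dropped; insertion codes are rejected.
    """
    path = Path(path)
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    seen_model_record = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                seen_model_record = True
                if in_model and current:
                    models.append(current)
                current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec == "ATOM  ":
                atom = _parse_atom_line(line.rstrip("\n"), lineno)
                if atom is not None:
                    current.append(atom)
            # HETATM, TER, remarks etc. are ignored by design
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBParseError(f"{path}: no ATOM records found")

    first = StructureModel(models[0])
    if len(models) == 1 and not seen_model_record:
        return first
    if len(models) == 1:
        # single explicit MODEL block: still a structure
        return first
    order = [a.key for a in first.atoms]
    frames = np.empty((len(models), len(order), 3), dtype=float)
    frames[0] = first.coords
    for mi, model_atoms in enumerate(models[1:], start=1):
        lookup = {a.key: a.position for a in model_atoms}
        if len(model_atoms) != len(order) or set(lookup) != set(order):
            raise TopologyError(
                f"{path}: model {mi + 1} has a different atom set than model 1"
            )
        frames[mi] = [lookup[k] for k in order]
    times = np.arange(len(models), dtype=float)
    return first, Trajectory(first, times, frames)


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB expected to hold a single model."""
    out = read_pdb(path)
    if isinstance(out, tuple):
        raise TopologyError(f"{path}: expected a single-model PDB, found a trajectory")
    return out


def read_trajectory(path: str | Path, dt_ps: float | None = None) -> Trajectory:
    """Read a multi-model PDB as a trajectory (optionally rescaling times)."""
    out = read_pdb(path)
    if isinstance(out, StructureModel):
        traj = Trajectory(out, np.zeros(1), out.coords[None, :, :])
    else:
        traj = out[1]
    if dt_ps is not None:
        traj = Trajectory(traj.topology, np.arange(traj.n_frames) * dt_ps, traj.coords)
    return traj


def _format_atom_line(serial: int, a: AtomRecord, pos: np.ndarray) -> str:
    name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3}"
    return (
        f"ATOM  {serial:>5} {name}{'':1}{a.residue_name:<3} {a.chain_id}"
        f"{a.residue_number:>4}    "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {a.element:>2}"
    )


def write_pdb(obj: StructureModel | Trajectory, path: str | Path) -> None:
    """Write a structure or trajectory as fixed-column (multi-model) PDB."""
    path = Path(path)
    lines: list[str] = []
    if isinstance(obj, StructureModel):
        for i, a in enumerate(obj.atoms, start=1):
            lines.append(_format_atom_line(i, a, a.position))
        lines.append("END")
    else:
        for f in range(obj.n_frames):
            lines.append(f"MODEL     {f + 1:>4}")
            for i, a in enumerate(obj.topology.atoms, start=1):
                lines.append(_format_atom_line(i, a, obj.coords[f, i - 1]))
            lines.append("ENDMDL")
        lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

_KEYWORDS = ("chain", "resnum", "resname", "name")


def _match_clause(atom: AtomRecord, keyword: str, values: list[str]) -> bool:
    if keyword == "chain":
        return atom.chain_id in values
    if keyword == "resname":
        return atom.residue_name in values
    if keyword == "name":
        return atom.atom_name in values
    # resnum: values are ints or "a-b" ranges, pre-validated
    for v in values:
        if "-" in v[1:]:
            lo, hi = v.split("-", 1) if not v.startswith("-") else (v[0] + v[1:].split("-", 1)[0], v[1:].split("-", 1)[1])
            if int(lo) <= atom.residue_number <= int(hi):
                return True
        elif atom.residue_number == int(v):
            return True
    return False


def select(model: StructureModel, expression: str) -> AtomSelection:
    """Select atoms with a small expression grammar.

    Grammar: clauses joined by ``and``; each clause is one of
    ``chain <id>...``, ``resnum <n | a-b>...``, ``resname <code>...``,
    ``name <atom>...`` with one or more space-separated values.
    ``all`` selects every atom.  An empty result is allowed.
    """
    tokens = expression.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    if tokens == ["all"]:
        idx = np.arange(model.n_atoms)
        return AtomSelection(idx, expression)
    clauses: list[tuple[str, list[str]]] = []
    i = 0
    while i < len(tokens):
        kw = tokens[i]
        if kw == "and":
            i += 1
            continue
        if kw not in _KEYWORDS:
            raise SelectionError(
                f"unknown keyword {kw!r} at token {i + 1} of {expression!r}"
            )
        values: list[str] = []
        i += 1
        while i < len(tokens) and tokens[i] != "and" and tokens[i] not in _KEYWORDS:
            values.append(tokens[i])
            i += 1
        if not values:
            raise SelectionError(f"keyword {kw!r} has no values in {expression!r}")
        if kw == "resnum":
            for v in values:
                parts = v.split("-")
                try:
                    [int(p) for p in parts if p != ""]
                except ValueError:
                    raise SelectionError(
                        f"bad residue number {v!r} in {expression!r}"
                    ) from None
        clauses.append((kw, values))
    mask = [
        all(_match_clause(a, kw, vals) for kw, vals in clauses) for a in model.atoms
    ]
    idx = np.flatnonzero(mask)
    return AtomSelection(idx, expression)


# ---------------------------------------------------------------------------
# Superposition and distances
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Kabsch fit over proper rotations and translations (no reflection).
    Requires >= 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise FitError("superpose needs two equally-shaped (n, 3) coordinate sets")
    n = mobile.shape[0]
    if n < 3:
        raise FitError(f"superpose needs >= 3 points, got {n}")
    if np.array_equal(mobile, reference):
        return Superposition(np.eye(3), np.zeros(3), 0.0)
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    mc = mobile - cm
    rc = reference - cr
    sv = np.linalg.svd(mc, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise FitError("superpose: degenerate (collinear or coincident) point set")
    rot, rssd = Rotation.align_vectors(rc, mc)
    rmsd = float(rssd / math.sqrt(n))
    R = rot.as_matrix()
    t = cr - R @ cm
    return Superposition(R, t, rmsd)


def _resolve_atom_spec(model: StructureModel, spec) -> int:
    """Resolve an atom spec to an index.

    Accepted forms: integer index; ``(chain, resnum, name)`` tuple;
    ``(resnum, name)`` tuple; ``"A:629:CB"`` or ``"629:CB"`` strings.
    """
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    if isinstance(spec, str):
        parts = spec.split(":")
        if len(parts) == 3:
            return model.index_of(parts[0], int(parts[1]), parts[2])
        if len(parts) == 2:
            return model.index_of(None, int(parts[0]), parts[1])
        raise LookupAtomError(f"bad atom spec {spec!r} (use 'chain:resnum:name')")
    if len(spec) == 3:
        return model.index_of(spec[0], int(spec[1]), spec[2])
    if len(spec) == 2:
        return model.index_of(None, int(spec[0]), spec[1])
    raise LookupAtomError(f"bad atom spec {spec!r}")


def pair_distance(model: StructureModel, atom_a, atom_b, coords: np.ndarray | None = None) -> float:
    """Euclidean distance (Angstrom) between two atoms of a model or frame."""
    ia = _resolve_atom_spec(model, atom_a)
    ib = _resolve_atom_spec(model, atom_b)
    xyz = model.coords if coords is None else np.asarray(coords, dtype=float)
    return float(np.linalg.norm(xyz[ia] - xyz[ib]))


def pair_distance_by_chain(
    model: StructureModel,
    residue_a: int,
    name_a: str,
    residue_b: int,
    name_b: str,
    coords: np.ndarray | None = None,
) -> dict[str, float]:
    """Per-chain distance between two atoms of the same subunit."""
    out: dict[str, float] = {}
    for c in model.chain_order:
        out[c] = pair_distance(model, (c, residue_a, name_a), (c, residue_b, name_b), coords)
    return out
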