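"""Readers and writers for the file formats the analysis chain consumes.

Supported formats are deliberately minimal, plain-text dialects:

* Sparky-style peak lists (assignment, two positions, intensity),
* tab-separated chemical-shift tables and a minimal NMR-STAR subset
  (the atom-shift and distance-restraint loops only),
* multi-model PDB coordinate files (read through biotite),
* CYANA-style upper-limit distance-restraint files (``.upl``).

All downstream modules consume only the container types defined here.
Residue numbering is taken verbatim from the files; no renumbering is
performed, so residue labels in reports match the construct numbering of
the input data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "ParseError",
    "IntegrityError",
    "FormatError",
    "Peak",
    "PeakList",
    "ShiftRecord",
    "ShiftTable",
    "StructureEnsemble",
    "Restraint",
    "RestraintList",
    "read_peak_list",
    "read_shift_table",
    "read_ensemble",
    "read_restraints",
    "write_restraints",
    "write_ensemble",
]


class ParseError(ValueError):
    """A line of an input file could not be interpreted."""


class IntegrityError(ValueError):
    """Parsed content violates a container invariant (e.g. duplicate keys)."""


class FormatError(ValueError):
    """The file as a whole is not of the expected format."""


ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

#: Backbone-amide atoms; anything else on the assignment marks a side-chain site.
_BACKBONE_AMIDE = ("N", "H", "HN")


@dataclass(frozen=True)
class Peak:
    """One cross peak: assignment, two spectral positions and an intensity."""

    residue_index: int
    residue_name: str  # 3-letter code or "?"
    atom1: str
    atom2: str
    position1: float  # ppm
    position2: float  # ppm
    intensity: float
    site_label: str = "bb"  # "bb" backbone amide, "sc" side chain

    def __post_init__(self):
        if self.residue_index < 1:
            raise IntegrityError(f"residue index must be >= 1, got {self.residue_index}")
        for value, name in ((self.position1, "position1"),
                            (self.position2, "position2"),
                            (self.intensity, "intensity")):
            if not np.isfinite(value):
                raise IntegrityError(f"{name} is not finite for residue {self.residue_index}")


@dataclass
class PeakList:
    entries: list[Peak] = field(default_factory=list)
    source_label: str = ""
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def by_site(self) -> dict[tuple[int, str], Peak]:
        """Index peaks by (residue_index, site_label)."""
        return {(p.residue_index, p.site_label): p for p in self.entries}


@dataclass(frozen=True)
class ShiftRecord:
    residue_index: int
    residue_name: str
    atom: str  # one of N, H, CA, CB, HA, C
    shift: float  # ppm


#: Atom names the shift table understands ("C" is the carbonyl C').
SHIFT_ATOMS = ("N", "H", "CA", "CB", "HA", "C")
_ATOM_ALIASES = {"C'": "C", "CO": "C", "HN": "H"}


@dataclass
class ShiftTable:
    records: list[ShiftRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            key = (rec.residue_index, rec.atom)
            if key in seen:
                raise IntegrityError(f"duplicate shift record for residue {key[0]} atom {key[1]}")
            seen.add(key)
            if not np.isfinite(rec.shift):
                raise IntegrityError(f"non-finite shift for residue {key[0]} atom {key[1]}")

    def __len__(self) -> int:
        return len(self.records)

    def get(self, residue_index: int, atom: str) -> float | None:
        for rec in self.records:
            if rec.residue_index == residue_index and rec.atom == atom:
                return rec.shift
        return None

    def residues(self) -> list[int]:
        return sorted({rec.residue_index for rec in self.records})

    def residue_name(self, residue_index: int) -> str:
        for rec in self.records:
            if rec.residue_index == residue_index:
                return rec.residue_name
        return "?"


@dataclass
class StructureEnsemble:
    """Multi-model coordinates on a unified atom roster.

    ``atoms`` holds one (residue_index, residue_name, atom_name, element)
    tuple per roster position; ``coords`` has shape (n_models, n_atoms, 3)
    in Angstrom.  Every model shares the identical roster by construction.
    """

    atoms: list[tuple[int, str, str, str]]
    coords: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise IntegrityError("coords must have shape (n_models, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise IntegrityError("ensemble needs at least one model")
        if self.coords.shape[1] != len(self.atoms):
            raise IntegrityError("coordinate count does not match atom roster")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_ids(self) -> list[int]:
        return sorted({a[0] for a in self.atoms})

    def residue_name(self, residue_index: int) -> str:
        for res_id, res_name, _, _ in self.atoms:
            if res_id == residue_index:
                return res_name
        raise KeyError(residue_index)

    def atom_index(self, residue_index: int, atom_name: str) -> int | None:
        for i, (res_id, _, name, _) in enumerate(self.atoms):
            if res_id == residue_index and name == atom_name:
                return i
        return None

    def select(self, residue_indices=None, atom_names=None, heavy_only=False) -> np.ndarray:
        """Boolean mask over the roster."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if residue_indices is not None:
            residue_indices = set(residue_indices)
            mask &= np.array([a[0] in residue_indices for a in self.atoms])
        if atom_names is not None:
            atom_names = set(atom_names)
            mask &= np.array([a[2] in atom_names for a in self.atoms])
        if heavy_only:
            mask &= np.array([a[3] != "H" for a in self.atoms])
        return mask


@dataclass(frozen=True)
class Restraint:
    res_i: int
    name_i: str
    atom_i: str
    res_j: int
    name_j: str
    atom_j: str
    lower: float  # Angstrom, 0 for upper-limit-only restraints
    upper: float  # Angstrom
    kind: str = "NOE"  # one of NOE, zinc, other

    def __post_init__(self):
        if not self.upper > 0:
            raise IntegrityError(f"upper bound must be positive, got {self.upper}")
        if self.lower > self.upper:
            raise IntegrityError(f"lower bound {self.lower} exceeds upper bound {self.upper}")
        if (self.res_i, self.atom_i) == (self.res_j, self.atom_j):
            raise IntegrityError(f"restraint between an atom and itself: {self.res_i} {self.atom_i}")

    @property
    def separation(self) -> int:
        return abs(self.res_i - self.res_j)


@dataclass
class RestraintList:
    restraints: list[Restraint] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.restraints)

    def of_kind(self, kind: str) -> "RestraintList":
        return RestraintList([r for r in self.restraints if r.kind == kind])


# ---------------------------------------------------------------------------
# Sparky peak lists
# ---------------------------------------------------------------------------

_ASSIGNMENT_RE = re.compile(
    r"^(?P<code>[A-Z?])(?P<index>\d+)(?P<sc>sc)?(?P<atom1>[A-Z][A-Z0-9']*)-(?P<atom2>[A-Z][A-Z0-9']*)$"
)


def parse_assignment(token: str) -> tuple[int, str, str, str, str]:
    """Parse a Sparky assignment like ``G96N-H`` or ``W112scNE1-HE1``.

    Returns (residue_index, residue_name, atom1, atom2, site_label).
    """
    m = _ASSIGNMENT_RE.match(token)
    if m is None:
        raise ParseError(f"malformed assignment {token!r}")
    code = m.group("code")
    res_name = ONE_TO_THREE.get(code, "?")
    atom1, atom2 = m.group("atom1"), m.group("atom2")
    sc = m.group("sc") is not None or atom1 not in _BACKBONE_AMIDE
    return int(m.group("index")), res_name, atom1, atom2, "sc" if sc else "bb"


def read_peak_list(path, dialect: str = "sparky") -> PeakList:
    """Read a peak list; one :class:`Peak` per data line.

    Lines starting with ``#`` and Sparky column headers (first token
    ``Assignment``) are comments.  Any other malformed line raises
    :class:`ParseError` naming the line number, so no data line is ever
    silently dropped.
    """
    if dialect != "sparky":
        raise ValueError(f"unsupported peak-list dialect {dialect!r}")
    path = Path(path)
    entries = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if tokens[0] == "Assignment":  # Sparky header
                continue
            if len(tokens) < 4:
                raise ParseError(f"{path.name}:{lineno}: expected >= 4 columns, got {len(tokens)}")
            try:
                idx, res_name, atom1, atom2, site = parse_assignment(tokens[0])
            except ParseError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
            try:
                w1, w2, height = float(tokens[1]), float(tokens[2]), float(tokens[3])
            except ValueError:
                raise ParseError(f"{path.name}:{lineno}: non-numeric column") from None
            entries.append(Peak(idx, res_name, atom1, atom2, w1, w2, height, site))
    return PeakList(entries=entries, source_label=path.name)


# ---------------------------------------------------------------------------
# Chemical-shift tables
# ---------------------------------------------------------------------------

def _shift_records_from_rows(rows, source: str):
    records, warnings, seen = [], [], set()
    for lineno, (res_idx, res_name, atom, value) in rows:
        atom = _ATOM_ALIASES.get(atom, atom)
        if atom not in SHIFT_ATOMS:
            warnings.append(f"{source}:{lineno}: unknown atom {atom!r} skipped")
            continue
        key = (res_idx, atom)
        if key in seen:
            raise IntegrityError(f"{source}:{lineno}: duplicate shift for residue {res_idx} atom {atom}")
        seen.add(key)
        records.append(ShiftRecord(res_idx, res_name, atom, value))
    return records, warnings


def read_shift_table(path, dialect: str = "tsv") -> ShiftTable:
    """Read a chemical-shift table.

    ``tsv``: tab/whitespace-separated columns
    ``residue_index residue_name atom shift`` with an optional header line.
    ``nmrstar_min``: the atom-shift loop of an NMR-STAR file (only the
    sequence-id, residue-name, atom-id and value tags are interpreted).

    Unknown atom names are skipped and counted in ``table.warnings``;
    duplicate (residue, atom) rows raise :class:`IntegrityError`.
    """
    path = Path(path)
    if dialect == "tsv":
        rows = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                tokens = line.split()
                if tokens[0].lower() in ("residue", "residue_index", "res"):
                    continue  # header
                if len(tokens) < 4:
                    raise ParseError(f"{path.name}:{lineno}: expected 4 columns")
                try:
                    idx = int(tokens[0])
                    value = float(tokens[3])
                except ValueError:
                    raise ParseError(f"{path.name}:{lineno}: non-numeric column") from None
                rows.append((lineno, (idx, tokens[1].upper(), tokens[2].upper(), value)))
    elif dialect == "nmrstar_min":
        rows = _star_shift_rows(path)
    else:
        raise ValueError(f"unsupported shift-table dialect {dialect!r}")
    records, warnings = _shift_records_from_rows(rows, path.name)
    table = ShiftTable(records=records)
    table.warnings = warnings
    return table


def _star_loops(path):
    """Minimal STAR loop extractor: yields (tags, rows) per ``loop_`` block."""
    tags, rows, in_loop, in_header = [], [], False, False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "loop_":
                if in_loop and tags:
                    yield tags, rows
                tags, rows, in_loop, in_header = [], [], True, True
                continue
            if not in_loop:
                continue
            if line == "stop_" or line.startswith("save_"):
                if tags:
                    yield tags, rows
                tags, rows, in_loop, in_header = [], [], False, False
                continue
            if line.startswith("_"):
                if in_header:
                    tags.append(line.split()[0])
                continue
            in_header = False
            rows.append(line.split())
    if in_loop and tags:
        yield tags, rows


def _find_tag(tags, *suffixes):
    for suffix in suffixes:
        for i, tag in enumerate(tags):
            if tag.lower().endswith(suffix.lower()):
                return i
    return None


def _star_shift_rows(path):
    for tags, rows in _star_loops(path):
        i_seq = _find_tag(tags, ".Seq_ID", ".Comp_index_ID")
        i_comp = _find_tag(tags, ".Comp_ID")
        i_atom = _find_tag(tags, ".Atom_ID")
        i_val = _find_tag(tags, ".Val", ".Chem_shift_val")
        if i_seq is None or i_atom is None or i_val is None:
            continue
        out = []
        for n, row in enumerate(rows, start=1):
            if len(row) <= max(i_seq, i_atom, i_val):
                raise ParseError(f"{Path(path).name}: short row in shift loop")
            name = row[i_comp].upper() if i_comp is not None else "?"
            out.append((n, (int(row[i_seq]), name, row[i_atom].upper(), float(row[i_val]))))
        return out
    return []


# ---------------------------------------------------------------------------
# Multi-model PDB ensembles
# ---------------------------------------------------------------------------

def read_ensemble(path) -> StructureEnsemble:
    """Read a (possibly multi-model) PDB file into a unified-roster ensemble.

    Atoms present in only a subset of the models are dropped with a warning;
    hydrogen atoms are kept.  Raises :class:`FormatError` if the file holds
    no ATOM records.
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    try:
        n_models = pdb.get_model_count()
    except Exception as exc:  # pragma: no cover - biotite internal failure modes
        raise FormatError(f"{path.name}: not a readable PDB file: {exc}") from None
    if n_models == 0:
        raise FormatError(f"{path.name}: no ATOM records")
    models = []
    for i in range(1, n_models + 1):
        arr = pdb.get_structure(model=i)
        if arr.array_length() == 0:
            raise FormatError(f"{path.name}: model {i} holds no ATOM records")
        models.append(arr)

    def roster_keys(arr):
        return list(zip(arr.chain_id.tolist(), arr.res_id.tolist(), arr.atom_name.tolist()))

    keys0 = roster_keys(models[0])
    common = set(keys0)
    for arr in models[1:]:
        common &= set(roster_keys(arr))
    warnings = []
    order = [k for k in keys0 if k in common]
    dropped = len(keys0) - len(order)
    if dropped:
        warnings.append(f"{dropped} atom(s) absent from some models were dropped")

    atoms = []
    index0 = {k: i for i, k in enumerate(keys0)}
    arr0 = models[0]
    for key in order:
        i = index0[key]
        element = arr0.element[i].capitalize() if arr0.element[i] else "?"
        atoms.append((int(arr0.res_id[i]), str(arr0.res_name[i]), str(arr0.atom_name[i]), element))

    coords = np.empty((n_models, len(order), 3), dtype=float)
    for m, arr in enumerate(models):
        lookup = {k: i for i, k in enumerate(roster_keys(arr))}
        idx = np.array([lookup[k] for k in order], dtype=int)
        coords[m] = arr.coord[idx]
    return StructureEnsemble(atoms=atoms, coords=coords, warnings=warnings)


def write_ensemble(ensemble: StructureEnsemble, path) -> None:
    """Write an ensemble as a (multi-)model PDB file."""
    import biotite.structure as struc

    arrays = []
    for m in range(ensemble.n_models):
        arr = struc.AtomArray(ensemble.n_atoms)
        arr.coord = ensemble.coords[m]
        arr.chain_id[:] = "A"
        arr.res_id = np.array([a[0] for a in ensemble.atoms])
        arr.res_name = np.array([a[1] for a in ensemble.atoms])
        arr.atom_name = np.array([a[2] for a in ensemble.atoms])
        arr.element = np.array([a[3].upper() for a in ensemble.atoms])
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Distance restraints
# ---------------------------------------------------------------------------

def read_restraints(path, dialect: str = "cyana_upl", kind: str = "NOE") -> RestraintList:
    """Read a distance-restraint list.

    ``cyana_upl`` lines are ``res_i name_i atom_i res_j name_j atom_j upper``
    with an implicit lower bound of zero.  ``nmrstar_min`` reads the general
    distance-constraint loop of an NMR-STAR file.
    """
    path = Path(path)
    restraints = []
    if dialect == "cyana_upl":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                tokens = line.split()
                if len(tokens) < 7:
                    raise ParseError(f"{path.name}:{lineno}: expected 7 columns, got {len(tokens)}")
                try:
                    res_i, res_j = int(tokens[0]), int(tokens[3])
                    upper = float(tokens[6])
                except ValueError:
                    raise ParseError(f"{path.name}:{lineno}: non-numeric bound or index") from None
                restraints.append(Restraint(res_i, tokens[1].upper(), tokens[2].upper(),
                                            res_j, tokens[4].upper(), tokens[5].upper(),
                                            0.0, upper, kind))
    elif dialect == "nmrstar_min":
        restraints = _star_restraints(path, kind)
    else:
        raise ValueError(f"unsupported restraint dialect {dialect!r}")
    return RestraintList(restraints=restraints)


def _star_restraints(path, kind):
    restraints = []
    for tags, rows in _star_loops(path):
        i_s1 = _find_tag(tags, ".Seq_ID_1", ".Comp_index_ID_1")
        i_s2 = _find_tag(tags, ".Seq_ID_2", ".Comp_index_ID_2")
        i_a1 = _find_tag(tags, ".Atom_ID_1")
        i_a2 = _find_tag(tags, ".Atom_ID_2")
        i_up = _find_tag(tags, ".Distance_upper_bound_val", ".Upper_distance_limit")
        i_lo = _find_tag(tags, ".Distance_lower_bound_val", ".Lower_distance_limit")
        i_n1 = _find_tag(tags, ".Comp_ID_1")
        i_n2 = _find_tag(tags, ".Comp_ID_2")
        if None in (i_s1, i_s2, i_a1, i_a2, i_up):
            continue
        for row in rows:
            try:
                upper = float(row[i_up])
            except ValueError:
                raise ParseError(f"{Path(path).name}: non-numeric bound {row[i_up]!r}") from None
            lower = 0.0
            if i_lo is not None and row[i_lo] not in (".", "?"):
                try:
                    lower = float(row[i_lo])
                except ValueError:
                    lower = 0.0
            restraints.append(Restraint(
                int(row[i_s1]), row[i_n1].upper() if i_n1 is not None else "?", row[i_a1].upper(),
                int(row[i_s2]), row[i_n2].upper() if i_n2 is not None else "?", row[i_a2].upper(),
                lower, upper, kind))
    return restraints


def write_restraints(restraint_list: RestraintList, dialect: str = "cyana_upl") -> str:
    """Serialize restraints; deterministic ordering, fixed 2-decimal bounds.

    Only the upper bound is written (upper-limit format); the output of a
    shuffled input list is byte-identical to that of the sorted list.
    """
    if dialect != "cyana_upl":
        raise ValueError(f"unsupported restraint dialect {dialect!r}")
    ordered = sorted(restraint_list.restraints,
                     key=lambda r: (r.res_i, r.atom_i, r.res_j, r.atom_j))
    lines = [
        f"{r.res_i:4d} {r.name_i:<4s} {r.atom_i:<4s} "
        f"{r.res_j:4d} {r.name_j:<4s} {r.atom_j:<4s} {r.upper:6.2f}"
        for r in ordered
    ]
    return "\n".join(lines) + ("\n" if lines else "")
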