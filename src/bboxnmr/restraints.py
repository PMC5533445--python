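"""Zinc-site restraint generation, NOE classification and violation checks.

Tetrahedral zinc sites in RING/B-box folds are encoded as heavy-atom pair
restraints rather than explicit metal placement: a Zn pseudo-atom (atom name
``ZN``) is restrained to every donor atom, each Cys/Asp donor is tethered to
its anchor carbon, and donor-donor pairs (SG-SG, His NE2 - Cys SG) keep the
ligands arranged tetrahedrally.  All distance bounds live in a configurable
scheme table; the defaults are common zinc-site calibrations and should be
adapted to the downstream structure-calculation force field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Restraint, RestraintList, StructureEnsemble

__all__ = [
    "ZincSite",
    "DEFAULT_ZINC_SCHEME",
    "RangeCounts",
    "ViolationReport",
    "generate_zinc_restraints",
    "classify_noe",
    "check_violations",
]

_DONORS_BY_RESIDUE = {
    "CYS": ("SG",),
    "HIS": ("NE2", "ND1"),
    "ASP": ("OD1", "OD2"),
}

#: Distance-bound table (Angstrom) per restraint class.  ``ZN-*`` classes
#: bind the Zn pseudo-atom to a donor; the remaining classes are
#: donor-anchor tethers and donor-donor geometry restraints.
DEFAULT_ZINC_SCHEME = {
    "ZN-SG": (2.25, 2.40),
    "ZN-NE2": (1.95, 2.10),
    "ZN-ND1": (1.95, 2.10),
    "ZN-OD": (1.90, 2.05),
    "SG-SG": (3.55, 3.95),
    "NE2-SG": (3.40, 3.80),
    "ND1-SG": (3.40, 3.80),
    "SG-CB": (3.00, 3.40),
    "OD-CG": (2.80, 3.20),
}

#: Residue index assigned to the Zn pseudo-atom in emitted restraints.
ZINC_PSEUDO_RESIDUE = 999


@dataclass(frozen=True)
class ZincSite:
    """A candidate zinc-coordination site: 2-4 donor ligands."""

    label: str
    ligands: tuple  # of (residue_index, residue_name, donor_atom)

    def __post_init__(self):
        object.__setattr__(self, "ligands", tuple(self.ligands))
        if self.ligands and not 2 <= len(self.ligands) <= 4:
            raise ValueError(f"site {self.label}: expected 2-4 ligands, got {len(self.ligands)}")
        for res_idx, res_name, donor in self.ligands:
            allowed = _DONORS_BY_RESIDUE.get(res_name)
            if allowed is None:
                raise ValueError(f"site {self.label}: residue type {res_name} cannot ligate zinc")
            if donor not in allowed:
                raise ValueError(
                    f"site {self.label}: donor {donor} inconsistent with {res_name}{res_idx}")


def _zn_class(donor: str) -> str:
    return "ZN-OD" if donor.startswith("OD") else f"ZN-{donor}"


def generate_zinc_restraints(site: ZincSite, scheme: dict | None = None,
                             zinc_residue_index: int = ZINC_PSEUDO_RESIDUE) -> RestraintList:
    """Distance restraints enforcing tetrahedral geometry for one zinc site.

    Per site the default scheme emits: one Zn-donor restraint per ligand, a
    donor-anchor tether per Cys (SG-CB) and per Asp (OD-CG), every Cys SG-SG
    pair, and every His NE2/ND1 - Cys SG pair.  Emission order is canonical
    (ligands sorted by residue index), so the output is invariant to the
    ligand listing order.  All restraints carry ``kind="zinc"``.
    """
    scheme = dict(DEFAULT_ZINC_SCHEME, **(scheme or {}))
    ligands = sorted(site.ligands)
    restraints = []

    def add(res_i, name_i, atom_i, res_j, name_j, atom_j, cls):
        lower, upper = scheme[cls]
        restraints.append(Restraint(res_i, name_i, atom_i, res_j, name_j, atom_j,
                                    lower, upper, kind="zinc"))

    for res_idx, res_name, donor in ligands:
        add(zinc_residue_index, "ZN", "ZN", res_idx, res_name, donor, _zn_class(donor))
    for res_idx, res_name, donor in ligands:
        if res_name == "CYS":
            add(res_idx, res_name, donor, res_idx, res_name, "CB", "SG-CB")
        elif res_name == "ASP":
            add(res_idx, res_name, donor, res_idx, res_name, "CG", "OD-CG")
    cys = [(r, n, d) for r, n, d in ligands if n == "CYS"]
    his = [(r, n, d) for r, n, d in ligands if n == "HIS"]
    for a in range(len(cys)):
        for b in range(a + 1, len(cys)):
            add(cys[a][0], "CYS", "SG", cys[b][0], "CYS", "SG", "SG-SG")
    for h_res, _, h_donor in his:
        for c_res, _, _ in cys:
            add(h_res, "HIS", h_donor, c_res, "CYS", "SG", f"{h_donor}-SG")
    return RestraintList(restraints=restraints)


# ---------------------------------------------------------------------------
# NOE classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RangeCounts:
    """NOE counts binned by sequence separation s = |i - j|:
    intra (s = 0), sequential (s = 1), medium (2 <= s <= 4), long (s >= 5)."""

    intra: int = 0
    sequential: int = 0
    medium: int = 0
    long: int = 0
    ignored: int = 0  # restraints of a non-NOE kind, not binned

    @property
    def total(self) -> int:
        return self.intra + self.sequential + self.medium + self.long


def classify_noe(restraint_list: RestraintList) -> RangeCounts:
    """Bin NOE restraints by sequence separation; non-NOE restraints are
    counted in ``ignored`` instead of being binned."""
    intra = sequential = medium = long_ = ignored = 0
    for r in restraint_list.restraints:
        if r.kind != "NOE":
            ignored += 1
            continue
        s = r.separation
        if s == 0:
            intra += 1
        elif s == 1:
            sequential += 1
        elif s <= 4:
            medium += 1
        else:
            long_ += 1
    return RangeCounts(intra, sequential, medium, long_, ignored)


# ---------------------------------------------------------------------------
# Violation counting
# ---------------------------------------------------------------------------

@dataclass
class ViolationReport:
    threshold: float  # Angstrom
    violated_restraints: list  # of (Restraint, max excess over models)
    skipped: list = field(default_factory=list)  # restraints with unresolvable atoms
    warnings: list[str] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.violated_restraints)


def _resolve_atom(ensemble: StructureEnsemble, res: int, atom: str):
    """Indices of the atom(s) a restraint endpoint addresses.

    Exact atom names resolve directly; CYANA-style pseudo-atoms (``QB``,
    ``QG1``, ...) expand to the matching proton group and are evaluated at
    the group centroid.
    """
    idx = ensemble.atom_index(res, atom)
    if idx is not None:
        return [idx]
    if atom.startswith("Q"):
        prefix = "H" + atom[1:]
        matches = [i for i, (r, _, name, _) in enumerate(ensemble.atoms)
                   if r == res and name.startswith(prefix)]
        if matches:
            return matches
    return []


def check_violations(restraint_list: RestraintList, ensemble: StructureEnsemble,
                     threshold: float = 0.5) -> ViolationReport:
    """Count restraints violated beyond ``threshold`` in any model.

    A restraint is violated when, in at least one model, the inter-atomic
    distance exceeds ``upper + threshold`` or falls below
    ``lower - threshold``.  The count is over restraints, not model-restraint
    pairs; the reported excess is the maximum over models.  Restraints whose
    atoms cannot be resolved in the roster are skipped with a warning.
    """
    report = ViolationReport(threshold=threshold, violated_restraints=[])
    for r in restraint_list.restraints:
        idx_i = _resolve_atom(ensemble, r.res_i, r.atom_i)
        idx_j = _resolve_atom(ensemble, r.res_j, r.atom_j)
        if not idx_i or not idx_j:
            report.skipped.append(r)
            report.warnings.append(
                f"unresolvable atom(s) {r.res_i}/{r.atom_i} - {r.res_j}/{r.atom_j}, skipped")
            continue
        pos_i = ensemble.coords[:, idx_i, :].mean(axis=1)
        pos_j = ensemble.coords[:, idx_j, :].mean(axis=1)
        dist = np.linalg.norm(pos_i - pos_j, axis=1)
        excess = np.maximum(dist - r.upper, r.lower - dist)
        worst = float(excess.max())
        if worst > threshold:
            report.violated_restraints.append((r, worst))
    return report
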