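"""Geometry statistics on multi-model NMR ensembles.

Implements least-squares rigid superposition (Kabsch, with reflection
guard), average pairwise RMSD over model pairs, ordered-residue detection
from CA fluctuations, a reduced secondary-structure assignment based on the
Kabsch-Sander hydrogen-bond energy (helix/strand/coil only), Shrake-Rupley
solvent accessibility with extended Gly-X-Gly normalization of side-chain
exposure, and single-linkage clustering of perturbed sites into surface
patches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import StructureEnsemble

__all__ = [
    "SuperpositionResult",
    "OrderedRegion",
    "SecondaryStructureProfile",
    "AccessibilityRecord",
    "Patch",
    "BACKBONE_ATOMS",
    "superpose",
    "average_pairwise_rmsd",
    "ordered_residues",
    "secondary_structure",
    "secondary_structure_profile",
    "accessibility",
    "shrake_rupley",
    "cluster_patches",
]

#: Backbone atom set used for RMSD selections (O excluded by convention).
BACKBONE_ATOMS = ("N", "CA", "C")


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper orthonormal
    translation: np.ndarray  # Angstrom
    rmsd: float  # Angstrom over the fitted selection

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(model_a: np.ndarray, model_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid fit of ``model_b`` onto ``model_a``.

    Uses the SVD construction of the optimal rotation with a determinant
    guard against reflections.  Requires >= 3 non-collinear matched atoms.
    """
    a = np.asarray(model_a, dtype=float)
    b = np.asarray(model_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must share shape (n, 3)")
    if a.shape[0] < 3:
        raise ValueError("need >= 3 atoms to superpose")
    b_centered = b - b.mean(axis=0)
    if np.linalg.matrix_rank(b_centered, tol=1e-8) < 2:
        raise ValueError("atoms are collinear")
    ac, bc = a.mean(axis=0), b.mean(axis=0)
    h = (b - bc).T @ (a - ac)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ac - rot @ bc
    moved = b @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def _selection_mask(ensemble: StructureEnsemble, residues, atom_set: str) -> np.ndarray:
    if atom_set == "backbone":
        mask = ensemble.select(residue_indices=residues, atom_names=BACKBONE_ATOMS)
    elif atom_set == "heavy":
        mask = ensemble.select(residue_indices=residues, heavy_only=True)
    else:
        raise ValueError(f"unknown atom set {atom_set!r}")
    if not mask.any():
        raise ValueError("empty atom selection")
    return mask


def average_pairwise_rmsd(ensemble: StructureEnsemble, residues=None,
                          atom_set: str = "backbone") -> tuple[float, float]:
    """Mean and standard deviation of the RMSD over all unordered model
    pairs, each pair superposed on the selection before measuring."""
    if ensemble.n_models < 2:
        raise ValueError("need >= 2 models")
    mask = _selection_mask(ensemble, residues, atom_set)
    coords = ensemble.coords[:, mask, :]
    values = []
    for i in range(ensemble.n_models):
        for j in range(i + 1, ensemble.n_models):
            values.append(superpose(coords[i], coords[j]).rmsd)
    values = np.array(values)
    return float(values.mean()), float(values.std())


@dataclass
class OrderedRegion:
    residues: set[int]
    rmsf: dict[int, float]  # per-residue CA RMSF, Angstrom
    threshold: float


def ordered_residues(ensemble: StructureEnsemble, rmsf_threshold: float = 1.0) -> OrderedRegion:
    """Residues whose CA fluctuation stays below the threshold.

    All models are superposed onto model 1 on every CA, the mean structure
    is formed, and the per-residue CA RMSF about that mean is compared to
    the threshold.
    """
    if ensemble.n_models < 2:
        raise ValueError("need >= 2 models")
    mask = ensemble.select(atom_names=("CA",))
    res_ids = [a[0] for a, m in zip(ensemble.atoms, mask) if m]
    ca = ensemble.coords[:, mask, :]
    fitted = np.empty_like(ca)
    fitted[0] = ca[0]
    for m in range(1, ca.shape[0]):
        fitted[m] = superpose(ca[0], ca[m]).apply(ca[m])
    mean = fitted.mean(axis=0)
    rmsf_values = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
    rmsf = {res: float(v) for res, v in zip(res_ids, rmsf_values)}
    ordered = {res for res, v in rmsf.items() if v < rmsf_threshold}
    return OrderedRegion(residues=ordered, rmsf=rmsf, threshold=rmsf_threshold)


# ---------------------------------------------------------------------------
# Secondary structure (reduced DSSP)
# ---------------------------------------------------------------------------

_HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_HB_Q1Q2F = 0.084 * 332.0  # partial charges times electrostatic factor
_CHAIN_BREAK_CN = 2.5  # Angstrom; larger C(i)-N(i+1) distances break the chain


def _backbone_frames(ensemble: StructureEnsemble, model: int):
    """Per-residue N/CA/C/O (+H, rebuilt if missing) for one model."""
    residues = ensemble.residue_ids()
    frames = {}
    for res in residues:
        frame = {}
        for name in ("N", "CA", "C", "O", "H"):
            idx = ensemble.atom_index(res, name)
            if idx is not None:
                frame[name] = ensemble.coords[model, idx]
        if all(k in frame for k in ("N", "CA", "C", "O")):
            frames[res] = frame
    ordered = sorted(frames)
    # chain continuity and amide-proton reconstruction from C(i-1), N(i), CA(i)
    for prev, res in zip(ordered, ordered[1:]):
        if res != prev + 1:
            continue
        if np.linalg.norm(frames[res]["N"] - frames[prev]["C"]) > _CHAIN_BREAK_CN:
            continue
        frames[res]["prev"] = prev
        if "H" not in frames[res]:
            n, ca, c_prev = frames[res]["N"], frames[res]["CA"], frames[prev]["C"]
            u = (n - c_prev) / np.linalg.norm(n - c_prev) + (n - ca) / np.linalg.norm(n - ca)
            frames[res]["H"] = n + 1.01 * u / np.linalg.norm(u)
    return frames, ordered


def _hbond_set(frames, ordered):
    """Pairs (i, j) where the CO of residue i accepts the NH of residue j."""
    bonds = set()
    for j in ordered:
        fj = frames[j]
        if "H" not in fj or "prev" not in fj:
            continue  # no amide proton (chain start, break or proline)
        for i in ordered:
            if i == j:
                continue
            fi = frames[i]
            r_on = np.linalg.norm(fi["O"] - fj["N"])
            r_ch = np.linalg.norm(fi["C"] - fj["H"])
            r_oh = np.linalg.norm(fi["O"] - fj["H"])
            r_cn = np.linalg.norm(fi["C"] - fj["N"])
            if min(r_on, r_oh) < 0.5:  # overlapping atoms, not a bond
                continue
            energy = _HB_Q1Q2F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < _HB_ENERGY_CUTOFF:
                bonds.add((i, j))
    return bonds


def secondary_structure(ensemble: StructureEnsemble, model: int = 0) -> dict[int, str]:
    """Reduced per-residue secondary structure for one model: H, E or C.

    Hydrogen bonds use the Kabsch-Sander electrostatic energy with the -0.5
    kcal/mol cutoff; helices come from runs of i -> i+4 bonds (two
    consecutive 4-turns), strands from parallel or antiparallel bridge
    pairing.  pi/3-10 helices, isolated turns and bends all report as coil;
    residues with missing backbone atoms are omitted from the result.
    """
    frames, ordered = _backbone_frames(ensemble, model)
    hb = _hbond_set(frames, ordered)
    present = set(ordered)
    states = {res: "C" for res in ordered}

    def turn4(i):
        return (i, i + 4) in hb and i + 4 in present

    for i in ordered:
        if turn4(i - 1) and turn4(i):
            for k in range(i, i + 4):
                if k in states:
                    states[k] = "H"

    def hbond(i, j):
        return (i, j) in hb

    for i in ordered:
        for j in ordered:
            if j - i < 3:
                continue
            parallel = (hbond(i - 1, j) and hbond(j, i + 1)) or (hbond(j - 1, i) and hbond(i, j + 1))
            antiparallel = (hbond(i, j) and hbond(j, i)) or (hbond(i - 1, j + 1) and hbond(j - 1, i + 1))
            if parallel or antiparallel:
                for k in (i, j):
                    if states.get(k) == "C":
                        states[k] = "E"
    return states


@dataclass
class SecondaryStructureProfile:
    residues: list[int]
    per_model: list[str]  # one state string per model
    frequency: dict[int, dict[str, float]]  # residue -> state -> fraction of models


def secondary_structure_profile(ensemble: StructureEnsemble) -> SecondaryStructureProfile:
    """Per-model state strings and per-residue state frequencies."""
    residues = None
    per_model, assignments = [], []
    for m in range(ensemble.n_models):
        states = secondary_structure(ensemble, model=m)
        if residues is None:
            residues = sorted(states)
        assignments.append(states)
        per_model.append("".join(states.get(r, "C") for r in residues))
    frequency = {
        r: {s: sum(a.get(r) == s for a in assignments) / len(assignments) for s in "HEC"}
        for r in residues
    }
    return SecondaryStructureProfile(residues=residues, per_model=per_model, frequency=frequency)


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake-Rupley)
# ---------------------------------------------------------------------------

_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
              "P": 1.80, "Zn": 1.39, "Se": 1.90}
_DEFAULT_RADIUS = 1.70
_N_SPHERE_POINTS = 960


@lru_cache(maxsize=4)
def _sphere_points(n: int) -> np.ndarray:
    """Deterministic, approximately uniform points on the unit sphere
    (Fibonacci spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + np.sqrt(5.0)) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def shrake_rupley(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
                  n_points: int = _N_SPHERE_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Angstrom^2).

    Numeric Shrake-Rupley quadrature on a fixed point set: for each atom,
    the fraction of ``n_points`` test points on its solvent-expanded sphere
    not buried inside any neighbor's expanded sphere times the sphere area.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    expanded = radii + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_expanded = expanded.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        points = coords[i] + expanded[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], expanded[i] + max_expanded)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            accessible &= np.sum((points - coords[j]) ** 2, axis=1) > expanded[j] ** 2
            if not accessible.any():
                break
        areas[i] = accessible.mean() * 4 * np.pi * expanded[i] ** 2
    return areas


@dataclass(frozen=True)
class AccessibilityRecord:
    residue_index: int
    residue_name: str
    sidechain_sasa: float  # Angstrom^2, absolute
    relative_exposure: float  # fraction of the extended Gly-X-Gly reference; nan for Gly
    buried: bool


_SIDECHAIN_EXCLUDE = {"N", "CA", "C", "O", "OXT"}


@lru_cache(maxsize=32)
def _reference_sidechain_sasa(res_name: str, probe: float = 1.4) -> float:
    """Side-chain SASA of X in an extended Gly-X-Gly tripeptide (heavy atoms)."""
    from .io_formats import THREE_TO_ONE
    from .peptide import build_peptide
    letter = THREE_TO_ONE[res_name]
    peptide = build_peptide(f"G{letter}G", sidechains=True, amide_h=False)
    mask = peptide.select(heavy_only=True)
    atoms = [a for a, m in zip(peptide.atoms, mask) if m]
    coords = peptide.coords[0, mask]
    radii = np.array([_VDW_RADII.get(a[3], _DEFAULT_RADIUS) for a in atoms])
    areas = shrake_rupley(coords, radii, probe=probe)
    side = np.array([a[0] == 2 and a[2] not in _SIDECHAIN_EXCLUDE for a in atoms])
    return float(areas[side].sum())


def accessibility(ensemble: StructureEnsemble, model: int = 0, probe: float = 1.4,
                  buried_threshold: float = 0.15) -> list[AccessibilityRecord]:
    """Side-chain solvent accessibility per residue for one model.

    Heavy atoms only; the relative exposure normalizes the side-chain SASA
    by that of the residue type in an extended Gly-X-Gly reference peptide,
    and a side chain is flagged buried below ``buried_threshold`` (default
    15% exposure).  Glycine has no side chain and reports exposure nan,
    never buried.  Unknown elements fall back to a carbon-like radius.
    """
    mask = ensemble.select(heavy_only=True)
    atoms = [a for a, m in zip(ensemble.atoms, mask) if m]
    coords = ensemble.coords[model, mask]
    radii = np.array([_VDW_RADII.get(a[3], _DEFAULT_RADIUS) for a in atoms])
    areas = shrake_rupley(coords, radii, probe=probe)
    records = []
    for res in sorted({a[0] for a in atoms}):
        res_atoms = [(a, area) for a, area in zip(atoms, areas) if a[0] == res]
        res_name = res_atoms[0][0][1]
        side = [area for a, area in res_atoms if a[2] not in _SIDECHAIN_EXCLUDE]
        sasa = float(sum(side))
        if res_name == "GLY" or res_name not in _KNOWN_RESIDUES:
            records.append(AccessibilityRecord(res, res_name, sasa, float("nan"), False))
            continue
        reference = _reference_sidechain_sasa(res_name, probe)
        rel = sasa / reference if reference > 0 else float("nan")
        records.append(AccessibilityRecord(res, res_name, sasa, float(rel),
                                           bool(rel < buried_threshold)))
    return records


_KNOWN_RESIDUES = {"ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "HIS", "ILE",
                   "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"}


# ---------------------------------------------------------------------------
# Surface patch clustering
# ---------------------------------------------------------------------------

@dataclass
class Patch:
    members: list  # site labels as given
    anchor: np.ndarray  # mean CA position of member residues (model average)

    def __len__(self):
        return len(self.members)


def _site_residue(site) -> int:
    """Residue index of a site given as int, (residue, label) tuple or a
    string like ``"94"`` / ``"112sc"``."""
    if isinstance(site, tuple):
        return int(site[0])
    if isinstance(site, str):
        m = re.match(r"(\d+)", site)
        if m is None:
            raise ValueError(site)
        return int(m.group(1))
    return int(site)


def cluster_patches(ensemble: StructureEnsemble, significant_sites,
                    linkage_cutoff: float = 8.0) -> tuple[list[Patch], list[str]]:
    """Single-linkage clustering of significant sites into surface patches.

    Two sites link when the minimum heavy-atom distance between their
    residues, averaged over models, is at most ``linkage_cutoff``; patches
    are the connected components under that relation (equivalently,
    single-linkage clusters cut at the cutoff), sorted by decreasing size.
    Sites whose residue is absent from the ensemble are dropped with a
    warning.  Patches partition the resolvable sites.
    """
    warnings = []
    sites, residues = [], []
    for site in significant_sites:
        try:
            res = _site_residue(site)
        except (ValueError, TypeError):
            warnings.append(f"unparsable site label {site!r}, dropped")
            continue
        if res not in {a[0] for a in ensemble.atoms}:
            warnings.append(f"site {site!r}: residue {res} not in ensemble, dropped")
            continue
        sites.append(site)
        residues.append(res)
    if not sites:
        return [], warnings

    heavy = ensemble.select(heavy_only=True)
    coords_by_res = {}
    for res in set(residues):
        mask = heavy & ensemble.select(residue_indices=[res])
        coords_by_res[res] = ensemble.coords[:, mask, :]

    n = len(sites)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = coords_by_res[residues[i]], coords_by_res[residues[j]]
            per_model = [
                np.sqrt(((a[m][:, None, :] - b[m][None, :, :]) ** 2).sum(-1)).min()
                for m in range(ensemble.n_models)
            ]
            dist[i, j] = dist[j, i] = float(np.mean(per_model))

    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= linkage_cutoff:
                parent[find(i)] = find(j)

    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    patches = []
    ca_mask = ensemble.select(atom_names=("CA",))
    ca_res = [a[0] for a, m in zip(ensemble.atoms, ca_mask) if m]
    ca_coords = ensemble.coords[:, ca_mask, :].mean(axis=0)
    for members in groups.values():
        member_res = {residues[i] for i in members}
        anchor_pts = [ca_coords[k] for k, res in enumerate(ca_res) if res in member_res]
        anchor = np.mean(anchor_pts, axis=0) if anchor_pts else np.full(3, np.nan)
        patches.append(Patch(members=sorted((sites[i] for i in members), key=str),
                             anchor=anchor))
    patches.sort(key=lambda p: (-len(p), str(p.members)))
    return patches, warnings
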