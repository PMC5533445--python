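"""Ground-truth generators for every input class of the analysis chain.

All generators are pure functions of their parameters and an explicit seed
(one ``numpy`` Generator per call, no global state), so identical inputs
yield bit-identical outputs.  They emulate:

* monoexponential relaxation decays with Gaussian intensity noise, on the
  delay grids typical of 2D-detected R1 (19 delays, 10-646 ms) and R1rho
  (18 delays, 6-100 ms) experiments,
* fast-exchange 1:1-binding titrations, with the bound fraction from the
  exact binding quadratic and observed shifts population-weighted,
* idealized multi-model coordinate ensembles (helix, antiparallel hairpin,
  helix with a disordered tail) with Gaussian coordinate jitter,
* NOE-style restraint lists derived from a structure's own contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .io_formats import Restraint, RestraintList, StructureEnsemble
from .peptide import HELIX_DIHEDRALS, STRAND_DIHEDRALS, build_peptide
from .relaxation import RelaxationSeries
from .shift_analysis import TitrationSeries

__all__ = [
    "R1_DELAYS",
    "R1RHO_DELAYS",
    "BindingModel",
    "EnsembleRecipe",
    "gen_relaxation_series",
    "gen_titration",
    "gen_ensemble",
    "gen_restraints_from_structure",
    "bound_fraction",
]

#: Default relaxation delay grids in seconds.
R1_DELAYS = np.linspace(0.010, 0.646, 19)
R1RHO_DELAYS = np.linspace(0.006, 0.100, 18)


def gen_relaxation_series(rate: float, i0: float, delays=None,
                          noise_sigma: float = 0.0, seed: int = 0,
                          residue_index: int = 1) -> RelaxationSeries:
    """I(t) = I0 exp(-R t) plus Gaussian noise, seeded and reproducible."""
    delays = np.asarray(R1_DELAYS if delays is None else delays, dtype=float)
    if delays.size == 0:
        raise ValueError("empty delay grid")
    rng = np.random.default_rng(seed)
    intensities = i0 * np.exp(-rate * delays)
    if noise_sigma > 0:
        intensities = intensities + rng.normal(0.0, noise_sigma, size=delays.size)
    return RelaxationSeries(residue_index=residue_index, delays=delays,
                            intensities=intensities, noise_sigma=noise_sigma or None)


# ---------------------------------------------------------------------------
# Titrations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingModel:
    """Fast-exchange 1:1 binding: Kd, protein concentration, and the
    maximal (delta_H, delta_N) shift change per perturbed site."""

    kd: float  # micromolar
    protein_concentration: float = 200.0  # micromolar
    max_shifts: dict = field(default_factory=dict)  # site -> (ddH_max, ddN_max), ppm
    equivalents: tuple = (0.0, 0.25, 0.5, 1.0, 2.0)

    def __post_init__(self):
        if self.kd <= 0 or self.protein_concentration <= 0:
            raise ValueError("kd and protein concentration must be positive")


def bound_fraction(p_total: float, l_total: float, kd: float) -> float:
    """Exact bound fraction of the protein for 1:1 binding."""
    if l_total == 0:
        return 0.0
    s = p_total + l_total + kd
    return (s - np.sqrt(s * s - 4 * p_total * l_total)) / (2 * p_total)


def gen_titration(model: BindingModel, static_sites=(), seed: int = 0,
                  shift_noise: float = 0.0) -> TitrationSeries:
    """Titration series under fast exchange.

    Sites named in ``model.max_shifts`` move toward their bound-state shifts
    proportionally to the bound fraction; ``static_sites`` are carried along
    unshifted (controls).  Free-state amide positions are drawn once from
    typical ranges (seeded); optional Gaussian ``shift_noise`` (ppm, applied
    to both dimensions) perturbs every non-reference point.
    """
    rng = np.random.default_rng(seed)
    sites = list(model.max_shifts) + [s for s in static_sites if s not in model.max_shifts]
    eqs = np.asarray(model.equivalents, dtype=float)
    p = model.protein_concentration
    fractions = np.array([bound_fraction(p, eq * p, model.kd) for eq in eqs])
    shifts = {}
    for site in sites:
        free = np.array([rng.uniform(7.5, 9.5), rng.uniform(105.0, 130.0)])
        dmax = np.asarray(model.max_shifts.get(site, (0.0, 0.0)), dtype=float)
        traj = free[None, :] + fractions[:, None] * dmax[None, :]
        if shift_noise > 0:
            noise = rng.normal(0.0, shift_noise, size=traj.shape)
            noise[0] = 0.0  # the apo reference defines the origin
            traj = traj + noise
        shifts[site] = traj
    return TitrationSeries(equivalents=eqs, shifts=shifts,
                           protein_concentration=p)


# ---------------------------------------------------------------------------
# Coordinate ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnsembleRecipe:
    """Recipe for an idealized jittered ensemble.

    ``topology`` is one of ``helix``, ``hairpin``, ``helix+tail``; the tail
    (last ``tail_length`` residues, default a quarter of the chain) receives
    ``tail_sigma`` jitter, everything else ``core_sigma``.
    """

    topology: str = "helix"
    length: int = 16
    core_sigma: float = 0.0  # Angstrom
    tail_sigma: float = 0.0
    n_models: int = 1
    seed: int = 0
    sequence: str | None = None
    tail_length: int | None = None
    sidechains: bool = False
    start_index: int = 1

    def __post_init__(self):
        if self.topology not in ("helix", "hairpin", "helix+tail"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.core_sigma < 0 or self.tail_sigma < 0:
            raise ValueError("jitter sigma must be non-negative")
        if self.n_models < 1:
            raise ValueError("need at least one model")


@lru_cache(maxsize=8)
def _hairpin_transform(n_per_strand: int):
    """Rigid placement (rotation, translation) of the partner strand of an
    ideal antiparallel two-strand sheet.

    The placement minimizes the squared deviation of the intended
    inter-strand hydrogen-bond geometry (H...O 1.90 A, N...O 2.90 A for
    every other residue pair, both donor directions) plus a CA clash
    penalty, over the full 6-DOF rigid motion; the optimization is
    deterministic (fixed starts, Nelder-Mead).
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    base = build_peptide("A" * n_per_strand, [STRAND_DIHEDRALS] * n_per_strand,
                         sidechains=False, amide_h=True)
    coords = base.coords[0]
    index = {(r, a): k for k, (r, _, a, _) in enumerate(base.atoms)}
    # antiparallel register: residue i pairs with residue n+1-i of the partner
    pairs = [(i, n_per_strand + 1 - i) for i in range(2, n_per_strand + 1, 2)]
    ca = np.stack([coords[index[(i, "CA")]] for i in range(1, n_per_strand + 1)])

    def cost(params):
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        moved = coords @ rot.T + params[3:]
        c = 0.0
        for i, j in pairs:
            for donor, acceptor in ((coords, moved), (moved, coords)):
                di, ai = (i, j) if donor is coords else (j, i)
                if (di, "H") in index:
                    c += (np.linalg.norm(donor[index[(di, "H")]] - acceptor[index[(ai, "O")]]) - 1.90) ** 2
                    c += (np.linalg.norm(donor[index[(di, "N")]] - acceptor[index[(ai, "O")]]) - 2.90) ** 2
        ca_b = ca @ rot.T + params[3:]
        d = np.sqrt(((ca[:, None, :] - ca_b[None, :, :]) ** 2).sum(-1))
        c += np.sum(np.clip(4.2 - d, 0.0, None) ** 2)
        return c

    flip = Rotation.from_matrix(np.diag([-1.0, -1.0, 1.0])).as_rotvec()
    best = (np.inf, None)
    for tx in (0.0, 3.0, 6.0, 9.0, 12.0):
        for ty in (4.8, -4.8):
            x0 = np.concatenate([flip, [tx, ty, 0.0]])
            res = minimize(cost, x0, method="Nelder-Mead",
                           options=dict(maxiter=4000, xatol=1e-6, fatol=1e-9))
            if res.fun < best[0]:
                best = (res.fun, res.x)
    rot = Rotation.from_rotvec(best[1][:3]).as_matrix()
    return rot, best[1][3:].copy()


def _base_model(recipe: EnsembleRecipe) -> StructureEnsemble:
    length = recipe.length
    sequence = recipe.sequence or "A" * length
    if len(sequence) != length:
        raise ValueError("sequence length must match recipe length")
    if recipe.topology == "helix":
        return build_peptide(sequence, [HELIX_DIHEDRALS] * length,
                             start_index=recipe.start_index,
                             sidechains=recipe.sidechains)
    if recipe.topology == "helix+tail":
        tail = recipe.tail_length or max(length // 4, 2)
        dihedrals = [HELIX_DIHEDRALS] * (length - tail) + [STRAND_DIHEDRALS] * tail
        return build_peptide(sequence, dihedrals, start_index=recipe.start_index,
                             sidechains=recipe.sidechains)
    # hairpin: two antiparallel strands separated by a 2-residue numbering gap
    n = length // 2
    seq_a, seq_b = sequence[:n], sequence[n:2 * n]
    strand_a = build_peptide(seq_a, [STRAND_DIHEDRALS] * n,
                             start_index=recipe.start_index, sidechains=recipe.sidechains)
    strand_b = build_peptide(seq_b, [STRAND_DIHEDRALS] * n,
                             start_index=recipe.start_index + n + 2,
                             sidechains=recipe.sidechains)
    rot, trans = _hairpin_transform(n)
    coords_b = strand_b.coords[0] @ rot.T + trans
    atoms = strand_a.atoms + strand_b.atoms
    coords = np.concatenate([strand_a.coords[0], coords_b])[None]
    return StructureEnsemble(atoms=atoms, coords=coords)


def gen_ensemble(recipe: EnsembleRecipe) -> StructureEnsemble:
    """Idealized backbone ensemble with per-model Gaussian coordinate jitter.

    With zero sigma all models are identical copies of the idealized
    conformer.  For ``helix+tail`` the last ``tail_length`` residues receive
    ``tail_sigma``; all other residues (and other topologies) receive
    ``core_sigma``.
    """
    base = _base_model(recipe)
    rng = np.random.default_rng(recipe.seed)
    res_ids = np.array([a[0] for a in base.atoms])
    sigma = np.full(len(base.atoms), recipe.core_sigma)
    if recipe.topology == "helix+tail":
        tail = recipe.tail_length or max(recipe.length // 4, 2)
        tail_start = recipe.start_index + recipe.length - tail
        sigma[res_ids >= tail_start] = recipe.tail_sigma
    coords = np.repeat(base.coords, recipe.n_models, axis=0)
    # sigma is the per-atom RMS displacement, so each coordinate gets sigma/sqrt(3)
    noise = rng.normal(0.0, 1.0, size=coords.shape) * (sigma[None, :, None] / np.sqrt(3.0))
    return StructureEnsemble(atoms=list(base.atoms), coords=coords + noise)


# ---------------------------------------------------------------------------
# Structure-derived restraints
# ---------------------------------------------------------------------------

def gen_restraints_from_structure(ensemble: StructureEnsemble,
                                  contact_cutoff: float = 5.0,
                                  slack: float = 0.2) -> RestraintList:
    """NOE-style upper limits from every inter-residue heavy-atom contact in
    model 1: upper bound = observed distance + slack, lower bound 0."""
    from scipy.spatial import cKDTree

    mask = ensemble.select(heavy_only=True)
    atoms = [a for a, m in zip(ensemble.atoms, mask) if m]
    coords = ensemble.coords[0, mask]
    tree = cKDTree(coords)
    restraints = []
    for i, j in sorted(tree.query_pairs(contact_cutoff)):
        ai, aj = atoms[i], atoms[j]
        if ai[0] == aj[0]:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        restraints.append(Restraint(ai[0], ai[1], ai[2], aj[0], aj[1], aj[2],
                                    0.0, d + slack, kind="NOE"))
    return RestraintList(restraints=restraints)
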