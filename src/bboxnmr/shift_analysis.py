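"""Chemical-shift-based inference.

Composite amide chemical-shift perturbations (CSPs) combine the proton and
nitrogen shift changes of an amide group as

    csp = sqrt( d_H^2 + (d_N / 6.5)^2 )

where the nitrogen scale factor compensates for the wider 15N shift
dispersion.  The module also follows per-site CSPs along a titration,
classifies secondary structure from chemical-shift-index (CSI) deviations
versus random-coil values, and provides a configurable logistic score for
cysteine zinc coordination based on CA/CB shifts (a metal-bound Cys CB moves
downfield by several ppm relative to the free reduced state).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Peak, PeakList, ShiftTable

__all__ = [
    "NITROGEN_SCALE",
    "CSPRecord",
    "CSPResult",
    "TitrationSeries",
    "TitrationResult",
    "SecondaryAssignment",
    "ZincScore",
    "RANDOM_COIL_SHIFTS",
    "random_coil_table",
    "compute_csp",
    "select_significant",
    "titration_trajectory",
    "csi_classify",
    "zinc_probability",
]

#: Default nitrogen scale factor of the composite CSP.
NITROGEN_SCALE = 6.5
#: Default significance cutoff (ppm) on the composite CSP.
CSP_CUTOFF = 0.10


@dataclass(frozen=True)
class CSPRecord:
    residue_index: int
    site_label: str  # "bb" backbone amide, "sc" side chain
    delta_h: float  # ppm
    delta_n: float  # ppm
    csp: float  # ppm, composite

    def __post_init__(self):
        if self.csp < 0:
            raise ValueError("composite CSP cannot be negative")


@dataclass
class CSPResult:
    records: list[CSPRecord] = field(default_factory=list)
    unmatched: list[tuple[int, str, str]] = field(default_factory=list)  # (res, site, which list)
    warnings: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _amide_shifts(peak: Peak) -> tuple[float, float]:
    """Return (delta_H, delta_N) of a peak regardless of dimension order."""
    if peak.atom1.startswith("N"):
        return peak.position2, peak.position1
    if peak.atom1.startswith("H"):
        return peak.position1, peak.position2
    raise ValueError(f"cannot orient peak dimensions for atoms {peak.atom1}-{peak.atom2}")


def composite_csp(delta_h: float, delta_n: float,
                  nitrogen_scale: float = NITROGEN_SCALE) -> float:
    return float(np.hypot(delta_h, delta_n / nitrogen_scale))


def compute_csp(apo: PeakList, bound: PeakList,
                nitrogen_scale: float = NITROGEN_SCALE) -> CSPResult:
    """Composite CSP per site matched between an apo and a bound peak list.

    Sites are matched on (residue_index, site_label); peaks present in only
    one list are reported in ``result.unmatched`` rather than silently
    dropped.  An empty match set yields an empty result with a warning.
    """
    apo_sites = apo.by_site()
    bound_sites = bound.by_site()
    result = CSPResult()
    for key in sorted(set(apo_sites) | set(bound_sites)):
        if key not in apo_sites:
            result.unmatched.append((key[0], key[1], "bound-only"))
            continue
        if key not in bound_sites:
            result.unmatched.append((key[0], key[1], "apo-only"))
            continue
        h_apo, n_apo = _amide_shifts(apo_sites[key])
        h_bound, n_bound = _amide_shifts(bound_sites[key])
        dh, dn = h_bound - h_apo, n_bound - n_apo
        result.records.append(CSPRecord(key[0], key[1], dh, dn,
                                        composite_csp(dh, dn, nitrogen_scale)))
    if not result.records:
        result.warnings.append("no sites matched between the two peak lists")
    return result


def select_significant(records, cutoff: float = CSP_CUTOFF) -> set[tuple[int, str]]:
    """Sites with composite CSP at or above the cutoff (inclusive)."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    return {(r.residue_index, r.site_label) for r in records if r.csp >= cutoff}


# ---------------------------------------------------------------------------
# Titrations
# ---------------------------------------------------------------------------

@dataclass
class TitrationSeries:
    """Per-site (delta_H, delta_N) trajectories over a titration.

    ``shifts`` maps (residue_index, site_label) to an array of shape
    (n_points, 2) holding (delta_H, delta_N) at each titration point; the
    first point is the apo reference.
    """

    equivalents: np.ndarray
    shifts: dict[tuple[int, str], np.ndarray]
    protein_concentration: float = 200.0  # micromolar

    def __post_init__(self):
        self.equivalents = np.asarray(self.equivalents, dtype=float)
        if np.any(self.equivalents < 0):
            raise ValueError("equivalents must be non-negative")
        if np.any(np.diff(self.equivalents) <= 0):
            raise ValueError("equivalents must be strictly increasing")
        if self.equivalents[0] != 0:
            raise ValueError("first titration point must be the apo reference (0 equivalents)")
        for key, arr in self.shifts.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.equivalents.size, 2):
                raise ValueError(f"site {key}: expected shape ({self.equivalents.size}, 2)")
            self.shifts[key] = arr


@dataclass
class TitrationResult:
    equivalents: np.ndarray
    csp: dict[tuple[int, str], np.ndarray]  # per site, csp vs equivalents
    non_monotone: set[tuple[int, str]]


def titration_trajectory(series: TitrationSeries,
                         nitrogen_scale: float = NITROGEN_SCALE,
                         noise_floor: float = 0.0) -> TitrationResult:
    """Composite CSP of every site at every titration point versus the apo
    reference; a site is flagged non-monotone when its CSP decreases by more
    than ``noise_floor`` between consecutive points (under fast exchange the
    trajectory should be non-decreasing in ligand equivalents)."""
    if series.equivalents.size < 2:
        raise ValueError("need at least two titration points")
    csp = {}
    flagged = set()
    for key, arr in series.shifts.items():
        deltas = arr - arr[0]
        values = np.hypot(deltas[:, 0], deltas[:, 1] / nitrogen_scale)
        csp[key] = values
        if np.any(np.diff(values) < -noise_floor):
            flagged.add(key)
    return TitrationResult(series.equivalents.copy(), csp, flagged)


# ---------------------------------------------------------------------------
# Chemical shift index
# ---------------------------------------------------------------------------

#: Random-coil chemical shifts (ppm) per residue type, neighbor-uncorrected
#: consensus values for N, H, HA, CA, CB and carbonyl C.  The table is
#: swappable: any ShiftTable may serve as the random-coil reference.
RANDOM_COIL_SHIFTS: dict[str, dict[str, float]] = {
    "ALA": {"N": 123.8, "H": 8.24, "HA": 4.32, "CA": 52.5, "CB": 19.1, "C": 177.8},
    "ARG": {"N": 120.5, "H": 8.23, "HA": 4.34, "CA": 56.0, "CB": 30.9, "C": 176.3},
    "ASN": {"N": 118.7, "H": 8.40, "HA": 4.74, "CA": 53.1, "CB": 38.9, "C": 175.2},
    "ASP": {"N": 120.4, "H": 8.34, "HA": 4.64, "CA": 54.2, "CB": 41.1, "C": 176.3},
    "CYS": {"N": 118.8, "H": 8.32, "HA": 4.55, "CA": 58.2, "CB": 28.0, "C": 174.6},
    "GLN": {"N": 119.8, "H": 8.32, "HA": 4.34, "CA": 55.7, "CB": 29.4, "C": 176.0},
    "GLU": {"N": 120.2, "H": 8.42, "HA": 4.35, "CA": 56.6, "CB": 29.9, "C": 176.6},
    "GLY": {"N": 108.8, "H": 8.33, "HA": 3.96, "CA": 45.1, "CB": np.nan, "C": 174.9},
    "HIS": {"N": 118.2, "H": 8.42, "HA": 4.73, "CA": 55.0, "CB": 29.0, "C": 174.1},
    "ILE": {"N": 119.9, "H": 8.00, "HA": 4.17, "CA": 61.1, "CB": 38.8, "C": 176.4},
    "LEU": {"N": 121.8, "H": 8.16, "HA": 4.34, "CA": 55.1, "CB": 42.4, "C": 177.6},
    "LYS": {"N": 120.4, "H": 8.29, "HA": 4.32, "CA": 56.2, "CB": 33.1, "C": 176.6},
    "MET": {"N": 119.6, "H": 8.28, "HA": 4.48, "CA": 55.4, "CB": 32.9, "C": 176.3},
    "PHE": {"N": 120.3, "H": 8.30, "HA": 4.62, "CA": 57.7, "CB": 39.6, "C": 175.8},
    "PRO": {"N": 135.0, "H": np.nan, "HA": 4.42, "CA": 63.3, "CB": 32.1, "C": 177.3},
    "SER": {"N": 115.7, "H": 8.31, "HA": 4.47, "CA": 58.3, "CB": 63.8, "C": 174.6},
    "THR": {"N": 113.6, "H": 8.15, "HA": 4.35, "CA": 61.8, "CB": 69.8, "C": 174.7},
    "TRP": {"N": 121.3, "H": 8.25, "HA": 4.66, "CA": 57.5, "CB": 29.6, "C": 176.1},
    "TYR": {"N": 120.3, "H": 8.12, "HA": 4.55, "CA": 57.9, "CB": 38.8, "C": 175.9},
    "VAL": {"N": 119.2, "H": 8.03, "HA": 4.12, "CA": 62.2, "CB": 32.9, "C": 176.3},
}

#: Per-atom CSI thresholds (ppm) and the sign of helix evidence for a
#: positive deviation: CA moves downfield in helices, HA upfield; CB is a
#: strand-only indicator.
CSI_THRESHOLDS = {"CA": 0.7, "CB": 0.7, "HA": 0.1}
_CONSENSUS_RUN = 4


def random_coil_table(sequence: str, start_index: int = 1) -> ShiftTable:
    """Random-coil reference ShiftTable for a one-letter sequence."""
    from .io_formats import ONE_TO_THREE, ShiftRecord
    records = []
    for offset, letter in enumerate(sequence):
        name = ONE_TO_THREE[letter.upper()]
        for atom, value in RANDOM_COIL_SHIFTS[name].items():
            if np.isfinite(value):
                records.append(ShiftRecord(start_index + offset, name, atom, value))
    return ShiftTable(records=records)


@dataclass
class SecondaryAssignment:
    states: dict[int, str]  # residue -> H/E/C
    indices: dict[int, dict[str, int]]  # residue -> per-atom -1/0/+1 trace
    warnings: list[str] = field(default_factory=list)

    def state_string(self) -> str:
        return "".join(self.states[r] for r in sorted(self.states))


def _atom_votes(residue: int, shifts: ShiftTable, coil: ShiftTable):
    """Per-atom index trace and the residue-level helix(+1)/strand(-1) vote."""
    trace = {}
    vote = 0
    for atom in ("CA", "CB", "HA"):
        obs, ref = shifts.get(residue, atom), coil.get(residue, atom)
        if obs is None or ref is None:
            continue
        delta = obs - ref
        thr = CSI_THRESHOLDS[atom]
        idx = 1 if delta > thr else (-1 if delta < -thr else 0)
        trace[atom] = idx
        if atom == "CA":
            vote += idx  # downfield CA: helix; upfield: strand
        elif atom == "CB":
            vote -= max(idx, 0)  # downfield CB: strand evidence only
        elif atom == "HA":
            vote -= idx  # upfield HA: helix; downfield: strand
    return trace, int(np.sign(vote))


def csi_classify(shifts: ShiftTable, random_coil: ShiftTable) -> SecondaryAssignment:
    """Chemical-shift-index secondary structure.

    Per-residue evidence is the signed consensus of CA, CB and HA deviations
    from random coil (threshold 0.7 ppm for carbons, 0.1 ppm for HA); a
    helix or strand is called only for runs of >= 4 consecutive residues
    with the same non-coil sign, everything else is coil.  Residues without
    a CA shift in both tables are skipped with a warning.  Classification
    depends only on shift differences, so a referencing offset applied to
    both tables cancels.
    """
    warnings = []
    residues = []
    votes = {}
    traces = {}
    for res in shifts.residues():
        if shifts.get(res, "CA") is None or random_coil.get(res, "CA") is None:
            warnings.append(f"residue {res}: no CA shift in both tables, skipped")
            continue
        trace, vote = _atom_votes(res, shifts, random_coil)
        residues.append(res)
        votes[res] = vote
        traces[res] = trace

    states = {res: "C" for res in residues}
    run = []
    for res in residues + [None]:
        sign = votes.get(res) if res is not None else None
        if run and (res is None or sign != votes[run[-1]] or res != run[-1] + 1):
            if len(run) >= _CONSENSUS_RUN and votes[run[0]] != 0:
                label = "H" if votes[run[0]] > 0 else "E"
                for r in run:
                    states[r] = label
            run = []
        if res is not None:
            run.append(res)
    return SecondaryAssignment(states=states, indices=traces, warnings=warnings)


# ---------------------------------------------------------------------------
# Cysteine zinc-coordination score
# ---------------------------------------------------------------------------

#: Default (CA, CB) reference centroids in ppm and logistic steepness in
#: ppm^-1.  These are configurable surrogates, not a calibrated probability
#: model: the score orders candidate cysteines along the free-reduced to
#: metal-bound axis in (CA, CB) shift space.
ZINC_FREE_CENTROID = (59.0, 28.0)
ZINC_BOUND_CENTROID = (58.5, 31.5)
ZINC_STEEPNESS = 1.5


@dataclass(frozen=True)
class ZincScore:
    residue_index: int
    score: float
    ca_shift: float
    cb_shift: float

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


def zinc_probability(shifts: ShiftTable, residues,
                     free_centroid=ZINC_FREE_CENTROID,
                     bound_centroid=ZINC_BOUND_CENTROID,
                     steepness: float = ZINC_STEEPNESS) -> tuple[list[ZincScore], list[str]]:
    """Logistic zinc-coordination score per queried cysteine.

    The score is sigmoid(k * s) where s is the signed distance of the
    residue's (CA, CB) point along the axis from the free-reduced centroid
    to the metal-bound centroid, measured from the perpendicular bisector of
    the two centroids (score 0.5 exactly on the bisector).  Residues missing
    a CA or CB shift are omitted with a warning.
    """
    free = np.asarray(free_centroid, dtype=float)
    bound = np.asarray(bound_centroid, dtype=float)
    axis = bound - free
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("centroids must differ")
    axis /= norm
    midpoint = (free + bound) / 2
    scores, warnings = [], []
    for res in residues:
        ca, cb = shifts.get(res, "CA"), shifts.get(res, "CB")
        if ca is None or cb is None:
            warnings.append(f"residue {res}: missing CA or CB shift, score omitted")
            continue
        s = float(np.dot(np.array([ca, cb]) - midpoint, axis))
        score = float(1.0 / (1.0 + np.exp(-steepness * s)))
        scores.append(ZincScore(res, score, ca, cb))
    return scores, warnings
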