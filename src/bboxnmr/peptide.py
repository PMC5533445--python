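"""Idealized peptide construction from backbone dihedrals.

Backbones are grown atom by atom with the standard internal-coordinate
(NeRF) construction using canonical bond lengths and angles; carbonyl
oxygens and amide protons are placed geometrically and side chains are
grafted from the chemical-component-dictionary templates bundled with
biotite by superimposing each template's N/CA/C frame onto the built
backbone.  The module backs the synthetic ensemble generator and the
extended Gly-X-Gly reference peptides used to normalize side-chain solvent
accessibility.
"""

from __future__ import annotations

import numpy as np
import biotite.structure.info as struc_info

from .io_formats import ONE_TO_THREE, StructureEnsemble

__all__ = [
    "place_atom",
    "build_backbone",
    "build_peptide",
    "HELIX_DIHEDRALS",
    "STRAND_DIHEDRALS",
]

# Canonical backbone geometry (Angstrom / degrees).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.01
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8

HELIX_DIHEDRALS = (-57.0, -47.0)
STRAND_DIHEDRALS = (-139.0, 135.0)

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


def place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Position atom D from reference atoms A-B-C, the C-D bond length, the
    B-C-D angle and the A-B-C-D dihedral (degrees)."""
    angle = np.deg2rad(angle)
    dihedral = np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(dihedrals) -> list[dict[str, np.ndarray]]:
    """Grow an N/CA/C/O backbone for per-residue (phi, psi) pairs.

    The first residue's phi and the last residue's psi only affect O
    placement.  Returns one dict of atom positions per residue.
    """
    dihedrals = [(float(phi), float(psi)) for phi, psi in dihedrals]
    n_res = len(dihedrals)
    if n_res == 0:
        return []
    residues = [dict() for _ in range(n_res)]
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues[0].update(N=n0, CA=ca0, C=c0)
    for i in range(n_res - 1):
        _, psi = dihedrals[i]
        phi_next = dihedrals[i + 1][0]
        n_i, ca_i, c_i = residues[i]["N"], residues[i]["CA"], residues[i]["C"]
        n_next = place_atom(n_i, ca_i, c_i, _B_C_N, _A_CA_C_N, psi)
        ca_next = place_atom(ca_i, c_i, n_next, _B_N_CA, _A_C_N_CA, 180.0)  # omega trans
        c_next = place_atom(c_i, n_next, ca_next, _B_CA_C, _A_N_CA_C, phi_next)
        residues[i + 1].update(N=n_next, CA=ca_next, C=c_next)
    for i in range(n_res):
        psi = dihedrals[i][1]
        res = residues[i]
        # O anti to the next amide nitrogen about the CA-C axis
        res["O"] = place_atom(res["N"], res["CA"], res["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
    return residues


def _amide_proton(n, ca, c_prev) -> np.ndarray:
    u = (n - c_prev) / np.linalg.norm(n - c_prev) + (n - ca) / np.linalg.norm(n - ca)
    return n + _B_N_H * u / np.linalg.norm(u)


def _sidechain_template(res_name: str):
    tmpl = struc_info.residue(res_name)
    heavy = tmpl[(tmpl.element != "H")]
    frame = {}
    for name in ("N", "CA", "C"):
        frame[name] = heavy.coord[heavy.atom_name == name][0]
    side_mask = ~np.isin(heavy.atom_name, list(_BACKBONE_NAMES))
    return frame, heavy.atom_name[side_mask].tolist(), heavy.coord[side_mask], heavy.element[side_mask].tolist()


def _kabsch(moving: np.ndarray, fixed: np.ndarray):
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, fc - rot @ mc


def build_peptide(sequence: str, dihedrals=None, start_index: int = 1,
                  sidechains: bool = True, amide_h: bool = True) -> StructureEnsemble:
    """Build a single-model idealized peptide.

    ``sequence`` is one-letter; ``dihedrals`` one (phi, psi) per residue
    (default: extended strand).  With ``sidechains`` the full heavy-atom
    side chains are grafted from ideal residue templates, otherwise only CB
    is kept.  Amide protons (all residues but the first; none for Pro) are
    included when ``amide_h`` is set.
    """
    sequence = sequence.upper()
    if dihedrals is None:
        dihedrals = [STRAND_DIHEDRALS] * len(sequence)
    if len(dihedrals) != len(sequence):
        raise ValueError("need one (phi, psi) pair per residue")
    backbone = build_backbone(dihedrals)
    atoms, coords = [], []
    for i, letter in enumerate(sequence):
        res_name = ONE_TO_THREE[letter]
        res_id = start_index + i
        bb = backbone[i]
        for name in ("N", "CA", "C", "O"):
            atoms.append((res_id, res_name, name, name[0]))
            coords.append(bb[name])
        if amide_h and i > 0 and res_name != "PRO":
            atoms.append((res_id, res_name, "H", "H"))
            coords.append(_amide_proton(bb["N"], bb["CA"], backbone[i - 1]["C"]))
        if res_name != "GLY":
            frame, side_names, side_coords, side_elements = _sidechain_template(res_name)
            rot, trans = _kabsch(np.stack([frame["N"], frame["CA"], frame["C"]]),
                                 np.stack([bb["N"], bb["CA"], bb["C"]]))
            placed = side_coords @ rot.T + trans
            for name, pos, elem in zip(side_names, placed, side_elements):
                if not sidechains and name != "CB":
                    continue
                atoms.append((res_id, res_name, name, elem.capitalize()))
                coords.append(pos)
    return StructureEnsemble(atoms=atoms, coords=np.asarray(coords)[None, :, :])
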