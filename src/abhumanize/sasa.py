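"""Shrake-Rupley solvent-accessible surface area.

Each atom is expanded by the probe radius (water, 1.4 A) and sampled with a
deterministic golden-spiral point set; points falling inside any neighbouring
expanded sphere are occluded. Per-residue SASA is normalized by a bundled
Gly-X-Gly maximum-accessibility table to give relative accessibility in
[0, 1].
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree

from .contacts import StructureModel

logger = logging.getLogger(__name__)

#: van der Waals radii (A) by element; unlisted elements fall back to carbon
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_VDW = 1.70
PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960

#: maximum accessible surface per residue type (A^2), theoretical Gly-X-Gly values
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    indices = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * indices / n)
    theta = np.pi * (1.0 + 5.0**0.5) * indices
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible area (A^2) by Shrake-Rupley sampling."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n_atoms = len(coords)
    expanded = radii + probe
    unit = sphere_points(n_points)
    areas = np.zeros(n_atoms)
    if n_atoms == 0:
        return areas
    tree = cKDTree(coords)
    max_reach = expanded.max()
    for i in range(n_atoms):
        pts = coords[i] + expanded[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], expanded[i] + max_reach) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    return areas


def residue_sasa(
    model: StructureModel,
    probe: float = PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[tuple[str, int, str], float]:
    """Total accessible area (A^2) per residue."""
    atoms = model.atoms
    coords = model.coords()
    radii = np.array([VDW_RADII.get(a.element, DEFAULT_VDW) for a in atoms])
    areas = atom_sasa(coords, radii, probe, n_points)
    out: dict[tuple[str, int, str], float] = {}
    for atom, area in zip(atoms, areas):
        out[atom.residue_key] = out.get(atom.residue_key, 0.0) + float(area)
    return out


def relative_sasa(
    model: StructureModel,
    probe: float = PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[tuple[str, int, str], float]:
    """Per-residue relative accessibility in [0, 1].

    Residue SASA divided by the Gly-X-Gly maximum for its type, clipped to
    [0, 1]; residues of unknown type are skipped with a warning.
    """
    totals = residue_sasa(model, probe, n_points)
    names = model.residue_names()
    out: dict[tuple[str, int, str], float] = {}
    for key, total in totals.items():
        resname = names[key]
        max_asa = MAX_ASA.get(resname)
        if max_asa is None:
            logger.warning("residue %s: unknown type %r, skipped in relative SASA", key, resname)
            continue
        out[key] = float(np.clip(total / max_asa, 0.0, 1.0))
    return out
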