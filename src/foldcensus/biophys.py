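"""Coarse structural properties: solvent accessibility, burial, coil content.

Solvent accessible surface area (SASA) is computed with the
Shrake–Rupley method: a deterministic golden-spiral lattice of test
points is placed on each atom's probe-expanded sphere and the exposed
fraction counted.  Burial fraction — a compactness/globularity proxy —
is one minus the ratio of a structure's SASA to the summed reference
areas of its residues in a maximally exposed state.  Coil fraction is
the share of residues whose secondary-structure code is not helix or
strand.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

#: Bondi (1964) van der Waals radii by element, in Angstrom.
VDW_RADII: Dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70

#: Theoretical maximum accessible surface areas per residue (A^2),
#: Tien et al. 2013, used as the maximally-exposed reference state.
MAX_ASA_TIEN_2013: Dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: DSSP secondary-structure code alphabet (including the extended
#: polyproline 'P' code and unassigned '-'/' '/'C').
DSSP_CODES = frozenset("HGIEBTSPC- ")

#: Codes counted as regular secondary structure; everything else is coil.
DEFAULT_STRUCTURED_CODES = frozenset("HGIEB")


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom with coordinates and a van der Waals radius."""

    residue_index: int
    residue_name: str
    element: str
    coords: Tuple[float, float, float]
    vdw_radius: float

    def __post_init__(self):
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError("coordinates must be finite")


@dataclass(frozen=True)
class ResidueAreaTable:
    """Reference surface area (A^2) of each isolated, maximally exposed
    residue, with provenance recorded for the report."""

    areas: Mapping[str, float]
    provenance: str

    def __post_init__(self):
        if len(self.areas) != 20 or any(v <= 0 for v in self.areas.values()):
            raise ValueError("reference table needs 20 positive entries")

    def __getitem__(self, aa: str) -> float:
        return self.areas[aa]


DEFAULT_AREA_TABLE = ResidueAreaTable(
    areas=MAX_ASA_TIEN_2013,
    provenance="Tien et al. 2013 theoretical maximum ASA",
)


@dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 1.4
    n_sphere_points: int = 960

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_sphere_points < 60:
            raise ValueError("n_sphere_points must be >= 60")


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform lattice of ``n`` points on the unit
    sphere (Fibonacci / golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = phi * i
    return np.column_stack((r * np.cos(theta), r * np.sin(theta), z))


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Center coordinates and rotate them into the principal axes of
    their covariance, with deterministic axis ordering and signs.

    An orthogonal transform preserves all interatomic distances, so
    occlusion geometry is unchanged; it only standardizes how the test
    lattice is oriented relative to the molecule."""
    centered = coords - coords.mean(axis=0)
    if coords.shape[0] < 2:
        return centered
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    # sign fixed by the third moment of the projections — an intrinsic
    # quantity, so the same orientation is chosen before and after any
    # rigid motion of the input
    proj = centered @ evecs
    for j in range(3):
        if np.sum(proj[:, j] ** 3) < 0:
            proj[:, j] = -proj[:, j]
    return proj


def shrake_rupley_sasa(
    atoms: Sequence[AtomRecord], params: SasaParams = SasaParams()
) -> np.ndarray:
    """Per-atom solvent accessible surface area in A^2.

    Each atom's probe-expanded sphere of radius ``r + probe`` carries a
    golden-spiral lattice of test points; a point is accessible when it
    lies outside every other atom's expanded sphere.  The atom's area
    is ``4 pi (r+p)^2`` times its accessible fraction; the molecule's
    SASA is the sum.
    """
    if not atoms:
        raise ValueError("need at least one atom")
    n = len(atoms)
    coords = np.array([a.coords for a in atoms], dtype=float)
    # express coordinates in the molecule's principal-axes frame so the
    # test-point lattice co-rotates with the molecule: the result is then
    # invariant under rigid motions up to floating precision, not merely
    # up to lattice discretization
    coords = _canonical_frame(coords)
    radii = np.array([a.vdw_radius for a in atoms], dtype=float) + params.probe_radius
    sphere = golden_spiral_points(params.n_sphere_points)

    # pairwise neighbor lists: atom j can occlude i only within r_i + r_j
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    cutoff2 = (radii[:, None] + radii[None, :]) ** 2

    areas = np.empty(n)
    for i in range(n):
        neighbors = np.flatnonzero((d2[i] < cutoff2[i]) & (np.arange(n) != i))
        full = 4.0 * math.pi * radii[i] ** 2
        if neighbors.size == 0:
            areas[i] = full
            continue
        pts = coords[i] + radii[i] * sphere  # (n_points, 3)
        diff = pts[:, None, :] - coords[neighbors][None, :, :]
        inside = np.any(
            np.sum(diff * diff, axis=-1) < radii[neighbors][None, :] ** 2, axis=1
        )
        areas[i] = full * float(np.count_nonzero(~inside)) / params.n_sphere_points
    return areas


def total_sasa(
    atoms: Sequence[AtomRecord], params: SasaParams = SasaParams()
) -> float:
    return float(shrake_rupley_sasa(atoms, params).sum())


def burial_fraction(
    atoms: Sequence[AtomRecord],
    sequence: str,
    ref_table: ResidueAreaTable = DEFAULT_AREA_TABLE,
    params: SasaParams = SasaParams(),
) -> float:
    """Fraction of total residue surface area buried in the structure.

    ``1 - SASA(structure) / sum_i ref_area(aa_i)`` where the reference
    is each residue's isolated, maximally exposed area.  Typically in
    [0, 1); a negative value (structure more exposed than the
    reference) is reported with a warning, not clamped.
    """
    residue_indices = sorted({a.residue_index for a in atoms})
    if len(residue_indices) != len(sequence):
        raise ValueError(
            f"sequence length {len(sequence)} != residue count {len(residue_indices)}"
        )
    missing = sorted(set(sequence) - set(ref_table.areas))
    if missing:
        raise ValueError(f"residues missing from reference table: {missing}")
    ref_total = sum(ref_table[aa] for aa in sequence)
    frac = 1.0 - total_sasa(atoms, params) / ref_total
    if frac < 0:
        logger.warning("negative burial fraction %.4f (structure more "
                       "exposed than the reference state)", frac)
    return frac


def coil_fraction(
    ss_string: str,
    structured_codes: frozenset = DEFAULT_STRUCTURED_CODES,
) -> float:
    """Fraction of residues annotated as coil (turn / bend / loop /
    unassigned) in a per-residue secondary-structure string.

    Coil is the complement of the helix and strand codes {H, G, I, E,
    B}; the code set is configurable because "coil" is ambiguous across
    assignment dialects.
    """
    if not ss_string:
        raise ValueError("empty secondary-structure string")
    for pos, code in enumerate(ss_string):
        if code not in DSSP_CODES:
            raise ValueError(f"unknown secondary-structure code {code!r} at position {pos}")
    n_coil = sum(1 for c in ss_string if c not in structured_codes)
    return n_coil / len(ss_string)
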