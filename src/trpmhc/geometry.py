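"""TR docking angle from the matched interface charge ring.

The docking angle theta of a TR on its pMHC is measured here from
electrostatic anatomy rather than from V-domain mass centres: the charged
residues of the pMHC groove that (i) belong to the epitope and (ii) have an
opposite-sign TR partner among their contacts form a ring; projected into
the groove plane the ring is elliptical, and theta is the in-plane angle
between the ellipse's major axis and the peptide's backbone axis.

Conventions:

* the peptide axis is the total-least-squares line through the peptide
  C-alpha atoms, oriented N-terminus to C-terminus;
* the groove plane is the least-squares plane through helix and peptide
  C-alpha atoms, its normal oriented toward the TR side;
* theta is the signed in-plane angle from the projected peptide direction
  to the major axis, reduced modulo 180 degrees, so theta lies in [0, 180)
  and is NOT folded at 90 (a receptor tilted "the other way" across the
  peptide reads, e.g., 112 rather than 68);
* mirror-reflecting a complex maps theta to 180 - theta.

The major axis comes from a 2-D principal-component decomposition of the
projected ring points ("a straight line drawn diagonally across the
ellipse"); near-isotropic rings (axis ratio < 1.05) are flagged
low-confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contacts import ContactMap
from .electrostatics import ChargeSet, PointCharge
from .structures import ChainRole, ComplexStructure

__all__ = [
    "Line3D",
    "Plane3D",
    "ChargeRing",
    "DockingAngleResult",
    "DegenerateGeometryError",
    "RingTooSmallError",
    "peptide_axis",
    "groove_plane",
    "groove_frame",
    "match_complementary_charges",
    "docking_angle",
]


class DegenerateGeometryError(ValueError):
    """Raised when a line or plane fit is underdetermined."""


class RingTooSmallError(ValueError):
    """Raised when fewer than four matched charges survive (ellipse underdetermined)."""


@dataclass(frozen=True)
class Line3D:
    point: tuple[float, float, float]
    direction: tuple[float, float, float]  # unit, oriented

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
            raise ValueError("line direction must be a unit vector")

    @property
    def d(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)


@dataclass(frozen=True)
class Plane3D:
    point: tuple[float, float, float]
    normal: tuple[float, float, float]  # unit

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-9):
            raise ValueError("plane normal must be a unit vector")

    @property
    def n(self) -> np.ndarray:
        return np.asarray(self.normal, dtype=float)

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Right-handed in-plane basis (e1, e2) with e2 = n x e1.

        The seed axis is the global axis least aligned with the normal;
        angles between in-plane vectors are basis-independent, so the
        arbitrary seed does not affect theta.
        """
        n = self.n
        seed = np.eye(3)[int(np.argmin(np.abs(n)))]
        e1 = seed - (seed @ n) * n
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        return e1, e2

    def project(self, xyz: np.ndarray) -> np.ndarray:
        """Project 3-D points to in-plane 2-D coordinates."""
        e1, e2 = self.basis()
        rel = np.atleast_2d(xyz) - np.asarray(self.point)
        return np.column_stack([rel @ e1, rel @ e2])

    def project_direction(self, d: np.ndarray) -> np.ndarray:
        e1, e2 = self.basis()
        v = np.array([d @ e1, d @ e2])
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            raise DegenerateGeometryError("direction is parallel to the plane normal")
        return v / norm


def peptide_axis(peptide: ComplexStructure | np.ndarray) -> Line3D:
    """Total-least-squares line through peptide C-alpha atoms, oriented N->C."""
    if isinstance(peptide, ComplexStructure):
        ca = peptide.ca_array(roles=[ChainRole.PEPTIDE])
        if len(ca) == 0:  # tolerate an unannotated single-chain unit
            ca = peptide.ca_array()
    else:
        ca = np.asarray(peptide, dtype=float).reshape(-1, 3)
    if len(ca) < 3:
        raise DegenerateGeometryError("peptide axis needs at least 3 C-alpha atoms")
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centroid)
    d = vt[0]
    # orient from the chain's N-terminal to C-terminal end
    if d @ (ca[-1] - ca[0]) < 0:
        d = -d
    return Line3D(point=tuple(centroid), direction=tuple(d / np.linalg.norm(d)))


def groove_plane(
    pmhc_unit: ComplexStructure, tr_unit: ComplexStructure | None = None
) -> Plane3D:
    """Least-squares plane through groove-helix and peptide C-alpha atoms.

    With ``tr_unit`` given, the normal is oriented toward the receptor side;
    otherwise its sign is arbitrary (and theta should be read folded).
    """
    ca = pmhc_unit.ca_array()
    if len(ca) < 10:
        raise DegenerateGeometryError("groove plane needs at least 10 C-alpha atoms")
    centroid = ca.mean(axis=0)
    _, s, vt = np.linalg.svd(ca - centroid)
    if s[1] < 1e-9:  # points on a line: plane undetermined
        raise DegenerateGeometryError("C-alpha atoms are collinear; plane undefined")
    n = vt[2]
    if tr_unit is not None:
        toward_tr = tr_unit.coord_array().mean(axis=0) - centroid
        if n @ toward_tr < 0:
            n = -n
    return Plane3D(point=tuple(centroid), normal=tuple(n / np.linalg.norm(n)))


def groove_frame(
    pmhc_unit: ComplexStructure, tr_unit: ComplexStructure | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, t) mapping the complex into the canonical groove frame.

    In the canonical frame the groove plane is z = 0 with the TR side at
    z > 0, the projected peptide axis is +x, and the plane centroid is the
    origin: x' = R @ (x - t).  Sampling potential fields after applying
    this transform puts every complex on a shared grid.
    """
    plane = groove_plane(pmhc_unit, tr_unit)
    pep = peptide_axis(pmhc_unit)
    n = plane.n
    ex = pep.d - (pep.d @ n) * n
    norm = np.linalg.norm(ex)
    if norm < 1e-9:
        raise DegenerateGeometryError("peptide axis is perpendicular to the groove plane")
    ex /= norm
    ey = np.cross(n, ex)
    rot = np.vstack([ex, ey, n])
    return rot, np.asarray(plane.point, dtype=float)


@dataclass
class ChargeRing:
    matched_pairs: list[tuple[PointCharge, PointCharge]]  # (pMHC charge, TR charge)
    ring_points: np.ndarray  # ordered 2-D projections in the groove plane
    plane: Plane3D

    @property
    def n_points(self) -> int:
        return len(self.matched_pairs)


def match_complementary_charges(
    pmhc_q: ChargeSet,
    tr_q: ChargeSet,
    contacts: ContactMap,
    plane: Plane3D,
    pairing_radius: float = 5.0,
) -> ChargeRing:
    """Pair groove charges with opposite-sign TR charges into the ring.

    A pMHC charge enters the ring iff its residue is part of the epitope
    and at least one opposite-sign TR charge (a) sits on a residue among
    its contact partners and (b) lies within ``pairing_radius`` of its
    anchor.  Charges missing from the interacting-residue lists are
    omitted, mirroring the cross-verification step of the angle protocol.
    Ring points are ordered clockwise (when viewed down the plane normal)
    about their centroid.
    """
    epitope_refs = {p.pmhc_residue for p in contacts.pairs}
    tr_by_ref: dict = {}
    for c in tr_q:
        tr_by_ref.setdefault(c.residue_ref, []).append(c)

    matched: list[tuple[PointCharge, PointCharge]] = []
    for mc in pmhc_q:
        if mc.residue_ref not in epitope_refs:
            continue
        partners = contacts.partners_of_pmhc(mc.residue_ref)
        best: tuple[float, PointCharge] | None = None
        for ref in partners:
            for tc in tr_by_ref.get(ref, []):
                if tc.sign == mc.sign:
                    continue
                d = float(np.linalg.norm(mc.xyz - tc.xyz))
                if d <= pairing_radius and (best is None or d < best[0]):
                    best = (d, tc)
        if best is not None:
            matched.append((mc, best[1]))

    if len(matched) < 4:
        raise RingTooSmallError(
            f"only {len(matched)} complementarity-verified charges; "
            "ellipse fit needs at least 4"
        )

    pts = plane.project(np.array([m[0].anchor for m in matched]))
    centred = pts - pts.mean(axis=0)
    # clockwise about the centroid as seen looking down the (TR-side) normal
    order = np.argsort(-np.arctan2(centred[:, 1], centred[:, 0]))
    matched = [matched[i] for i in order]
    return ChargeRing(matched_pairs=matched, ring_points=pts[order], plane=plane)


@dataclass(frozen=True)
class DockingAngleResult:
    complex_id: str
    theta: float  # degrees, [0, 180)
    major_axis: tuple[float, float]  # unit 2-vector in the groove-plane basis
    axis_ratio: float  # major / minor
    n_ring_points: int
    low_confidence: bool = False


def _ring_tr_sides(ring: ChargeRing) -> np.ndarray | None:
    """Per-pair flag: +1 for TR-beta-side partners, -1 for TR-alpha, else None."""
    sides = []
    for _, tc in ring.matched_pairs:
        if tc is None:  # ring built without TR labels (e.g. from bare points)
            return None
        sides.append(tc.chain_id)
    uniq = sorted(set(sides))
    if len(uniq) != 2:
        return None
    return np.array([1.0 if s == uniq[1] else -1.0 for s in sides])


def docking_angle(
    ring: ChargeRing,
    pep: Line3D,
    plane: Plane3D | None = None,
    complex_id: str = "",
    isotropy_ratio: float = 1.05,
) -> DockingAngleResult:
    """Angle between the ring ellipse's major axis and the peptide axis.

    The major axis is the leading principal component of the projected ring
    points.  When the TR partners span two chains the axis is oriented from
    the V-alpha-side to the V-beta-side pair centroid (cosmetic; theta is a
    modulo-180 quantity and does not depend on it).
    """
    plane = plane or ring.plane
    pts = ring.ring_points
    if len(pts) < 4:
        raise RingTooSmallError("ellipse fit needs at least 4 ring points")
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, 1]
    minor_var, major_var = max(evals[0], 1e-12), evals[1]
    axis_ratio = float(np.sqrt(major_var / minor_var))

    sides = _ring_tr_sides(ring)
    if sides is not None:
        proj = centred @ major
        if (proj * sides).sum() < 0:
            major = -major
    elif major[0] < 0:
        major = -major

    pep2d = plane.project_direction(pep.d)
    # signed in-plane angle, then reduced mod 180 (orientation of either
    # vector drops out; the plane-normal orientation fixes handedness)
    cross_z = pep2d[0] * major[1] - pep2d[1] * major[0]
    ang = np.degrees(np.arctan2(cross_z, pep2d @ major))
    theta = float(ang % 180.0)
    low_conf = axis_ratio < isotropy_ratio
    if low_conf:
        warnings.warn(
            f"near-isotropic charge ring (axis ratio {axis_ratio:.3f}); "
            "docking angle is low-confidence",
            stacklevel=2,
        )
    return DockingAngleResult(
        complex_id=complex_id,
        theta=theta,
        major_axis=(float(major[0]), float(major[1])),
        axis_ratio=axis_ratio,
        n_ring_points=len(pts),
        low_confidence=low_conf,
    )
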