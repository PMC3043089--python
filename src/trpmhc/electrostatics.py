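"""Formal charges, screened-Coulomb interface potentials and Hodgkin similarity.

The molecular-surface electrostatic potential (MSEP) of a pMHC interface is
approximated by placing unit formal charges on charged side chains
(Asp/Glu -1, Lys/Arg +1, His configurable) and evaluating a screened
Coulomb (Debye-Hueckel) potential

    phi(x) = sum_i q_i * exp(-kappa * |x - a_i|) / (eps * |x - a_i|)

on a shared set of sample points hovering above the groove plane.  Two
interfaces are compared with the Hodgkin similarity index

    SI(a, b) = 2 <phi_a, phi_b> / (<phi_a, phi_a> + <phi_b, phi_b>)

which is 1 for identical fields, -1 for sign-flipped fields, and is
converted to an electrostatic distance d = sqrt(2 - 2 SI) for clustering.

The uniform-dielectric screened-Coulomb model is a deliberate closed-form
stand-in for a finite-difference Poisson-Boltzmann solver: it preserves the
structure of the similarity analysis (linearity in the charges, shared-grid
inner products) at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .structures import ComplexStructure

__all__ = [
    "ChargeScheme",
    "PointCharge",
    "ChargeSet",
    "PotentialField",
    "SimilarityMatrix",
    "assign_formal_charges",
    "evaluate_potential_field",
    "similarity_matrix",
    "hodgkin_index",
    "electrostatic_distance",
    "shell_grid",
]

#: side-chain atoms whose centroid anchors each residue's formal charge
_ANCHOR_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("CZ",),
    "HIS": ("NE2", "ND1"),
}
_SIGNS = {"ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1, "HIS": +1}


@dataclass(frozen=True)
class ChargeScheme:
    """Which residues carry formal charges and how His/termini are treated."""

    his_charged: bool = False
    include_termini: bool = False  # backbone termini carry no charge by default

    def sign_of(self, residue_name: str) -> int | None:
        if residue_name == "HIS" and not self.his_charged:
            return None
        return _SIGNS.get(residue_name)


@dataclass(frozen=True)
class PointCharge:
    chain_id: str
    seq_id: tuple[int, str]
    residue_name: str
    sign: int  # +1 or -1
    anchor: tuple[float, float, float]
    anchor_source: str = "sidechain"  # "sidechain" | "CB" | "CA"

    @property
    def residue_ref(self) -> tuple[str, tuple[int, str], str]:
        return (self.chain_id, self.seq_id, self.residue_name)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.anchor, dtype=float)


@dataclass
class ChargeSet:
    charges: list[PointCharge] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.charges)

    def __iter__(self):
        return iter(self.charges)

    @property
    def net_charge(self) -> int:
        return sum(c.sign for c in self.charges)

    @property
    def n_fallback_anchors(self) -> int:
        return sum(1 for c in self.charges if c.anchor_source != "sidechain")

    def anchors(self) -> np.ndarray:
        return np.array([c.anchor for c in self.charges], dtype=float).reshape(-1, 3)

    def signs(self) -> np.ndarray:
        return np.array([c.sign for c in self.charges], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain": c.chain_id,
                "seq_id": f"{c.seq_id[0]}{c.seq_id[1]}",
                "residue": c.residue_name,
                "sign": c.sign,
                "x": round(c.anchor[0], 3),
                "y": round(c.anchor[1], 3),
                "z": round(c.anchor[2], 3),
            }
            for c in self.charges
        ]
        return pd.DataFrame(rows, columns=["chain", "seq_id", "residue", "sign", "x", "y", "z"])


def assign_formal_charges(
    unit: ComplexStructure, scheme: ChargeScheme = ChargeScheme()
) -> ChargeSet:
    """One unit charge per charged residue, anchored at its charged group.

    Anchors are the centroid of the residue's charge-bearing side-chain
    atoms; when those atoms are missing from the model the anchor falls
    back to CB, then CA, and the fallback is recorded on the charge.
    """
    out = ChargeSet()
    for chain in unit:
        for res in chain:
            sign = scheme.sign_of(res.name)
            if sign is None:
                continue
            anchor_atoms = [
                a for name in _ANCHOR_ATOMS.get(res.name, ()) if (a := res.atom(name))
            ]
            if anchor_atoms:
                anchor = tuple(np.mean([a.xyz for a in anchor_atoms], axis=0))
                source = "sidechain"
            elif (cb := res.atom("CB")) is not None:
                anchor, source = cb.coords, "CB"
            elif (ca := res.atom("CA")) is not None:
                anchor, source = ca.coords, "CA"
            else:
                continue  # no usable anchor atom at all
            out.charges.append(
                PointCharge(
                    chain_id=chain.id,
                    seq_id=res.seq_id,
                    residue_name=res.name,
                    sign=sign,
                    anchor=anchor,
                    anchor_source=source,
                )
            )
    return out


@dataclass
class PotentialField:
    complex_id: str
    sample_points: np.ndarray  # (n, 3) Angstrom
    values: np.ndarray  # (n,) consistent arbitrary units
    dielectric: float = 80.0
    kappa: float = 0.124  # 1/Angstrom; ~150 mM ionic strength at 298 K

    def __post_init__(self) -> None:
        self.sample_points = np.asarray(self.sample_points, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.sample_points) != len(self.values):
            raise ValueError("one value per sample point required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("potential values must be finite")


def evaluate_potential_field(
    q: ChargeSet,
    points: np.ndarray,
    dielectric: float = 80.0,
    kappa: float = 0.124,
    complex_id: str = "",
    min_r: float = 0.1,
) -> PotentialField:
    """Screened-Coulomb potential of a charge set on sample points.

    Distances below ``min_r`` (0.1 A) are clamped to avoid singularities.
    An empty charge set yields an all-zero field.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        raise ValueError("at least one sample point required")
    if dielectric <= 0:
        raise ValueError("dielectric must be positive")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if len(q) == 0:
        values = np.zeros(len(points))
    else:
        r = np.linalg.norm(points[:, None, :] - q.anchors()[None, :, :], axis=2)
        r = np.maximum(r, min_r)
        values = (q.signs()[None, :] * np.exp(-kappa * r) / (dielectric * r)).sum(axis=1)
    return PotentialField(
        complex_id=complex_id,
        sample_points=points,
        values=values,
        dielectric=dielectric,
        kappa=kappa,
    )


def hodgkin_index(phi_a: np.ndarray, phi_b: np.ndarray) -> float:
    """2<a,b> / (<a,a> + <b,b>); nan when both fields are identically zero."""
    phi_a = np.asarray(phi_a, dtype=float)
    phi_b = np.asarray(phi_b, dtype=float)
    denom = phi_a @ phi_a + phi_b @ phi_b
    if denom == 0.0:
        return float("nan")
    return float(2.0 * (phi_a @ phi_b) / denom)


def electrostatic_distance(si: float) -> float:
    return float(np.sqrt(max(2.0 - 2.0 * si, 0.0)))


@dataclass
class SimilarityMatrix:
    labels: list[str]
    si: np.ndarray  # Hodgkin indices, symmetric, unit diagonal
    dist: np.ndarray  # sqrt(2 - 2 si), zero diagonal
    flagged: list[tuple[str, str]] = field(default_factory=list)  # undefined entries

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dist, index=self.labels, columns=self.labels)


def similarity_matrix(fields: Sequence[PotentialField]) -> SimilarityMatrix:
    """Pairwise Hodgkin similarity and electrostatic distance on a shared grid."""
    if len(fields) < 2:
        raise ValueError("need at least two fields to compare")
    ref = fields[0].sample_points
    for f in fields[1:]:
        if f.sample_points.shape != ref.shape or not np.allclose(
            f.sample_points, ref, atol=1e-6
        ):
            raise ValueError(
                f"field {f.complex_id!r} was not evaluated on the shared point set"
            )
    n = len(fields)
    labels = [f.complex_id or str(i) for i, f in enumerate(fields)]
    phi = np.vstack([f.values for f in fields])
    norms = np.einsum("ij,ij->i", phi, phi)
    gram = phi @ phi.T
    denom = norms[:, None] + norms[None, :]
    flagged: list[tuple[str, str]] = []
    si = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if norms[i] == 0.0 or norms[j] == 0.0:
                # an all-zero field has no defined similarity to anything
                si[i, j] = np.nan
                if i < j:
                    flagged.append((labels[i], labels[j]))
            else:
                si[i, j] = 2.0 * gram[i, j] / denom[i, j]
    np.fill_diagonal(si, [1.0 if norms[i] > 0 else np.nan for i in range(n)])
    dist = np.sqrt(np.clip(2.0 - 2.0 * si, 0.0, None))
    np.fill_diagonal(dist, 0.0)
    return SimilarityMatrix(labels=labels, si=si, dist=dist, flagged=flagged)


def shell_grid(
    extent_x: tuple[float, float],
    extent_y: tuple[float, float],
    heights: tuple[float, float] = (3.0, 7.0),
    spacing: float = 1.0,
) -> np.ndarray:
    """Regular sample grid on a skin above the groove plane (z = 0 frame).

    Layers of an x-y grid are stacked between ``heights`` (Angstrom above
    the plane, PIPSA-style skin), at the given spacing in all axes.  The
    caller is responsible for expressing every complex in the same groove
    frame before sampling so the grid is shared.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    xs = np.arange(extent_x[0], extent_x[1] + 1e-9, spacing)
    ys = np.arange(extent_y[0], extent_y[1] + 1e-9, spacing)
    zs = np.arange(heights[0], heights[1] + 1e-9, spacing)
    grid = np.array(np.meshgrid(xs, ys, zs, indexing="ij")).reshape(3, -1).T
    return np.ascontiguousarray(grid)
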