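"""Synthetic TR/pMHC-like toy complexes with known ground truth.

Each toy complex emulates the geometry the docking-angle analysis relies
on: a linear peptide lying in the groove plane, two flanking helices
carrying a ring of charged residues whose elliptical footprint makes a
controlled angle theta_true with the peptide axis, and two TR
pseudo-domains hovering above the plane whose charges complement the ring
pairwise.  Negative ring charges sit toward the peptide's N-terminal half
and positive charges toward the C-terminal half, as observed on real
groove helices; a "flipped" pattern inverts every charge to emulate the
rarer predominantly-inverted interfaces.

Datasets add a planted linear binding-energy law BE = a + b*theta + noise
so that classification, correlation and clustering stages can be checked
against known truth.  Everything is deterministic under the spec's seed.

These are geometric cartoons, not physical proteins: helices are ideal
backbones decorated with pseudo side chains, and charge anchors are placed
exactly on the planted ellipse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .structures import Atom, Chain, ChainRole, ComplexStructure, Residue

__all__ = [
    "ToyComplexSpec",
    "ComplexTruth",
    "DatasetTruth",
    "generate_toy_complex",
    "generate_dataset",
    "TOY_ROLE_MAP",
]

_CA_SPACING = 3.5  # extended-chain C-alpha spacing, Angstrom
_HELIX_RISE = 1.5  # rise per residue along an ideal alpha helix
_HELIX_TWIST = np.deg2rad(100.0)
_HELIX_RADIUS = 2.3
_TR_OFFSET = 4.0  # TR charge anchors this far above their groove partners
_NEG_TYPES = ("ASP", "GLU")
_POS_TYPES = ("LYS", "ARG")

#: chain-role assignment shared by every generated toy complex
TOY_ROLE_MAP = {
    "A": ChainRole.MHC_ALPHA,
    "B": ChainRole.MHC_BETA,
    "C": ChainRole.PEPTIDE,
    "D": ChainRole.TR_ALPHA,
    "E": ChainRole.TR_BETA,
}


class SpecError(ValueError):
    """Raised for geometrically infeasible toy specifications."""


@dataclass(frozen=True)
class ToyComplexSpec:
    theta_true: float = 45.0  # degrees in [0, 180)
    n_ring_pairs: int = 8
    peptide_length: int = 9
    helix_offset: float = 9.0  # Angstrom, half-width of the groove
    coordinate_noise: float = 0.0  # Gaussian sigma per coordinate, Angstrom
    mhc_class: str = "I"
    seed: int = 0
    charge_pattern: str = "standard"  # "standard" | "flipped"
    n_distractors: int = 2  # charged groove residues with no TR partner
    ring_semi_minor: float | None = None  # default 0.8 * helix_offset
    ring_aspect: float = 1.75  # semi-major / semi-minor
    complex_id: str = "toy"

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_true < 180.0:
            raise SpecError("theta_true must lie in [0, 180)")
        if self.n_ring_pairs < 4:
            raise SpecError("need at least 4 ring pairs for an ellipse")
        if self.coordinate_noise < 0:
            raise SpecError("coordinate noise must be non-negative")
        if self.peptide_length < 3:
            raise SpecError("peptide needs at least 3 residues")
        if self.mhc_class not in ("I", "II"):
            raise SpecError("mhc_class must be 'I' or 'II'")
        if self.charge_pattern not in ("standard", "flipped"):
            raise SpecError("charge_pattern must be 'standard' or 'flipped'")
        if self.semi_minor >= self.helix_offset + _HELIX_RADIUS:
            raise SpecError(
                f"ring semi-minor axis {self.semi_minor:.1f} A does not fit a groove "
                f"of half-width {self.helix_offset:.1f} A"
            )

    @property
    def semi_minor(self) -> float:
        return self.ring_semi_minor if self.ring_semi_minor is not None else 0.8 * self.helix_offset

    @property
    def semi_major(self) -> float:
        return self.ring_aspect * self.semi_minor


@dataclass(frozen=True)
class ComplexTruth:
    complex_id: str
    theta_true: float
    n_ring_pairs: int
    charge_pattern: str
    mhc_class: str
    seed: int
    be_true: float | None = None
    epsilon: float | None = None
    agonist_class_true: str | None = None


def _ring_geometry(spec: ToyComplexSpec) -> tuple[np.ndarray, np.ndarray]:
    """Planted ellipse points (n, 3) in the groove plane, plus major-axis unit."""
    n = spec.n_ring_pairs
    t = 2.0 * np.pi * np.arange(n) / n + 0.4  # phase avoids axis-aligned points
    th = np.deg2rad(spec.theta_true)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    xy = rot @ np.vstack([spec.semi_major * np.cos(t), spec.semi_minor * np.sin(t)])
    pts = np.column_stack([xy[0], xy[1], np.zeros(n)])
    major = np.array([np.cos(th), np.sin(th), 0.0])
    return pts, major


def _charged_residue(
    name: str, number: int, ca: np.ndarray, anchor: np.ndarray
) -> Residue:
    """A pseudo charged residue: backbone CA, CB, and charge-bearing atoms."""
    cb = tuple(0.5 * (ca + anchor))
    atoms = [
        Atom("CA", "C", tuple(ca)),
        Atom("CB", "C", cb),
    ]
    if name == "LYS":
        atoms.append(Atom("NZ", "N", tuple(anchor)))
    elif name == "ARG":
        atoms.append(Atom("CZ", "C", tuple(anchor)))
    elif name == "ASP":
        atoms.append(Atom("OD1", "O", tuple(anchor + np.array([0, 0, 0.6]))))
        atoms.append(Atom("OD2", "O", tuple(anchor - np.array([0, 0, 0.6]))))
    elif name == "GLU":
        atoms.append(Atom("OE1", "O", tuple(anchor + np.array([0, 0, 0.6]))))
        atoms.append(Atom("OE2", "O", tuple(anchor - np.array([0, 0, 0.6]))))
    else:  # pragma: no cover
        raise ValueError(f"not a charged residue type: {name}")
    return Residue(name=name, seq_id=(number, ""), atoms=tuple(atoms))


def _helix_backbone(x_span: tuple[float, float], y_axis: float) -> np.ndarray:
    """Ideal-helix C-alpha positions along x at groove-wall offset y_axis."""
    n_res = int((x_span[1] - x_span[0]) / _HELIX_RISE) + 1
    i = np.arange(n_res)
    x = x_span[0] + i * _HELIX_RISE
    phase = i * _HELIX_TWIST
    y = y_axis + _HELIX_RADIUS * np.cos(phase)
    z = _HELIX_RADIUS * np.sin(phase)
    return np.column_stack([x, y, z])


def generate_toy_complex(spec: ToyComplexSpec) -> tuple[ComplexStructure, ComplexTruth]:
    """Build one annotated toy complex and its ground-truth record.

    The returned structure carries chain roles already assigned (the same
    assignment is available as :data:`TOY_ROLE_MAP` for pipeline configs)
    and an mhc_class matching the spec.
    """
    rng = np.random.default_rng(spec.seed)
    ring_pts, major = _ring_geometry(spec)

    flip = -1 if spec.charge_pattern == "flipped" else 1
    # negative charges on the peptide's N-terminal (-x) half
    signs = np.where(ring_pts[:, 0] < 0, -1, 1) * flip

    half_span = spec.semi_major + 8.0
    helix1 = _helix_backbone((-half_span, half_span), +spec.helix_offset)
    helix2 = _helix_backbone((-half_span, half_span), -spec.helix_offset)

    # map each ring charge to the nearest free backbone slot of its wall
    slot_of: dict[tuple[int, int], int] = {}  # (wall, slot) -> ring index
    for k, p in enumerate(ring_pts):
        wall = 0 if p[1] >= 0 else 1
        backbone = helix1 if wall == 0 else helix2
        order = np.argsort(np.abs(backbone[:, 0] - p[0]))
        slot = next(int(s) for s in order if (wall, int(s)) not in slot_of)
        slot_of[(wall, slot)] = k

    neg_cycle, pos_cycle = 0, 0
    mhc_res_type: dict[int, str] = {}
    for k in range(spec.n_ring_pairs):
        if signs[k] < 0:
            mhc_res_type[k] = _NEG_TYPES[neg_cycle % 2]
            neg_cycle += 1
        else:
            mhc_res_type[k] = _POS_TYPES[pos_cycle % 2]
            pos_cycle += 1

    # distractor charges at the helix ends, far from any TR atom
    distractor_slots: list[tuple[int, int]] = []
    for d in range(spec.n_distractors):
        wall = d % 2
        backbone = helix1 if wall == 0 else helix2
        ends = [0, len(backbone) - 1]
        for s in ends:
            if (wall, s) not in slot_of and (wall, s) not in distractor_slots:
                distractor_slots.append((wall, s))
                break

    def build_wall(wall: int, backbone: np.ndarray, start_num: int) -> list[Residue]:
        residues = []
        for s, ca in enumerate(backbone):
            num = start_num + s
            k = slot_of.get((wall, s))
            if k is not None:
                anchor = ring_pts[k]
                residues.append(_charged_residue(mhc_res_type[k], num, ca, anchor))
            elif (wall, s) in distractor_slots:
                name = "LYS" if wall == 0 else "ASP"
                anchor = ca + np.array([0.0, 0.0, 1.5])
                residues.append(_charged_residue(name, num, ca, anchor))
            else:
                residues.append(
                    Residue("GLY", (num, ""), (Atom("CA", "C", tuple(ca)),))
                )
        return residues

    if spec.mhc_class == "I":
        wall1 = build_wall(0, helix1, 50)
        wall2 = build_wall(1, helix2, 140)
        mhc_chains = {"A": Chain("A", ChainRole.MHC_ALPHA, wall1 + wall2)}
    else:
        wall1 = build_wall(0, helix1, 46)
        wall2 = build_wall(1, helix2, 50)
        mhc_chains = {
            "A": Chain("A", ChainRole.MHC_ALPHA, wall1),
            "B": Chain("B", ChainRole.MHC_BETA, wall2),
        }

    # peptide: extended chain along +x, N-terminus at -x, in the groove plane
    pep_res = []
    for i in range(spec.peptide_length):
        x = (i - (spec.peptide_length - 1) / 2.0) * _CA_SPACING
        ca = np.array([x, 0.0, 0.0])
        pep_res.append(
            Residue(
                "GLY",
                (i + 1, ""),
                (
                    Atom("N", "N", tuple(ca + np.array([-1.2, 0.4, 0.0]))),
                    Atom("CA", "C", tuple(ca)),
                    Atom("C", "C", tuple(ca + np.array([1.2, 0.4, 0.0]))),
                ),
            )
        )

    # TR pseudo-domains: complementary charges hovering above their partners,
    # split into V-alpha / V-beta blobs by the side of the ring's major axis
    tr_res: dict[str, list[Residue]] = {"D": [], "E": []}
    neg_cycle, pos_cycle = 0, 0
    for k, p in enumerate(ring_pts):
        side = "D" if p[:2] @ major[:2] < 0 else "E"
        if signs[k] < 0:  # groove charge negative -> TR partner positive
            name = _POS_TYPES[pos_cycle % 2]
            pos_cycle += 1
        else:
            name = _NEG_TYPES[neg_cycle % 2]
            neg_cycle += 1
        anchor = p + np.array([0.0, 0.0, _TR_OFFSET])
        ca = anchor + np.array([0.0, 0.0, 3.0])
        num = 20 + len(tr_res[side])
        tr_res[side].append(_charged_residue(name, num, ca, anchor))
    for side in ("D", "E"):
        if tr_res[side]:
            centroid = np.mean([r.atom("CA").xyz for r in tr_res[side]], axis=0)
        else:
            centroid = np.array([0.0, 0.0, _TR_OFFSET + 3.0])
        for j in range(3):  # neutral framework blob above the charges
            ca = centroid + np.array([1.5 * (j - 1), 1.5, 5.0])
            tr_res[side].append(Residue("GLY", (100 + j, ""), (Atom("CA", "C", tuple(ca)),)))

    chains = dict(mhc_chains)
    chains["C"] = Chain("C", ChainRole.PEPTIDE, pep_res)
    chains["D"] = Chain("D", ChainRole.TR_ALPHA, tr_res["D"])
    chains["E"] = Chain("E", ChainRole.TR_BETA, tr_res["E"])

    structure = ComplexStructure(
        id=spec.complex_id, chains=chains, mhc_class=spec.mhc_class
    )
    if spec.coordinate_noise > 0:
        structure = _jitter(structure, spec.coordinate_noise, rng)

    truth = ComplexTruth(
        complex_id=spec.complex_id,
        theta_true=spec.theta_true,
        n_ring_pairs=spec.n_ring_pairs,
        charge_pattern=spec.charge_pattern,
        mhc_class=spec.mhc_class,
        seed=spec.seed,
    )
    return structure, truth


def _jitter(c: ComplexStructure, sigma: float, rng: np.random.Generator) -> ComplexStructure:
    out = ComplexStructure(id=c.id, mhc_class=c.mhc_class)
    for cid, chain in c.chains.items():
        residues = []
        for res in chain:
            atoms = tuple(
                Atom(
                    a.name,
                    a.element,
                    tuple(a.xyz + rng.normal(0.0, sigma, size=3)),
                    a.occupancy,
                    a.altloc,
                    a.is_hetero,
                )
                for a in res.atoms
            )
            residues.append(Residue(res.name, res.seq_id, atoms))
        out.chains[cid] = Chain(cid, chain.role, residues)
    return out


@dataclass
class DatasetTruth:
    slope: float  # kcal/mol per degree
    intercept: float  # kcal/mol
    noise_sd: float
    seed: int
    complexes: list[ComplexTruth] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "complex_id": t.complex_id,
                    "theta_true": t.theta_true,
                    "be_true": t.be_true,
                    "epsilon": t.epsilon,
                    "charge_pattern": t.charge_pattern,
                    "mhc_class": t.mhc_class,
                    "seed": t.seed,
                }
                for t in self.complexes
            ]
        )


def generate_dataset(
    n: int = 50,
    theta_range: tuple[float, float] = (20.0, 110.0),
    a: float = -22.0,
    b: float = 0.12,
    noise_sd: float = 1.0,
    seed: int = 0,
    coordinate_noise: float = 0.3,
    flipped_fraction: float = 0.0,
    base_spec: ToyComplexSpec = ToyComplexSpec(),
) -> tuple[list[tuple[ComplexStructure, ComplexTruth]], DatasetTruth]:
    """A toy dataset with planted docking angles and a linear BE-theta law.

    Docking angles are uniform on ``theta_range``; BE_true = a + b*theta +
    Normal(0, noise_sd), with b > 0 on signed energies so larger angles mean
    weaker (less negative) binding.  The first round(flipped_fraction * n)
    complexes carry the flipped charge pattern (for cluster-recovery
    studies).  Per-complex seeds are spawned from ``seed``.
    """
    if n < 5:
        raise SpecError("datasets need at least 5 complexes")
    if theta_range[1] <= theta_range[0]:
        raise SpecError("empty theta range")
    rng = np.random.default_rng(seed)
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    thetas = rng.uniform(theta_range[0], theta_range[1], size=n)
    eps = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    n_flipped = int(round(flipped_fraction * n))

    out = []
    truth = DatasetTruth(slope=b, intercept=a, noise_sd=noise_sd, seed=seed)
    for i in range(n):
        spec = replace(
            base_spec,
            theta_true=float(thetas[i]),
            coordinate_noise=coordinate_noise,
            seed=int(child_seeds[i]),
            charge_pattern="flipped" if i < n_flipped else "standard",
            complex_id=f"toy{i:03d}",
        )
        structure, ct = generate_toy_complex(spec)
        ct = replace(
            ct,
            be_true=float(a + b * thetas[i] + eps[i]),
            epsilon=float(eps[i]),
        )
        truth.complexes.append(ct)
        out.append((structure, ct))
    return out, truth
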