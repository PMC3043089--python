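"""TR-pMHC interface contacts, paratope/epitope sets and conservation profiles.

A contact is a residue pair, one residue per unit, whose closest heavy
atoms lie within a distance cutoff (default 5.0 A, the conventional
criterion for TR/pMHC contact tables).  The TR-side residues of the
contact list form the paratope, the pMHC-side residues the epitope.
Conservation is profiled across structures over a user-supplied common
numbering (IMGT-style), not by running a sequence aligner.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import ComplexStructure

__all__ = [
    "ResidueRef",
    "ContactPair",
    "ContactMap",
    "InterfaceSet",
    "NumberingMap",
    "ConservationProfile",
    "compute_contacts",
    "extract_paratope_epitope",
    "conservation_profile",
]

#: (chain id, (resnum, icode), residue name)
ResidueRef = tuple[str, tuple[int, str], str]


@dataclass(frozen=True)
class ContactPair:
    pmhc_residue: ResidueRef
    tr_residue: ResidueRef
    min_distance: float


@dataclass
class ContactMap:
    complex_id: str
    pairs: list[ContactPair]
    cutoff: float

    def __len__(self) -> int:
        return len(self.pairs)

    def partners_of_pmhc(self, ref: ResidueRef) -> set[ResidueRef]:
        return {p.tr_residue for p in self.pairs if p.pmhc_residue == ref}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "complex_id": self.complex_id,
                "pmhc_chain": p.pmhc_residue[0],
                "pmhc_seq_id": _fmt_seqid(p.pmhc_residue[1]),
                "pmhc_residue": p.pmhc_residue[2],
                "tr_chain": p.tr_residue[0],
                "tr_seq_id": _fmt_seqid(p.tr_residue[1]),
                "tr_residue": p.tr_residue[2],
                "min_distance": round(p.min_distance, 3),
            }
            for p in self.pairs
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "complex_id",
                "pmhc_chain",
                "pmhc_seq_id",
                "pmhc_residue",
                "tr_chain",
                "tr_seq_id",
                "tr_residue",
                "min_distance",
            ],
        )


def _fmt_seqid(seq_id: tuple[int, str]) -> str:
    num, icode = seq_id
    return f"{num}{icode}"


@dataclass
class InterfaceSet:
    """Residues on one side of the interface (PARATOPE = TR, EPITOPE = pMHC)."""

    side: str  # "PARATOPE" or "EPITOPE"
    residues: set[ResidueRef]
    aligned: dict[str, str] | None = None  # common position label -> amino acid
    position_of: dict[ResidueRef, str] | None = None

    def align(self, numbering: "NumberingMap") -> "InterfaceSet":
        """Attach common-position labels; residues without a label are skipped."""
        aligned: dict[str, str] = {}
        position_of: dict[ResidueRef, str] = {}
        for ref in sorted(self.residues):
            chain_id, seq_id, name = ref
            pos = numbering.lookup(chain_id, seq_id)
            if pos is not None:
                aligned[pos] = name
                position_of[ref] = pos
        return InterfaceSet(
            side=self.side,
            residues=set(self.residues),
            aligned=aligned,
            position_of=position_of,
        )


@dataclass
class NumberingMap:
    """Mapping (chain id, author seq id) -> common position label.

    The map must be injective per chain: two residues of one chain cannot
    share a common position.
    """

    entries: dict[tuple[str, tuple[int, str]], str]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], tuple[int, str]] = {}
        for (chain, seq_id), pos in self.entries.items():
            key = (chain, pos)
            if key in seen and seen[key] != seq_id:
                raise ValueError(
                    f"numbering map not injective: chain {chain} position {pos} "
                    f"assigned to both {seen[key]} and {seq_id}"
                )
            seen[key] = seq_id

    def lookup(self, chain_id: str, seq_id: tuple[int, str]) -> str | None:
        return self.entries.get((chain_id, seq_id))

    @classmethod
    def from_tsv(cls, path) -> "NumberingMap":
        """Read a 3-column TSV: chain, seq_id, common_position."""
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        entries = {}
        for _, row in df.iterrows():
            raw = str(row.iloc[1]).strip()
            num = int("".join(ch for ch in raw if ch.isdigit() or ch == "-"))
            icode = "".join(ch for ch in raw if ch.isalpha())
            entries[(str(row.iloc[0]), (num, icode))] = str(row.iloc[2])
        return cls(entries)


@dataclass
class PositionStats:
    counts: Counter
    occupancy: float  # fraction of sets in which the position is contacted
    conservation: float  # modal-residue count / number of sets
    modal_residue: str
    conserved_position: bool
    conserved_residue: bool
    mostly_conserved: bool


@dataclass
class ConservationProfile:
    n_sets: int
    positions: dict[str, PositionStats] = field(default_factory=dict)

    def conserved_positions(self) -> list[str]:
        return [p for p, s in self.positions.items() if s.conserved_position]

    def conserved_residues(self) -> list[tuple[str, str]]:
        return [
            (p, s.modal_residue) for p, s in self.positions.items() if s.conserved_residue
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "position": pos,
                "modal_residue": s.modal_residue,
                "occupancy": round(s.occupancy, 4),
                "conservation": round(s.conservation, 4),
                "n_sets": self.n_sets,
                "conserved_position": s.conserved_position,
                "conserved_residue": s.conserved_residue,
                "mostly_conserved": s.mostly_conserved,
            }
            for pos, s in sorted(self.positions.items())
        ]
        return pd.DataFrame(rows)


def _unit_atoms(unit: ComplexStructure) -> tuple[np.ndarray, list[ResidueRef], np.ndarray]:
    """Flatten a unit to (coords, residue refs, per-atom residue index)."""
    coords: list[np.ndarray] = []
    refs: list[ResidueRef] = []
    idx: list[int] = []
    for chain in unit:
        for res in chain:
            refs.append((chain.id, res.seq_id, res.name))
            block = res.coord_array()
            coords.append(block)
            idx.extend([len(refs) - 1] * len(block))
    if not coords:
        return np.empty((0, 3)), [], np.empty(0, dtype=int)
    return np.vstack(coords), refs, np.asarray(idx, dtype=int)


def compute_contacts(
    pmhc_unit: ComplexStructure,
    tr_unit: ComplexStructure,
    cutoff: float = 5.0,
) -> ContactMap:
    """All residue pairs with any heavy-atom distance <= cutoff (Angstrom).

    Pairs are ordered deterministically by (pmhc chain, seq id) then
    (tr chain, seq id); the minimum heavy-atom distance is recorded.
    """
    if cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    p_xyz, p_refs, p_idx = _unit_atoms(pmhc_unit)
    t_xyz, t_refs, t_idx = _unit_atoms(tr_unit)
    if len(p_refs) == 0 or len(t_refs) == 0:
        raise ValueError("both units must contain residues")

    tree = cKDTree(t_xyz)
    neighbours = tree.query_ball_point(p_xyz, r=cutoff)
    best: dict[tuple[int, int], float] = {}
    for ai, hits in enumerate(neighbours):
        if not hits:
            continue
        ri = p_idx[ai]
        d = np.linalg.norm(t_xyz[hits] - p_xyz[ai], axis=1)
        for h, dist in zip(hits, d):
            key = (ri, t_idx[h])
            if dist < best.get(key, np.inf):
                best[key] = float(dist)

    pairs = [
        ContactPair(p_refs[ri], t_refs[ti], dist)
        for (ri, ti), dist in best.items()
    ]
    pairs.sort(key=lambda p: (p.pmhc_residue[0], p.pmhc_residue[1], p.tr_residue[0], p.tr_residue[1]))
    return ContactMap(complex_id=pmhc_unit.id, pairs=pairs, cutoff=cutoff)


def extract_paratope_epitope(cm: ContactMap) -> tuple[InterfaceSet, InterfaceSet]:
    """Project the contact list onto its two sides (unique residues each)."""
    paratope = InterfaceSet(side="PARATOPE", residues={p.tr_residue for p in cm.pairs})
    epitope = InterfaceSet(side="EPITOPE", residues={p.pmhc_residue for p in cm.pairs})
    return paratope, epitope


def conservation_profile(
    sets: Sequence[InterfaceSet],
    occupancy_threshold: float = 0.8,
    mostly_threshold: float = 0.9,
) -> ConservationProfile:
    """Profile residue conservation at aligned common positions.

    For each common position observed in at least one set: ``occupancy`` is
    the fraction of sets in which the position is contacted; ``conservation``
    is the modal-residue count over the total number of sets.  A position is
    flagged conserved when its occupancy reaches ``occupancy_threshold``; a
    residue is conserved when the same amino acid appears there in every
    set, and "mostly conserved" at ``mostly_threshold``.
    """
    if len(sets) < 2:
        raise ValueError("conservation requires at least two interface sets")
    for s in sets:
        if s.aligned is None:
            raise ValueError(
                f"interface set ({s.side}) lacks an aligned common numbering"
            )
    n = len(sets)
    counters: dict[str, Counter] = {}
    for s in sets:
        assert s.aligned is not None
        for pos, aa in s.aligned.items():
            counters.setdefault(pos, Counter())[aa] += 1

    profile = ConservationProfile(n_sets=n)
    for pos, counts in counters.items():
        modal, modal_n = counts.most_common(1)[0]
        total = sum(counts.values())
        occupancy = total / n
        conservation = modal_n / n
        profile.positions[pos] = PositionStats(
            counts=counts,
            occupancy=occupancy,
            conservation=conservation,
            modal_residue=modal,
            conserved_position=occupancy >= occupancy_threshold,
            conserved_residue=conservation >= 1.0,
            mostly_conserved=conservation >= mostly_threshold,
        )
    return profile


def interface_table(
    complex_id: str,
    sets: Iterable[InterfaceSet],
    min_distances: Mapping[ResidueRef, float] | None = None,
) -> pd.DataFrame:
    """TSV-ready long table of interface residues from one or more sets."""
    rows = []
    for s in sets:
        pos_of = s.position_of or {}
        for ref in sorted(s.residues):
            chain_id, seq_id, name = ref
            rows.append(
                {
                    "complex_id": complex_id,
                    "side": s.side,
                    "chain": chain_id,
                    "seq_id": _fmt_seqid(seq_id),
                    "residue": name,
                    "common_position": pos_of.get(ref, ""),
                    "min_distance": (
                        round(min_distances.get(ref, np.nan), 3)
                        if min_distances
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
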