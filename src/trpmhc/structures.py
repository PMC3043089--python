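"""Annotated protein-complex model: PDB parsing, chain-role annotation, truncation.

The rest of the pipeline consumes two units derived from a T-cell-receptor/
peptide-MHC (TR/pMHC) crystal structure: the pMHC binding interface (MHC
groove domains plus the bound peptide) and the TR variable domains.  This
module parses PDB text into a light-weight annotated model, assigns chain
roles (MHC alpha/beta, beta-2-microglobulin, peptide, TR alpha/beta), and
cuts out the two units by per-role residue ranges.

PDB reading and writing is delegated to :mod:`gemmi`; the classes here only
hold what downstream stages need (heavy-atom coordinates, residue identity,
chain roles).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "ChainRole",
    "ComplexStructure",
    "TruncationSpec",
    "ParseError",
    "AnnotationError",
    "TruncationError",
    "parse_pdb",
    "write_pdb",
    "annotate_roles",
    "truncate_complex",
    "DEFAULT_TRUNCATION",
]


class ParseError(ValueError):
    """Raised when PDB text cannot be turned into a structure."""


class AnnotationError(ValueError):
    """Raised on inconsistent chain-role assignment."""


class TruncationError(ValueError):
    """Raised when a truncation range removes every residue of a required role."""


class ChainRole(Enum):
    MHC_ALPHA = "MHC_ALPHA"
    MHC_BETA = "MHC_BETA"
    B2M = "B2M"
    PEPTIDE = "PEPTIDE"
    TR_ALPHA = "TR_ALPHA"
    TR_BETA = "TR_BETA"
    OTHER = "OTHER"


#: roles whose residues belong to the pMHC-interface unit
PMHC_ROLES = frozenset({ChainRole.MHC_ALPHA, ChainRole.MHC_BETA, ChainRole.PEPTIDE})
#: roles whose residues belong to the TR variable-domain unit
TR_ROLES = frozenset({ChainRole.TR_ALPHA, ChainRole.TR_BETA})


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0,1]")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass(frozen=True)
class Residue:
    name: str
    seq_id: tuple[int, str]  # (author number, insertion code)
    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.name}{self.seq_id} has no atoms")
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"duplicate atom names in {self.name}{self.seq_id} after altloc resolution"
            )

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def label(self) -> str:
        num, icode = self.seq_id
        return f"{self.name}{num}{icode.strip()}"

    def coord_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class Chain:
    id: str
    role: ChainRole
    residues: list[Residue]

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ComplexStructure:
    """A (possibly partial) TR/pMHC complex with per-chain role annotation."""

    id: str
    chains: dict[str, Chain] = field(default_factory=dict)
    mhc_class: str = "UNKNOWN"  # "I", "II" or "UNKNOWN"

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains.values())

    def chains_with_role(self, role: ChainRole) -> list[Chain]:
        return [c for c in self.chains.values() if c.role == role]

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains.values() for r in c)

    def coord_array(self, roles: Iterable[ChainRole] | None = None) -> np.ndarray:
        """All heavy-atom coordinates, optionally restricted to roles; (n, 3)."""
        want = set(roles) if roles is not None else None
        rows = [
            a.coords
            for c in self.chains.values()
            if want is None or c.role in want
            for r in c
            for a in r.atoms
        ]
        return np.array(rows, dtype=float).reshape(-1, 3)

    def ca_array(self, roles: Iterable[ChainRole] | None = None) -> np.ndarray:
        want = set(roles) if roles is not None else None
        rows = []
        for c in self.chains.values():
            if want is not None and c.role not in want:
                continue
            for r in c:
                ca = r.atom("CA")
                if ca is not None:
                    rows.append(ca.coords)
        return np.array(rows, dtype=float).reshape(-1, 3)

    def is_valid_complex(self) -> bool:
        """One peptide, at least one MHC chain, and both TR chains."""
        return (
            len(self.chains_with_role(ChainRole.PEPTIDE)) == 1
            and len(self.chains_with_role(ChainRole.MHC_ALPHA))
            + len(self.chains_with_role(ChainRole.MHC_BETA))
            >= 1
            and len(self.chains_with_role(ChainRole.TR_ALPHA)) >= 1
            and len(self.chains_with_role(ChainRole.TR_BETA)) >= 1
        )


# residues always treated as solvent/heteroatoms even when written as ATOM
_WATER_NAMES = {"HOH", "WAT", "DOD"}

_COORD_RE = re.compile(r"^[ \-+]?\d*\.\d+$|^[ \-+]?\d+$")


def _validate_atom_lines(text: str) -> None:
    """Light pre-check of coordinate fields so errors carry a line number."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise ParseError(f"line {lineno}: ATOM record too short for coordinates")
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            fld = line[lo:hi].strip()
            if not fld or not _COORD_RE.match(fld):
                raise ParseError(
                    f"line {lineno}: malformed coordinate field {fld!r}"
                )


def _resolve_altlocs(atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken by altloc code."""
    by_name: dict[str, gemmi.Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
            continue
        key_new = (-a.occ, a.altloc or "~")
        key_old = (-prev.occ, prev.altloc or "~")
        if key_new < key_old:
            by_name[a.name] = a
    return list(by_name.values())


def parse_pdb(
    text: str,
    structure_id: str = "",
    include_hetero: bool = False,
) -> ComplexStructure:
    """Parse PDB text into a :class:`ComplexStructure` with all roles OTHER.

    Only model 1 of multi-model files is read.  Hydrogens and waters are
    always dropped; other HETATM records are dropped unless
    ``include_hetero``.  Alternate locations are resolved to the
    highest-occupancy conformer (ties go to the lexicographically first
    altloc code).
    """
    _validate_atom_lines(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise ParseError(str(exc)) from exc
    if len(st) == 0:
        raise ParseError("no models in PDB text")
    model = st[0]

    chains: dict[str, Chain] = {}
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.name in _WATER_NAMES:
                continue
            is_het = gres.het_flag == "H"
            if is_het and not include_hetero:
                continue
            kept = _resolve_altlocs([a for a in gres if not a.is_hydrogen()])
            if not kept:
                continue
            atoms = tuple(
                Atom(
                    name=a.name,
                    element=a.element.name,
                    coords=(a.pos.x, a.pos.y, a.pos.z),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    altloc=(a.altloc if a.altloc != "\x00" else ""),
                    is_hetero=is_het,
                )
                for a in kept
            )
            residues.append(
                Residue(name=gres.name, seq_id=(gres.seqid.num, gres.seqid.icode.strip()), atoms=atoms)
            )
        if residues:
            chains[gchain.name] = Chain(id=gchain.name, role=ChainRole.OTHER, residues=residues)

    if not chains:
        raise ParseError("no ATOM records with heavy atoms found")
    return ComplexStructure(id=structure_id or (st.name or "complex"), chains=chains)


def write_pdb(c: ComplexStructure, remarks: Iterable[str] = ()) -> str:
    """Serialise a structure back to PDB text (roles are not persisted)."""
    st = gemmi.Structure()
    st.name = c.id
    model = gemmi.Model("1")
    for chain in c:
        gchain = gemmi.Chain(chain.id)
        for res in chain:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id[0], res.seq_id[1] or " ")
            gres.het_flag = "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    body = st.make_pdb_string()
    header = "".join(f"REMARK 999 {line}\n" for line in remarks)
    return header + body


def annotate_roles(
    c: ComplexStructure,
    role_map: Mapping[str, ChainRole | str],
    peptide_fallback: bool = True,
    peptide_length_range: tuple[int, int] = (8, 25),
) -> ComplexStructure:
    """Return a copy of ``c`` with chain roles assigned from ``role_map``.

    Chains absent from the map stay OTHER unless ``peptide_fallback`` is on,
    in which case the shortest unmapped chain whose length falls in
    ``peptide_length_range`` becomes the peptide (only when no chain was
    mapped to PEPTIDE explicitly).  ``mhc_class`` is II iff both MHC_ALPHA
    and MHC_BETA are present, else I.
    """
    roles: dict[str, ChainRole] = {}
    for cid, role in role_map.items():
        roles[cid] = ChainRole(role) if not isinstance(role, ChainRole) else role

    n_pep = sum(1 for r in roles.values() if r == ChainRole.PEPTIDE)
    if n_pep > 1:
        raise AnnotationError("two chains mapped to PEPTIDE")

    out = ComplexStructure(id=c.id, mhc_class=c.mhc_class)
    for cid, chain in c.chains.items():
        out.chains[cid] = Chain(
            id=cid, role=roles.get(cid, ChainRole.OTHER), residues=chain.residues
        )

    if n_pep == 0 and peptide_fallback:
        lo, hi = peptide_length_range
        candidates = [
            ch
            for ch in out
            if ch.role == ChainRole.OTHER and lo <= len(ch) <= hi
        ]
        if candidates:
            shortest = min(candidates, key=lambda ch: (len(ch), ch.id))
            shortest.role = ChainRole.PEPTIDE

    has_a = bool(out.chains_with_role(ChainRole.MHC_ALPHA))
    has_b = bool(out.chains_with_role(ChainRole.MHC_BETA))
    out.mhc_class = "II" if (has_a and has_b) else ("I" if has_a else "UNKNOWN")
    return out


@dataclass(frozen=True)
class TruncationSpec:
    """Per-role residue ranges (inclusive author numbering) defining the units.

    Defaults follow standard domain boundaries: the MHC-I groove is the
    alpha-chain G-ALPHA1/G-ALPHA2 region (residues 1-180), the MHC-II groove
    spans G-ALPHA (alpha 1-85) and G-BETA (beta 1-95), and TR variable
    domains are residues 1-115 of each receptor chain.
    """

    ranges: Mapping[ChainRole, tuple[int, int]] = field(
        default_factory=lambda: {
            ChainRole.MHC_ALPHA: (1, 180),
            ChainRole.MHC_BETA: (1, 95),
            ChainRole.TR_ALPHA: (1, 115),
            ChainRole.TR_BETA: (1, 115),
        }
    )
    mhc2_alpha_range: tuple[int, int] = (1, 85)

    def __post_init__(self) -> None:
        for role, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"empty range for {role}: ({lo}, {hi})")

    def range_for(self, role: ChainRole, mhc_class: str) -> tuple[int, int] | None:
        if role == ChainRole.MHC_ALPHA and mhc_class == "II":
            return self.mhc2_alpha_range
        return self.ranges.get(role)


DEFAULT_TRUNCATION = TruncationSpec()


def _filter_chain(chain: Chain, rng: tuple[int, int] | None) -> Chain:
    if rng is None:
        return Chain(chain.id, chain.role, list(chain.residues))
    lo, hi = rng
    kept = [r for r in chain.residues if lo <= r.seq_id[0] <= hi]
    return Chain(chain.id, chain.role, kept)


def truncate_complex(
    c: ComplexStructure, spec: TruncationSpec = DEFAULT_TRUNCATION
) -> tuple[ComplexStructure, ComplexStructure]:
    """Split an annotated complex into its pMHC-interface and TR-V units.

    The pMHC unit holds the MHC groove-domain ranges plus the entire
    peptide; the TR unit holds the V-domain ranges of both receptor chains.
    Chains with role OTHER/B2M are dropped.  The input is left untouched.
    """
    pmhc = ComplexStructure(id=c.id, mhc_class=c.mhc_class)
    tr = ComplexStructure(id=c.id, mhc_class=c.mhc_class)
    for cid, chain in c.chains.items():
        if chain.role == ChainRole.PEPTIDE:
            pmhc.chains[cid] = _filter_chain(chain, None)
        elif chain.role in PMHC_ROLES:
            sub = _filter_chain(chain, spec.range_for(chain.role, c.mhc_class))
            if not sub.residues:
                raise TruncationError(
                    f"truncation range removed every residue of role {chain.role.value}"
                )
            pmhc.chains[cid] = sub
        elif chain.role in TR_ROLES:
            sub = _filter_chain(chain, spec.range_for(chain.role, c.mhc_class))
            if not sub.residues:
                raise TruncationError(
                    f"truncation range removed every residue of role {chain.role.value}"
                )
            tr.chains[cid] = sub
    for unit, side in ((pmhc, "pMHC"), (tr, "TR")):
        if not unit.chains:
            raise TruncationError(f"no chains left on the {side} side after truncation")
    return pmhc, tr
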