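"""Binding energy from a distance-dependent statistical potential.

The TR/pMHC binding energy is estimated the way rigid-body knowledge-based
scoring functions (DFIRE-family) do it: the free energy of a unit is a sum
of atom-atom potentials of mean force u(type_i, type_j, r) over atom pairs
not in the same residue, and the binding energy is

    dG_bind = G(AB) - G(A) - G(B)

Because the two units are treated as rigid bodies, every intra-unit pair
cancels in the difference and only inter-unit pairs contribute; the
binding energy is therefore computed directly as the sum of u over
cross-unit atom pairs (each unordered pair once), with u = 0 beyond the
table's distance cutoff.

The potential table is an exchangeable input.  A small residue-typed toy
table ships with the package for tests and synthetic studies, and
:func:`train_dfire_table` can derive a DFIRE-form table from any structure
set; parity with any particular published scoring program is not promised.

Free energies and dissociation constants interconvert via
dG = R*T*ln(Kd) = -R*T*ln(Ka).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structures import ComplexStructure

__all__ = [
    "ThermoConstants",
    "PotentialTable",
    "BEResult",
    "TableFormatError",
    "load_potential_table",
    "load_default_table",
    "binding_energy",
    "binding_energy_bruteforce",
    "dg_from_kd",
    "kd_from_dg",
    "train_dfire_table",
]

#: gas constant, kcal / (mol K)
R_KCAL = 1.987e-3


class TableFormatError(ValueError):
    """Raised when a potential-table file violates the format contract."""


@dataclass(frozen=True)
class ThermoConstants:
    R: float = R_KCAL  # kcal mol^-1 K^-1
    T: float = 298.15  # K

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("absolute temperature must be positive")

    @property
    def RT(self) -> float:
        return self.R * self.T


def dg_from_kd(kd: float, tc: ThermoConstants = ThermoConstants()) -> float:
    """Binding free energy (kcal/mol) from a dissociation constant (mol/L)."""
    if kd <= 0:
        raise ValueError("Kd must be positive")
    return tc.RT * math.log(kd)


def kd_from_dg(dg: float, tc: ThermoConstants = ThermoConstants()) -> float:
    return math.exp(dg / tc.RT)


@dataclass
class PotentialTable:
    """Symmetric atom-pair potential table binned on distance.

    ``atom_typing`` names the typing scheme: "residue" types an atom by its
    parent residue's 3-letter code; "atom" by "RES:ATOMNAME".  ``bin_edges``
    are ascending Angstrom edges; the last edge is the cutoff r_cut beyond
    which u = 0.  Distances below the first edge are scored in bin 0.
    """

    atom_typing: str
    types: list[str]
    bin_edges: np.ndarray
    u_bar: np.ndarray  # (n_types, n_types, n_bins), kcal/mol
    table_id: str = "unnamed"
    n_missing_filled: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise TableFormatError("bin edges must be strictly increasing")
        if not np.allclose(self.u_bar, np.swapaxes(self.u_bar, 0, 1), atol=1e-9):
            raise TableFormatError("potential table must be symmetric in (i, j)")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def r_cut(self) -> float:
        return float(self.bin_edges[-1])

    def type_index(self, type_name: str) -> int | None:
        try:
            return self.types.index(type_name)
        except ValueError:
            return None

    def atom_type(self, residue_name: str, atom_name: str) -> str:
        if self.atom_typing == "residue":
            return residue_name
        return f"{residue_name}:{atom_name}"

    def lookup(self, type_i: str, type_j: str, r: float) -> float:
        """u for one pair at distance r; 0 beyond r_cut or for unknown types."""
        if r >= self.r_cut:
            return 0.0
        i = self.type_index(type_i)
        j = self.type_index(type_j)
        if i is None or j is None:
            return 0.0
        b = int(np.searchsorted(self.bin_edges, r, side="right")) - 1
        b = min(max(b, 0), self.n_bins - 1)
        return float(self.u_bar[i, j, b])

    def save(self, path: str | Path) -> None:
        path = Path(path)
        lines = [
            "# trpmhc potential table",
            f"#table_id\t{self.table_id}",
            f"#typing\t{self.atom_typing}",
            "#bin_edges\t" + "\t".join(f"{e:g}" for e in self.bin_edges),
            "type_i\ttype_j\tbin_index\tu_bar",
        ]
        for i, ti in enumerate(self.types):
            for j, tj in enumerate(self.types):
                if j < i:
                    continue
                for b in range(self.n_bins):
                    u = self.u_bar[i, j, b]
                    if u != 0.0:
                        lines.append(f"{ti}\t{tj}\t{b}\t{u:.6g}")
        path.write_text("\n".join(lines) + "\n")


def load_potential_table(source: str | Path, symmetry_tol: float = 1e-6) -> PotentialTable:
    """Load and validate a potential-table TSV (see :meth:`PotentialTable.save`).

    Missing (i, j, bin) entries are filled with zero and counted; entries
    present for both (i, j) and (j, i) must agree within ``symmetry_tol``.
    """
    path = Path(source)
    typing_scheme: str | None = None
    edges: np.ndarray | None = None
    table_id = path.stem
    rows: list[tuple[str, str, int, float]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line.lstrip("#").split("\t")
            if parts[0] == "typing":
                typing_scheme = parts[1]
            elif parts[0] == "bin_edges":
                edges = np.array([float(x) for x in parts[1:]])
            elif parts[0] == "table_id":
                table_id = parts[1]
            continue
        if line.startswith("type_i"):
            continue
        ti, tj, b, u = line.split("\t")
        rows.append((ti, tj, int(b), float(u)))
    if typing_scheme is None:
        raise TableFormatError("table file does not declare a typing scheme")
    if edges is None:
        raise TableFormatError("table file does not declare bin edges")
    if np.any(np.diff(edges) <= 0):
        raise TableFormatError("bin edges must be strictly increasing")
    n_bins = len(edges) - 1

    types = sorted({t for ti, tj, _, _ in rows for t in (ti, tj)})
    idx = {t: k for k, t in enumerate(types)}
    u = np.zeros((len(types), len(types), n_bins))
    seen = np.zeros_like(u, dtype=bool)
    for ti, tj, b, val in rows:
        if not 0 <= b < n_bins:
            raise TableFormatError(f"bin index {b} outside 0..{n_bins - 1}")
        i, j = idx[ti], idx[tj]
        for a, c in ((i, j), (j, i)):
            if seen[a, c, b] and abs(u[a, c, b] - val) > symmetry_tol:
                raise TableFormatError(
                    f"asymmetric entries for ({ti}, {tj}) bin {b}: "
                    f"{u[a, c, b]} vs {val}"
                )
            u[a, c, b] = val
            seen[a, c, b] = True
    n_missing = int((~seen).sum() // 2)
    return PotentialTable(
        atom_typing=typing_scheme,
        types=types,
        bin_edges=edges,
        u_bar=u,
        table_id=table_id,
        n_missing_filled=n_missing,
    )


def load_default_table() -> PotentialTable:
    """The residue-typed toy table packaged with trpmhc."""
    with resources.as_file(
        resources.files("trpmhc") / "data" / "toy_potential.tsv"
    ) as p:
        return load_potential_table(p)


@dataclass(frozen=True)
class BEResult:
    complex_id: str
    be: float  # kcal/mol
    n_pairs_scored: int
    table_id: str
    n_unknown_type_atoms: int = 0


def _typed_atoms(
    unit: ComplexStructure, table: PotentialTable, unknown_policy: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """(coords, type indices) for all atoms with a known table type."""
    coords: list[tuple[float, float, float]] = []
    tidx: list[int] = []
    unknown = 0
    for chain in unit:
        for res in chain:
            for atom in res.atoms:
                t = table.type_index(table.atom_type(res.name, atom.name))
                if t is None:
                    if unknown_policy == "fail":
                        raise KeyError(
                            f"atom type {table.atom_type(res.name, atom.name)!r} "
                            f"not in table {table.table_id!r}"
                        )
                    unknown += 1
                    continue
                coords.append(atom.coords)
                tidx.append(t)
    return (
        np.asarray(coords, dtype=float).reshape(-1, 3),
        np.asarray(tidx, dtype=int),
        unknown,
    )


def binding_energy(
    a: ComplexStructure,
    b: ComplexStructure,
    table: PotentialTable,
    unknown_policy: str = "skip",
) -> BEResult:
    """Sum u over inter-unit atom pairs within the table cutoff.

    Each unordered cross pair is scored once; intra-unit pairs are never
    scored (they cancel in the rigid-body free-energy difference).  Atoms
    whose type is absent from the table are skipped and counted, or raise,
    per ``unknown_policy`` ("skip" | "fail").
    """
    xa, ta, unk_a = _typed_atoms(a, table, unknown_policy)
    xb, tb, unk_b = _typed_atoms(b, table, unknown_policy)
    if len(xa) == 0 or len(xb) == 0:
        return BEResult(a.id, 0.0, 0, table.table_id, unk_a + unk_b)

    tree_b = cKDTree(xb)
    pairs = cKDTree(xa).query_ball_tree(tree_b, r=table.r_cut)
    total = 0.0
    n_scored = 0
    edges = table.bin_edges
    n_bins = table.n_bins
    for ia, hits in enumerate(pairs):
        if not hits:
            continue
        hits = np.asarray(hits, dtype=int)
        d = np.linalg.norm(xb[hits] - xa[ia], axis=1)
        inside = d < table.r_cut
        hits, d = hits[inside], d[inside]
        if len(hits) == 0:
            continue
        bins = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
        total += float(table.u_bar[ta[ia], tb[hits], bins].sum())
        n_scored += len(hits)
    return BEResult(
        complex_id=a.id,
        be=total,
        n_pairs_scored=n_scored,
        table_id=table.table_id,
        n_unknown_type_atoms=unk_a + unk_b,
    )


def binding_energy_bruteforce(
    a: ComplexStructure, b: ComplexStructure, table: PotentialTable
) -> float:
    """Independent O(n^2) per-pair loop over the same sum (test oracle)."""
    total = 0.0
    atoms_a = [
        (res.name, atom.name, atom.xyz)
        for chain in a
        for res in chain
        for atom in res.atoms
    ]
    atoms_b = [
        (res.name, atom.name, atom.xyz)
        for chain in b
        for res in chain
        for atom in res.atoms
    ]
    for rn_a, an_a, xa in atoms_a:
        for rn_b, an_b, xb in atoms_b:
            r = float(np.linalg.norm(xa - xb))
            total += table.lookup(
                table.atom_type(rn_a, an_a), table.atom_type(rn_b, an_b), r
            )
    return total


def train_dfire_table(
    structures: Sequence[ComplexStructure],
    bin_edges: Iterable[float],
    alpha: float = 1.61,
    eta: float = 1.0,
    tc: ThermoConstants = ThermoConstants(),
    atom_typing: str = "residue",
    table_id: str = "dfire-trained",
) -> PotentialTable:
    """Derive a DFIRE-form residue-typed table from observed pair counts.

    For each type pair the observed count N(i,j,r) in a distance bin is
    compared with the distance-scaled ideal-gas expectation anchored at the
    cutoff bin:

        u(i,j,r) = -eta * R*T * ln[ N(i,j,r) /
                    ((r/r_cut)^alpha * (dr/dr_cut) * N(i,j,r_cut)) ]

    with r the bin midpoint and dr the bin width.  Bins with no
    observations (or pairs unobserved at the cutoff bin) score zero.
    """
    edges = np.asarray(list(bin_edges), dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    n_bins = len(edges) - 1
    r_cut = edges[-1]
    mids = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)

    type_names: dict[str, int] = {}
    counts: dict[tuple[int, int], np.ndarray] = {}

    for st in structures:
        flat: list[tuple[int, int, np.ndarray]] = []  # (residue serial, type, xyz)
        serial = 0
        for chain in st:
            for res in chain:
                for atom in res.atoms:
                    tname = res.name if atom_typing == "residue" else f"{res.name}:{atom.name}"
                    t = type_names.setdefault(tname, len(type_names))
                    flat.append((serial, t, atom.xyz))
                serial += 1
        if len(flat) < 2:
            continue
        xyz = np.array([f[2] for f in flat])
        res_of = np.array([f[0] for f in flat])
        typ_of = np.array([f[1] for f in flat])
        tree = cKDTree(xyz)
        for ia, ib in tree.query_pairs(r=r_cut):
            if res_of[ia] == res_of[ib]:
                continue  # same-residue pairs are excluded from the sum
            r = float(np.linalg.norm(xyz[ia] - xyz[ib]))
            if r >= r_cut:
                continue
            b = min(max(int(np.searchsorted(edges, r, side="right")) - 1, 0), n_bins - 1)
            i, j = sorted((typ_of[ia], typ_of[ib]))
            counts.setdefault((i, j), np.zeros(n_bins))[b] += 1

    types = sorted(type_names, key=type_names.get)
    n_t = len(types)
    u = np.zeros((n_t, n_t, n_bins))
    for (i, j), hist in counts.items():
        ref = hist[-1]
        if ref <= 0:
            continue
        for b in range(n_bins):
            if hist[b] <= 0:
                continue
            expected = (mids[b] / r_cut) ** alpha * (widths[b] / widths[-1]) * ref
            val = -eta * tc.RT * math.log(hist[b] / expected)
            u[i, j, b] = val
            u[j, i, b] = val
    u[:, :, -1] = 0.0  # reference bin: u vanishes at the cutoff by construction
    return PotentialTable(
        atom_typing=atom_typing,
        types=types,
        bin_edges=edges,
        u_bar=u,
        table_id=table_id,
    )
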