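"""Agonist classification, BE-theta correlation and electrostatic clustering.

Binding energies (kcal/mol, more negative = stronger) are divided into
weak / moderate / strong agonist classes per MHC class using cutoffs at
mean +/- one sample standard deviation of the analysed dataset.  The
binding energy is correlated against the docking angle theta with a
least-squares line and Pearson's r, with both user-listed and
automatically flagged (|studentized residual| > 2) outliers reported.
Interfaces are clustered on their electrostatic distance matrix with
average linkage (UPGMA), and the tree exports to Newick with
allele/TR-type/species leaf annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .electrostatics import SimilarityMatrix

__all__ = [
    "AgonistClass",
    "ClassCutoffs",
    "ClassificationSummary",
    "CorrelationReport",
    "ClusterTree",
    "derive_cutoffs",
    "classify_agonist",
    "summarize_classes",
    "correlate_be_theta",
    "cluster_interfaces",
]

WEAK, MODERATE, STRONG = "WEAK", "MODERATE", "STRONG"
AgonistClass = str


@dataclass(frozen=True)
class ClassCutoffs:
    """Weak/strong class boundaries at mean +/- sd (signed kcal/mol)."""

    mhc_class: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("standard deviation must be positive")

    @property
    def weak_bound(self) -> float:
        """Above (less negative than) this value a ligand is a weak agonist."""
        return self.mean + self.sd

    @property
    def strong_bound(self) -> float:
        """Below (more negative than) this value a ligand is a strong agonist."""
        return self.mean - self.sd


def derive_cutoffs(be_values: Sequence[float], mhc_class: str) -> ClassCutoffs:
    """Cutoffs from a dataset: mean and sample (n-1) standard deviation."""
    values = np.asarray(be_values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 binding energies to derive cutoffs")
    sd = float(values.std(ddof=1))
    if sd <= 0:
        raise ValueError("zero spread in binding energies; cutoffs undefined")
    return ClassCutoffs(mhc_class=mhc_class, mean=float(values.mean()), sd=sd)


def classify_agonist(be: float, cutoffs: ClassCutoffs) -> AgonistClass:
    """WEAK above mean+sd, STRONG below mean-sd, MODERATE between (inclusive).

    A positive (non-binding) energy is classified weak; boundary values
    belong to the moderate class.
    """
    if be > cutoffs.weak_bound:
        return WEAK
    if be < cutoffs.strong_bound:
        return STRONG
    return MODERATE


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class ClassificationSummary:
    n_total: int
    counts: Mapping[AgonistClass, int]
    percentages: Mapping[AgonistClass, int]  # rounded half-up to integers
    cutoffs: ClassCutoffs | None = None

    def __str__(self) -> str:
        parts = [
            f"{self.counts[c]} ({self.percentages[c]}%) {c.lower()}"
            for c in (WEAK, MODERATE, STRONG)
        ]
        return ", ".join(parts) + f" of {self.n_total}"


def summarize_classes(
    assignments: Sequence[AgonistClass], cutoffs: ClassCutoffs | None = None
) -> ClassificationSummary:
    if not assignments:
        raise ValueError("no class assignments to summarise")
    counts = {c: 0 for c in (WEAK, MODERATE, STRONG)}
    for a in assignments:
        if a not in counts:
            raise ValueError(f"unknown agonist class {a!r}")
        counts[a] += 1
    n = len(assignments)
    pct = {c: _round_half_up(100.0 * counts[c] / n) for c in counts}
    return ClassificationSummary(n_total=n, counts=counts, percentages=pct, cutoffs=cutoffs)


@dataclass(frozen=True)
class CorrelationReport:
    n: int
    pearson_r: float
    r_squared: float
    slope: float  # kcal/mol per degree, BE regressed on theta
    intercept: float
    slope_stderr: float
    outliers_excluded: tuple[str, ...]
    auto_flagged: tuple[str, ...]
    r_with_outliers: float

    def __post_init__(self) -> None:
        assert abs(self.r_squared - self.pearson_r**2) < 1e-12


def _pearson_line(theta: np.ndarray, be: np.ndarray):
    if np.ptp(theta) == 0 or np.ptp(be) == 0:
        raise ValueError("zero variance in theta or BE; correlation undefined")
    fit = sps.linregress(theta, be)
    return fit


def _studentized_residuals(theta: np.ndarray, be: np.ndarray) -> np.ndarray:
    """Internally studentized residuals of the be-on-theta simple regression."""
    n = len(theta)
    fit = sps.linregress(theta, be)
    resid = be - (fit.intercept + fit.slope * theta)
    h = 1.0 / n + (theta - theta.mean()) ** 2 / ((theta - theta.mean()) ** 2).sum()
    s2 = (resid**2).sum() / (n - 2)
    denom = np.sqrt(np.maximum(s2 * (1.0 - h), 1e-300))
    return resid / denom


def correlate_be_theta(
    records: Sequence[tuple[str, float, float]],
    exclusions: Sequence[str] = (),
    auto_flag: bool = True,
    studentized_cut: float = 2.0,
) -> CorrelationReport:
    """Pearson correlation and regression of BE on theta.

    ``records`` are (complex id, BE kcal/mol, theta degrees).  Ids in
    ``exclusions`` are removed before the reported fit; r over the full
    record list is reported alongside.  Records whose studentized residual
    exceeds ``studentized_cut`` in magnitude are flagged (not removed
    unless listed).
    """
    ids = [r[0] for r in records]
    be_all = np.array([r[1] for r in records], dtype=float)
    th_all = np.array([r[2] for r in records], dtype=float)
    excl = tuple(x for x in exclusions if x in ids)
    keep = np.array([i not in excl for i in ids])
    if keep.sum() < 3:
        raise ValueError("need at least 3 records after exclusion")

    fit_all = _pearson_line(th_all, be_all)
    fit = _pearson_line(th_all[keep], be_all[keep])

    flagged: tuple[str, ...] = ()
    if auto_flag and len(records) > 3:
        sr = _studentized_residuals(th_all, be_all)
        flagged = tuple(i for i, s in zip(ids, sr) if abs(s) > studentized_cut)

    return CorrelationReport(
        n=int(keep.sum()),
        pearson_r=float(fit.rvalue),
        r_squared=float(fit.rvalue) ** 2,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_stderr=float(fit.stderr),
        outliers_excluded=excl,
        auto_flagged=flagged,
        r_with_outliers=float(fit_all.rvalue),
    )


@dataclass
class ClusterTree:
    """UPGMA tree over complexes with leaf annotations.

    ``heights`` are ultrametric node heights (half the cophenetic distance
    between the merged groups, so every leaf is ``height`` below its merge
    node); ``merges`` follow scipy linkage indexing (leaves 0..n-1, merge k
    creates node n+k).
    """

    leaves: list[str]
    merges: np.ndarray  # (n-1, 2) int node indices
    heights: np.ndarray  # (n-1,) node heights
    annotations: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    linkage_method: str = "average"

    @property
    def linkage(self) -> np.ndarray:
        """Scipy-style linkage matrix (distances = 2 * heights)."""
        n = len(self.leaves)
        sizes = np.ones(2 * n - 1)
        z = np.zeros((n - 1, 4))
        for k, ((a, b), h) in enumerate(zip(self.merges, self.heights)):
            sizes[n + k] = sizes[a] + sizes[b]
            z[k] = [a, b, 2.0 * h, sizes[n + k]]
        return z

    def leaf_label(self, name: str) -> str:
        if name in self.annotations:
            allele, tr_type, species = self.annotations[name]
            return f"{name}|{allele}|{tr_type}|{species}"
        return name

    def flat_clusters(self, height: float) -> dict[str, int]:
        """Cut the tree at a node height; returns leaf -> cluster id."""
        assign = hierarchy.fcluster(self.linkage, t=2.0 * height, criterion="distance")
        return {leaf: int(c) for leaf, c in zip(self.leaves, assign)}

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.leaves[i] for i in order]

    def to_newick(self) -> str:
        n = len(self.leaves)
        node_h = {i: 0.0 for i in range(n)}
        reps: dict[int, str] = {}
        for i, leaf in enumerate(self.leaves):
            reps[i] = self.leaf_label(leaf).replace(" ", "_")
        for k, ((a, b), h) in enumerate(zip(self.merges, self.heights)):
            la = h - node_h[int(a)]
            lb = h - node_h[int(b)]
            reps[n + k] = f"({reps[int(a)]}:{la:.6g},{reps[int(b)]}:{lb:.6g})"
            node_h[n + k] = h
        return reps[2 * n - 2] + ";"


def cluster_interfaces(
    m: SimilarityMatrix,
    annotations: Mapping[str, tuple[str, str, str]] | None = None,
) -> ClusterTree:
    """Average-linkage (UPGMA) tree on the electrostatic distance matrix."""
    dist = np.array(m.dist, dtype=float)  # copy: the diagonal is zeroed below
    if dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-9, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains undefined (flagged) entries")
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.average(squareform(dist, checks=False))
    return ClusterTree(
        leaves=list(m.labels),
        merges=z[:, :2].astype(int),
        heights=z[:, 2] / 2.0,
        annotations=dict(annotations or {}),
        linkage_method="average",
    )
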