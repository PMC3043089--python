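"""End-to-end orchestration: structures in, per-complex and dataset reports out.

Per structure: parse -> annotate -> truncate -> contacts -> charges ->
binding energy -> electrostatic field on the shared groove-frame shell ->
docking angle.  Per dataset: class cutoffs -> agonist classification ->
BE-theta correlation -> electrostatic similarity -> UPGMA clustering.
Per-structure failures are recorded and do not abort the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import ContactMap, compute_contacts, extract_paratope_epitope
from .electrostatics import (
    ChargeScheme,
    PotentialField,
    assign_formal_charges,
    evaluate_potential_field,
    shell_grid,
    similarity_matrix,
)
from .energetics import PotentialTable, binding_energy, load_default_table, load_potential_table
from .geometry import (
    RingTooSmallError,
    docking_angle,
    groove_frame,
    groove_plane,
    match_complementary_charges,
    peptide_axis,
)
from .stats import (
    ClassCutoffs,
    ClassificationSummary,
    CorrelationReport,
    ClusterTree,
    classify_agonist,
    cluster_interfaces,
    correlate_be_theta,
    derive_cutoffs,
    summarize_classes,
)
from .structures import (
    ChainRole,
    ComplexStructure,
    TruncationSpec,
    annotate_roles,
    parse_pdb,
    truncate_complex,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "export_report"]


@dataclass
class PipelineConfig:
    """Validated run configuration (see ``PipelineConfig.from_yaml``)."""

    input_paths: list[Path] = field(default_factory=list)
    role_maps: dict[str, dict[str, str]] = field(default_factory=dict)  # per id or "*"
    truncation: TruncationSpec = field(default_factory=TruncationSpec)
    contact_cutoff: float = 5.0
    pairing_radius: float = 5.0
    charge_scheme: ChargeScheme = field(default_factory=ChargeScheme)
    dielectric: float = 80.0
    kappa: float = 0.124
    shell_heights: tuple[float, float] = (3.0, 7.0)
    shell_margin: float = 5.0
    grid_spacing: float = 1.0
    potential_table_path: Path | None = None
    exclusions: list[str] = field(default_factory=list)
    cluster_cut_height: float | None = None
    annotations: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    output_dir: Path = Path("trpmhc_out")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0 or self.pairing_radius <= 0:
            raise ValueError("contact cutoff and pairing radius must be positive")
        if self.grid_spacing <= 0:
            raise ValueError("grid spacing must be positive")

    def role_map_for(self, complex_id: str) -> dict[str, ChainRole]:
        raw = self.role_maps.get(complex_id, self.role_maps.get("*", {}))
        return {cid: ChainRole(role) for cid, role in raw.items()}

    def load_table(self) -> PotentialTable:
        if self.potential_table_path is None:
            return load_default_table()
        return load_potential_table(self.potential_table_path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text()) or {}
        kwargs: dict = {}
        base = path.parent
        if "inputs" in doc:
            inputs: list[Path] = []
            for entry in doc["inputs"]:
                p = (base / entry).resolve() if not Path(entry).is_absolute() else Path(entry)
                if p.is_dir():
                    inputs.extend(sorted(p.glob("*.pdb")))
                elif p.exists():
                    inputs.append(p)
                else:
                    raise FileNotFoundError(f"input path {entry!r} does not exist")
            kwargs["input_paths"] = inputs
        if "role_maps" in doc:
            kwargs["role_maps"] = doc["role_maps"]
        if "truncation" in doc:
            ranges = {
                ChainRole(role): tuple(rng)
                for role, rng in doc["truncation"].get("ranges", {}).items()
            }
            spec_kwargs = {}
            if ranges:
                spec_kwargs["ranges"] = ranges
            if "mhc2_alpha_range" in doc["truncation"]:
                spec_kwargs["mhc2_alpha_range"] = tuple(doc["truncation"]["mhc2_alpha_range"])
            kwargs["truncation"] = TruncationSpec(**spec_kwargs)
        for key in (
            "contact_cutoff",
            "pairing_radius",
            "dielectric",
            "kappa",
            "grid_spacing",
            "shell_margin",
            "seed",
            "cluster_cut_height",
        ):
            if key in doc:
                kwargs[key] = doc[key]
        if "shell_heights" in doc:
            kwargs["shell_heights"] = tuple(doc["shell_heights"])
        if "his_charged" in doc:
            kwargs["charge_scheme"] = ChargeScheme(his_charged=bool(doc["his_charged"]))
        if "potential_table" in doc:
            p = base / doc["potential_table"]
            if not p.exists():
                raise FileNotFoundError(f"potential table {p} does not exist")
            kwargs["potential_table_path"] = p
        if "exclusions" in doc:
            kwargs["exclusions"] = list(doc["exclusions"])
        if "annotations" in doc:
            kwargs["annotations"] = {
                k: tuple(v) for k, v in doc["annotations"].items()
            }
        if "output_dir" in doc:
            kwargs["output_dir"] = base / doc["output_dir"]
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "inputs": [str(p) for p in self.input_paths],
                "role_maps": self.role_maps,
                "contact_cutoff": self.contact_cutoff,
                "pairing_radius": self.pairing_radius,
                "dielectric": self.dielectric,
                "kappa": self.kappa,
                "shell_heights": list(self.shell_heights),
                "grid_spacing": self.grid_spacing,
                "exclusions": self.exclusions,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class StructureRow:
    complex_id: str
    mhc_class: str = "UNKNOWN"
    be: float | None = None
    agonist_class: str | None = None
    theta: float | None = None
    axis_ratio: float | None = None
    theta_low_confidence: bool = False
    n_contacts: int | None = None
    n_paratope: int | None = None
    n_epitope: int | None = None
    n_ring_points: int | None = None
    cluster_id: int | None = None
    error: str | None = None


@dataclass
class RunReport:
    rows: list[StructureRow]
    cutoffs: dict[str, ClassCutoffs]
    summaries: dict[str, ClassificationSummary]
    correlations: dict[str, CorrelationReport]
    tree: ClusterTree | None
    failures: dict[str, str]
    version: str
    config_hash: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "complex_id": r.complex_id,
                    "mhc_class": r.mhc_class,
                    "be": None if r.be is None else round(r.be, 4),
                    "agonist_class": r.agonist_class,
                    "theta": None if r.theta is None else round(r.theta, 2),
                    "axis_ratio": None if r.axis_ratio is None else round(r.axis_ratio, 3),
                    "theta_low_confidence": r.theta_low_confidence,
                    "n_contacts": r.n_contacts,
                    "n_paratope": r.n_paratope,
                    "n_epitope": r.n_epitope,
                    "n_ring_points": r.n_ring_points,
                    "cluster_id": r.cluster_id,
                    "error": r.error or "",
                }
                for r in self.rows
            ]
        )

    def global_blocks(self) -> dict:
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "cutoffs": {
                k: {"mean": c.mean, "sd": c.sd, "weak_bound": c.weak_bound, "strong_bound": c.strong_bound}
                for k, c in self.cutoffs.items()
            },
            "classification": {
                k: {"n_total": s.n_total, "counts": dict(s.counts), "percentages": dict(s.percentages)}
                for k, s in self.summaries.items()
            },
            "correlation": {
                k: {
                    "n": c.n,
                    "pearson_r": c.pearson_r,
                    "r_squared": c.r_squared,
                    "slope": c.slope,
                    "intercept": c.intercept,
                    "outliers_excluded": list(c.outliers_excluded),
                    "auto_flagged": list(c.auto_flagged),
                    "r_with_outliers": c.r_with_outliers,
                }
                for k, c in self.correlations.items()
            },
            "failures": self.failures,
        }


def process_structure(
    structure: ComplexStructure,
    cfg: PipelineConfig,
    table: PotentialTable,
    shared_grid: np.ndarray,
) -> tuple[StructureRow, PotentialField | None]:
    """All per-structure stages on an already-parsed, annotated complex."""
    row = StructureRow(complex_id=structure.id, mhc_class=structure.mhc_class)
    pmhc, tr = truncate_complex(structure, cfg.truncation)
    cm: ContactMap = compute_contacts(pmhc, tr, cutoff=cfg.contact_cutoff)
    paratope, epitope = extract_paratope_epitope(cm)
    row.n_contacts = len(cm)
    row.n_paratope = len(paratope.residues)
    row.n_epitope = len(epitope.residues)

    be = binding_energy(pmhc, tr, table)
    row.be = be.be

    pmhc_q = assign_formal_charges(pmhc, cfg.charge_scheme)
    tr_q = assign_formal_charges(tr, cfg.charge_scheme)

    plane = groove_plane(pmhc, tr)
    pep = peptide_axis(pmhc)
    field_out: PotentialField | None = None
    rot, origin = groove_frame(pmhc, tr)
    # express charges in the canonical groove frame so every complex shares the grid
    canon_q = _transform_charges(pmhc_q, rot, origin)
    field_out = evaluate_potential_field(
        canon_q,
        shared_grid,
        dielectric=cfg.dielectric,
        kappa=cfg.kappa,
        complex_id=structure.id,
    )

    try:
        ring = match_complementary_charges(
            pmhc_q, tr_q, cm, plane, pairing_radius=cfg.pairing_radius
        )
        result = docking_angle(ring, pep, plane, complex_id=structure.id)
        row.theta = result.theta
        row.axis_ratio = result.axis_ratio
        row.theta_low_confidence = result.low_confidence
        row.n_ring_points = result.n_ring_points
    except RingTooSmallError as exc:
        row.error = f"docking angle: {exc}"
    return row, field_out


def _transform_charges(q, rot: np.ndarray, origin: np.ndarray):
    from .electrostatics import ChargeSet, PointCharge

    out = ChargeSet()
    for c in q:
        new = rot @ (c.xyz - origin)
        out.charges.append(
            PointCharge(
                chain_id=c.chain_id,
                seq_id=c.seq_id,
                residue_name=c.residue_name,
                sign=c.sign,
                anchor=tuple(new),
                anchor_source=c.anchor_source,
            )
        )
    return out


def _load_structures(cfg: PipelineConfig) -> tuple[list[ComplexStructure], dict[str, str]]:
    structures = []
    failures: dict[str, str] = {}
    for path in cfg.input_paths:
        cid = path.stem
        try:
            c = parse_pdb(path.read_text(), structure_id=cid)
            c = annotate_roles(c, cfg.role_map_for(cid))
            structures.append(c)
        except Exception as exc:
            failures[cid] = f"{type(exc).__name__}: {exc}"
    return structures, failures


def run_pipeline(
    cfg: PipelineConfig,
    structures: Sequence[ComplexStructure] | None = None,
) -> RunReport:
    """Run every stage; ``structures`` bypasses file input when given."""
    if structures is None:
        structures, failures = _load_structures(cfg)
    else:
        structures, failures = list(structures), {}
    if not structures:
        raise RuntimeError("no structures could be processed")

    table = cfg.load_table()
    extent = _shared_extent(structures, cfg)
    grid = shell_grid(
        extent_x=extent[0],
        extent_y=extent[1],
        heights=cfg.shell_heights,
        spacing=cfg.grid_spacing,
    )

    rows: list[StructureRow] = []
    fields: list[PotentialField] = []
    for st in structures:
        try:
            row, f = process_structure(st, cfg, table, grid)
            rows.append(row)
            if f is not None:
                fields.append(f)
        except Exception as exc:
            failures[st.id] = f"{type(exc).__name__}: {exc}"
    if not rows:
        raise RuntimeError(
            "no structures survived the per-structure stages; "
            f"failures: {failures}"
        )

    cutoffs: dict[str, ClassCutoffs] = {}
    summaries: dict[str, ClassificationSummary] = {}
    correlations: dict[str, CorrelationReport] = {}
    for mhc_class in ("I", "II"):
        members = [r for r in rows if r.mhc_class == mhc_class and r.be is not None]
        if len(members) >= 3:
            try:
                co = derive_cutoffs([r.be for r in members], mhc_class)
            except ValueError:
                continue
            cutoffs[mhc_class] = co
            for r in members:
                r.agonist_class = classify_agonist(r.be, co)
            summaries[mhc_class] = summarize_classes(
                [r.agonist_class for r in members], co
            )
            recs = [
                (r.complex_id, r.be, r.theta)
                for r in members
                if r.theta is not None
            ]
            if len(recs) >= 3:
                try:
                    correlations[mhc_class] = correlate_be_theta(
                        recs, exclusions=cfg.exclusions
                    )
                except ValueError:
                    pass

    tree: ClusterTree | None = None
    if len(fields) >= 2:
        sim = similarity_matrix(fields)
        if not np.isnan(sim.dist).any():
            tree = cluster_interfaces(sim, cfg.annotations)
            if cfg.cluster_cut_height is not None:
                flat = tree.flat_clusters(cfg.cluster_cut_height)
            else:
                flat = tree.flat_clusters(float(tree.heights[-1]) * 0.5)
            by_id = {r.complex_id: r for r in rows}
            for leaf, cid in flat.items():
                if leaf in by_id:
                    by_id[leaf].cluster_id = cid

    return RunReport(
        rows=rows,
        cutoffs=cutoffs,
        summaries=summaries,
        correlations=correlations,
        tree=tree,
        failures=failures,
        version=__version__,
        config_hash=cfg.config_hash(),
    )


def _shared_extent(
    structures: Sequence[ComplexStructure], cfg: PipelineConfig
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Grid extent covering every groove footprint in the canonical frame."""
    xmax = ymax = 0.0
    for st in structures:
        try:
            pmhc, tr = truncate_complex(st, cfg.truncation)
            rot, origin = groove_frame(pmhc, tr)
            local = (rot @ (pmhc.coord_array() - origin).T).T
            xmax = max(xmax, float(np.abs(local[:, 0]).max()))
            ymax = max(ymax, float(np.abs(local[:, 1]).max()))
        except Exception:
            continue
    xmax = np.ceil(xmax + cfg.shell_margin)
    ymax = np.ceil(ymax + cfg.shell_margin)
    if xmax == 0 or ymax == 0:
        xmax = ymax = 20.0
    return (-xmax, xmax), (-ymax, ymax)


def export_report(
    report: RunReport,
    out_dir: str | Path,
    formats: Sequence[str] = ("tsv", "json", "newick"),
) -> dict[str, Path]:
    """Write the per-structure TSV, global JSON and Newick tree; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    header = f"# trpmhc {report.version} config={report.config_hash}\n"
    if "tsv" in formats:
        p = out / "per_structure.tsv"
        with open(p, "w") as fh:
            fh.write(header)
            report.to_frame().to_csv(fh, sep="\t", index=False)
        written["tsv"] = p
    if "json" in formats:
        p = out / "report.json"
        p.write_text(json.dumps(report.global_blocks(), indent=2, sort_keys=True) + "\n")
        written["json"] = p
    if "newick" in formats and report.tree is not None:
        p = out / "clusters.nwk"
        provenance = f"[trpmhc {report.version} config={report.config_hash}]"
        p.write_text(provenance + report.tree.to_newick() + "\n")
        written["newick"] = p
    return written
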