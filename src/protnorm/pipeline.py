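"""End-to-end orchestration with fail-fast validation and a run report.

Stage order: read → scale → aggregate → ratios → classify → cluster →
enrich → triage. The effective configuration is echoed into the report and
every number in it is recomputable from that echo plus the checksummed
inputs; rerunning with identical inputs reproduces the report byte for
byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .classify import (
    Thresholds,
    classify_records,
    count_filter_tiers,
    summarise,
)
from .cluster import (
    average_linkage,
    first_merge_partner,
    merge_table,
    pairwise_distance,
    to_newick,
    zscore_rows,
)
from .enrich import ora, results_to_frame
from .errors import SummaryError, ValidationError
from .io import (
    ColumnMap,
    GeneSetCollection,
    SampleDesign,
    read_gmt,
    read_quant_table,
    write_results,
)
from .preprocess import (
    aggregate_replicates,
    compute_ratios,
    scale_total_intensity,
)
from .triage import candidate_report, select_candidates

__all__ = ["PipelineConfig", "RunReport", "load_config", "paper_profile", "run"]

log = logging.getLogger("protnorm")

#: GO cellular-component categories used for biomarker triage.
TRIAGE_CATEGORIES = ("GO:0031012", "GO:0005886", "GO:0030054")


@dataclass
class PipelineConfig:
    quant_table: str
    gene_sets: list[str]
    out_dir: str
    columns: ColumnMap
    design: SampleDesign
    thresholds: Thresholds = field(default_factory=Thresholds)
    level: str = "strict"
    zero_is_missing: bool = False
    scaling_enabled: bool = True
    scaling_target: float | None = None
    aggregation_method: str = "mean"
    aggregation_min_detected: int = 1
    cluster_metric: str = "euclidean"
    cluster_axis: str = "cols"
    enrich_min_overlap: int = 2
    enrich_alpha: float = 0.05
    triage_categories: tuple[str, ...] = TRIAGE_CATEGORIES
    triage_require_normalised: bool = True
    match_on: str = "auto"
    profile: str = "default"

    def validate(self) -> None:
        """Fail fast: missing inputs or bad settings before any computation."""
        if not Path(self.quant_table).is_file():
            raise ValidationError(f"quant table not found: {self.quant_table}")
        for gmt in self.gene_sets:
            if not Path(gmt).is_file():
                raise ValidationError(f"gene-set file not found: {gmt}")
        if self.level not in ("standard", "strict"):
            raise ValidationError(f"unknown filter level {self.level!r}")
        if self.cluster_metric not in ("euclidean", "pearson"):
            raise ValidationError(f"unknown cluster metric {self.cluster_metric!r}")
        if self.cluster_axis not in ("rows", "cols"):
            raise ValidationError(f"unknown cluster axis {self.cluster_axis!r}")
        if self.aggregation_method not in ("mean", "median"):
            raise ValidationError(
                f"unknown aggregation method {self.aggregation_method!r}"
            )

    def echo(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["columns"] = {
            "accession": self.columns.accession,
            "unique_peptides": self.columns.unique_peptides,
            "gene_symbol": self.columns.gene_symbol,
            "abundances": dict(self.columns.abundances),
        }
        d["design"] = {
            "roles": dict(self.design.roles),
            "replicate_groups": dict(self.design.replicate_groups),
        }
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        d["triage_categories"] = list(self.triage_categories)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline configuration file."""
    with Path(path).open("r", encoding="utf-8") as fh:
        raw: Mapping[str, Any] = yaml.safe_load(fh)
    try:
        paths = raw["paths"]
        columns = raw["columns"]
        design = raw["design"]
    except KeyError as exc:
        raise ValidationError(f"config is missing section {exc}") from None
    cm = ColumnMap(
        accession=columns["accession"],
        unique_peptides=columns["unique_peptides"],
        gene_symbol=columns.get("gene_symbol"),
        abundances=dict(columns["abundances"]),
    )
    sd = SampleDesign(
        roles=dict(design["roles"]),
        replicate_groups=dict(design["replicate_groups"]),
    )
    thr = Thresholds(**raw.get("thresholds", {}))
    pre = raw.get("preprocess", {})
    scaling = pre.get("scaling", {})
    agg = pre.get("aggregation", {})
    clu = raw.get("cluster", {})
    enr = raw.get("enrich", {})
    tri = raw.get("triage", {})
    cfg = PipelineConfig(
        quant_table=str(paths["quant_table"]),
        gene_sets=[str(p) for p in paths.get("gene_sets", [])],
        out_dir=str(paths["out_dir"]),
        columns=cm,
        design=sd,
        thresholds=thr,
        level=raw.get("level", "strict"),
        zero_is_missing=bool(raw.get("zero_is_missing", False)),
        scaling_enabled=bool(scaling.get("enabled", True)),
        scaling_target=scaling.get("target"),
        aggregation_method=agg.get("method", "mean"),
        aggregation_min_detected=int(agg.get("min_detected", 1)),
        cluster_metric=clu.get("metric", "euclidean"),
        cluster_axis=clu.get("axis", "cols"),
        enrich_min_overlap=int(enr.get("min_overlap", 2)),
        enrich_alpha=float(enr.get("alpha", 0.05)),
        triage_categories=tuple(tri.get("categories", TRIAGE_CATEGORIES)),
        triage_require_normalised=bool(tri.get("require_normalised", True)),
        match_on=raw.get("match_on", "auto"),
        profile=raw.get("profile", "default"),
    )
    if cfg.profile == "paper":
        cfg = paper_profile(cfg)
    return cfg


def paper_profile(cfg: PipelineConfig) -> PipelineConfig:
    """Reproduction profile: the study's published thresholds and metric.

    Fold-change band 2 / 0.5, unique-peptide tiers 2 and 5, inclusive
    5-fold biomarker bound, the three cellular-component triage
    categories, and Pearson correlation distance for the profile-panel
    clustering. Idempotent and leaves paths untouched.
    """
    return dataclasses.replace(
        cfg,
        thresholds=Thresholds(
            fc_high=2.0,
            fc_low=0.5,
            up_min_standard=2,
            up_min_strict=5,
            biomarker_fold=5.0,
        ),
        triage_categories=TRIAGE_CATEGORIES,
        cluster_metric="pearson",
        profile="paper",
    )


@dataclass
class RunReport:
    version: str
    config: dict[str, Any]
    input_checksums: dict[str, str]
    tier_counts: dict[str, int]
    fraction_summary: dict[str, float]
    fraction_summary_standard: dict[str, float] | None
    cluster_grouping: dict[str, Any]
    enrichment: dict[str, list[dict[str, Any]]]
    candidates: list[dict[str, Any]]

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, **kwargs)

    def summary_text(self) -> str:
        fs = self.fraction_summary
        lines = [
            f"protnorm {self.version}",
            f"identified proteins:          {self.tier_counts['n_identified']}",
            f"regulated (standard tier):    {self.tier_counts['n_regulated_standard']}",
            f"unregulated (standard tier):  {self.tier_counts['n_unregulated_standard']}",
            f"regulated (strict tier):      {self.tier_counts['n_regulated_strict']}",
            f"regulated up / down:          {fs['n_regulated_up']} / {fs['n_regulated_down']}",
            (
                f"normalised / trend / not:     {fs['n_normalised']} / "
                f"{fs['n_trend']} / {fs['n_not_normalised']}"
            ),
            (
                f"pct normalised/trend/not:     {fs['pct_normalised']:.1f}% / "
                f"{fs['pct_trend']:.1f}% / {fs['pct_not_normalised']:.1f}%"
            ),
            (
                "treated groups with (regulated set / normalised subset): "
                f"{self.cluster_grouping.get('treated_partner')} / "
                f"{self.cluster_grouping.get('normalised_subset', {}).get('treated_partner')}"
            ),
            f"biomarker candidates:         {len(self.candidates)}",
        ]
        return "\n".join(lines) + "\n"


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run(cfg: PipelineConfig) -> RunReport:
    """Execute all stages and write result tables plus a JSON report."""
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    checksums = {cfg.quant_table: _sha256(cfg.quant_table)}
    for gmt in cfg.gene_sets:
        checksums[gmt] = _sha256(gmt)

    records = read_quant_table(
        cfg.quant_table, cfg.columns, zero_is_missing=cfg.zero_is_missing
    )
    log.info("quant_io: %d proteins read", len(records))

    if cfg.scaling_enabled:
        records = scale_total_intensity(records, cfg.scaling_target)
        log.info("preprocess: per-sample total-intensity scaling applied")
    aggregated = aggregate_replicates(
        records,
        cfg.design,
        method=cfg.aggregation_method,  # type: ignore[arg-type]
        min_detected=cfg.aggregation_min_detected,
    )
    ratios = compute_ratios(aggregated, cfg.design)
    log.info("preprocess: %d ratio records", len(ratios))

    tier_counts = count_filter_tiers(ratios, cfg.thresholds)
    log.info(
        "classify: identified=%d regulated_standard=%d unregulated_standard=%d "
        "regulated_strict=%d",
        tier_counts.n_identified,
        tier_counts.n_regulated_standard,
        tier_counts.n_unregulated_standard,
        tier_counts.n_regulated_strict,
    )
    classified = classify_records(ratios, cfg.thresholds, level=cfg.level)  # type: ignore[arg-type]
    write_results(classified, out_dir / "classified.tsv")
    summary = summarise(classified)

    classified_standard = classify_records(ratios, cfg.thresholds, level="standard")
    try:
        summary_standard: dict[str, float] | None = summarise(
            classified_standard
        ).as_dict()
    except SummaryError:
        summary_standard = None

    # --- clustering of condition profiles (complete cases) -----------------
    # Two views: the whole regulated set (global structure, where the
    # treated line may sit between reference and disease) and the
    # normalised subset (the panel where it should group with the
    # reference).
    role_of_group = cfg.design.group_roles()

    def _profile(accessions: set[str]) -> pd.DataFrame | None:
        import numpy as np

        rows = []
        for rec in aggregated:
            if rec.accession not in accessions:
                continue
            by_role = {
                role_of_group[g]: v
                for g, v in rec.abundances.items()
                if g in role_of_group and v > 0
            }
            if set(role_of_group.values()) <= set(by_role):
                rows.append({"accession": rec.accession, **by_role})
        if len(rows) < 2:
            return None
        profile = pd.DataFrame(rows).set_index("accession")
        profile = profile[["reference", "disease", "treated"]]
        return pd.DataFrame(
            np.log2(profile.to_numpy(dtype=float)),
            index=profile.index,
            columns=profile.columns,
        )

    def _grouping(profile: pd.DataFrame, stem: str | None) -> dict[str, Any]:
        z = zscore_rows(profile)
        d = pairwise_distance(z, metric=cfg.cluster_metric, axis=cfg.cluster_axis)  # type: ignore[arg-type]
        tree = average_linkage(d)
        if stem is not None:
            merge_table(tree).to_csv(
                out_dir / f"{stem}.tsv", sep="\t", index=False,
                lineterminator="\n",
            )
            (out_dir / f"{stem}.nwk").write_text(to_newick(tree) + "\n")
        out: dict[str, Any] = {"n_proteins": len(profile)}
        if cfg.cluster_axis == "cols":
            partner = first_merge_partner(tree, "treated")
            out["treated_partner"] = (
                partner if isinstance(partner, str) else sorted(partner)
            )
        return out

    grouping: dict[str, Any] = {"metric": cfg.cluster_metric}
    reg_mask = classified["regulation_call"].isin(
        ["regulated_up", "regulated_down"]
    )
    regulated_profile = _profile(set(classified.loc[reg_mask, "accession"]))
    if regulated_profile is not None:
        grouping["regulated_set"] = _grouping(regulated_profile, "linkage")
        grouping["treated_partner"] = grouping["regulated_set"].get(
            "treated_partner"
        )
    norm_mask = classified["normalisation_call"] == "normalised"
    normalised_profile = _profile(set(classified.loc[norm_mask, "accession"]))
    if normalised_profile is not None:
        grouping["normalised_subset"] = _grouping(
            normalised_profile, "linkage_normalised"
        )
    log.info("cluster: grouping=%s", grouping)

    # --- enrichment: regulated selections vs quantified universe -----------
    universe = set(classified["accession"])
    enrichment: dict[str, list[dict[str, Any]]] = {}
    if cfg.gene_sets:
        collection = GeneSetCollection()
        for gmt in cfg.gene_sets:
            part = read_gmt(gmt)
            for s in part.sets.values():
                if s.set_id in collection.sets:
                    raise ValidationError(
                        f"gene set {s.set_id!r} appears in multiple GMT files"
                    )
                collection.sets[s.set_id] = s
        for direction, call in (
            ("upregulated", "regulated_up"),
            ("downregulated", "regulated_down"),
        ):
            selected = set(
                classified.loc[
                    classified["regulation_call"] == call, "accession"
                ]
            )
            results = ora(
                selected, universe, collection, min_overlap=cfg.enrich_min_overlap
            )
            frame = results_to_frame(results)
            frame.to_csv(
                out_dir / f"enrichment_{direction}.tsv",
                sep="\t",
                index=False,
                lineterminator="\n",
            )
            enrichment[direction] = frame.to_dict(orient="records")
            log.info(
                "enrich: %s — %d sets tested, %d below alpha=%.3g",
                direction,
                len(results),
                sum(r.q_value <= cfg.enrich_alpha for r in results),
                cfg.enrich_alpha,
            )

        available = [c for c in cfg.triage_categories if c in collection]
        candidates = (
            select_candidates(
                classified,
                collection,
                available,
                cfg.thresholds,
                require_normalised=cfg.triage_require_normalised,
                match_on=cfg.match_on,  # type: ignore[arg-type]
            )
            if available
            else []
        )
    else:
        candidates = []
    report_frame = candidate_report(candidates)
    write_results(report_frame, out_dir / "candidates.tsv")
    log.info("triage: %d candidates", len(candidates))

    report = RunReport(
        version=__version__,
        config=cfg.echo(),
        input_checksums=checksums,
        tier_counts=tier_counts.as_dict(),
        fraction_summary=summary.as_dict(),
        fraction_summary_standard=summary_standard,
        cluster_grouping=grouping,
        enrichment=enrichment,
        candidates=report_frame.drop(
            columns=["literature_concordance", "expression_atlas_concordance"]
        ).to_dict(orient="records"),
    )
    (out_dir / "report.json").write_text(report.to_json())
    (out_dir / "report.txt").write_text(report.summary_text())
    return report
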