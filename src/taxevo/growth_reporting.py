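"""Growth-kinetics utilities and the end-to-end pipeline driver.

Doubling times are estimated from exponential growth, ``N = N0 * exp(k t)``,
by ordinary least squares of ``ln N`` on ``t`` inside a user-chosen
exponential window; the doubling time is ``ln 2 / k``.  Drug sensitivity is
summarised as the ratio of surviving cells in a sub-line over the parental
line at the same dose.

:func:`run_pipeline` wires the whole analysis together from a YAML
configuration: read inputs, classify acquired/selective events, triage
classes, call copy-number changes with expression-concordance rescue, rank
candidate genes against the seed set, tally hallmarks, and test gene-set
over-representation.  All reports are TSV with JSON mirrors plus a run log
carrying input checksums; reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cna_expression as cna
from . import gene_prioritization as prio
from . import stage_io
from . import variant_evolution as ve
from .errors import (
    ConfigurationError,
    NonGrowingCurveError,
    TaxevoError,
    UndefinedRatioError,
    ValidationError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# growth kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthCurve:
    """Absorbance (proportional to cell number) versus time in days."""

    times: tuple[float, ...]
    values: tuple[float, ...]
    exponential_window: tuple[int, int]  # inclusive index range

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValidationError("times and values must have equal length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValidationError("times: must be strictly increasing")
        lo, hi = self.exponential_window
        if not (0 <= lo <= hi < len(self.times)):
            raise ValidationError("exponential_window: indices out of range")
        if any(v <= 0 for v in self.values[lo : hi + 1]):
            raise ValidationError("values: must be positive within the exponential window")

    @property
    def window_points(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.exponential_window
        return np.asarray(self.times[lo : hi + 1]), np.asarray(self.values[lo : hi + 1])


@dataclass(frozen=True)
class SurvivalRatio:
    label: str
    docetaxel_nM: float
    ratio: float


def doubling_time(curve: GrowthCurve) -> float:
    """Doubling time in days from a log-linear least-squares fit of the window."""
    t, v = curve.window_points
    if len(t) < 2:
        raise ValidationError("exponential_window: need at least two points")
    k = np.polyfit(t, np.log(v), 1)[0]
    if k <= 0:
        raise NonGrowingCurveError(f"fitted growth rate k={k:.4g} is not positive")
    return float(np.log(2.0) / k)


def survival_ratio(
    sub_viability: float, parental_viability: float, label: str = "", docetaxel_nM: float = 0.0
) -> SurvivalRatio:
    """Sub-line viability over parental viability at the same dose."""
    for name, v in (("sub_viability", sub_viability), ("parental_viability", parental_viability)):
        if not 0.0 <= v <= 1.5:  # >1 tolerated for assay noise
            raise ValidationError(f"{name}: {v} outside [0, 1.5]")
    if parental_viability == 0.0:
        raise UndefinedRatioError("parental viability is zero; ratio undefined")
    return SurvivalRatio(label=label, docetaxel_nM=docetaxel_nM, ratio=sub_viability / parental_viability)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    series: stage_io.StageSeries
    vcf: Path
    annotations: Path
    region_counts: dict[str, Path] = field(default_factory=dict)
    gene_models: Optional[Path] = None
    expression: Optional[Path] = None
    network: Optional[Path] = None
    seed_genes: Optional[Path] = None
    hallmarks: Optional[Path] = None
    enrichment_terms: Optional[Path] = None
    cna_alpha: float = 0.05
    cna_reference: str = "parental"  # or "preceding"
    restart_prob: float = 0.5
    enrichment_alpha: float = 0.05
    out_dir: Path = Path("reports")
    seed: int = 0


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def resolve(p):
        return None if p is None else (base / p if not Path(p).is_absolute() else Path(p))

    stages = tuple(
        stage_io.Stage(
            label=s["label"],
            docetaxel_nM=float(s.get("docetaxel_nM", 0.0)),
            role=s.get("role", "intermediate"),
        )
        for s in raw["series"]
    )
    inputs = raw.get("inputs", {})
    params = raw.get("parameters", {})
    if "vcf" not in inputs or "annotations" not in inputs:
        raise ConfigurationError("config inputs must name at least 'vcf' and 'annotations'")
    region_counts = {
        label: resolve(p) for label, p in (inputs.get("region_counts") or {}).items()
    }
    cfg = PipelineConfig(
        series=stage_io.StageSeries(stages=stages),
        vcf=resolve(inputs["vcf"]),
        annotations=resolve(inputs["annotations"]),
        region_counts=region_counts,
        gene_models=resolve(inputs.get("gene_models")),
        expression=resolve(inputs.get("expression")),
        network=resolve(inputs.get("network")),
        seed_genes=resolve(inputs.get("seed_genes")),
        hallmarks=resolve(inputs.get("hallmarks")),
        enrichment_terms=resolve(inputs.get("enrichment_terms")),
        cna_alpha=float(params.get("cna_alpha", 0.05)),
        cna_reference=str(params.get("cna_reference", "parental")),
        restart_prob=float(params.get("restart_prob", 0.5)),
        enrichment_alpha=float(params.get("enrichment_alpha", 0.05)),
        out_dir=resolve(raw.get("out_dir", "reports")) or base / "reports",
        seed=int(raw.get("seed", 0)),
    )
    if cfg.cna_reference not in ("parental", "preceding"):
        raise ConfigurationError(f"cna_reference: {cfg.cna_reference!r} not parental/preceding")
    if cfg.network is not None and cfg.seed_genes is None:
        raise ConfigurationError("network given without seed_genes: prioritization needs both")
    return cfg


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _ReportWriter:
    """Writes TSV + JSON mirror pairs; can roll back everything it wrote."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.written: list[Path] = []

    def table(self, name: str, df: pd.DataFrame, index: bool = False) -> Path:
        tsv = self.out_dir / f"{name}.tsv"
        df.to_csv(tsv, sep="\t", index=index)
        records = json.loads(df.reset_index().to_json(orient="records") if index
                             else df.to_json(orient="records"))
        js = self.out_dir / f"{name}.json"
        js.write_text(json.dumps(records, indent=2) + "\n")
        self.written += [tsv, js]
        return tsv

    def json(self, name: str, payload) -> Path:
        p = self.out_dir / f"{name}.json"
        p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        self.written.append(p)
        return p

    def rollback(self) -> None:
        for p in self.written:
            p.unlink(missing_ok=True)


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> dict[str, Path]:
    """Run the full staged analysis; returns {report name: path}.

    Any stage error aborts with the stage name and cause, and removes the
    partial outputs already written.
    """
    cfg = load_pipeline_config(config_path)
    if out_dir is not None:
        cfg.out_dir = Path(out_dir)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    writer = _ReportWriter(cfg.out_dir)
    reports: dict[str, Path] = {}
    stage_name = "setup"
    try:
        series = cfg.series
        stage_name = "stage_io"
        variants = stage_io.read_multistage_vcf(cfg.vcf, series)
        annotations = stage_io.read_annotation_table(cfg.annotations)
        by_variant: dict[str, list] = {}
        for a in annotations:
            by_variant.setdefault(a.variant_key, []).append(a)

        stage_name = "variant_evolution"
        calls = [ve.classify_variant(v, series) for v in variants]
        reports["stage_summary"] = writer.table(
            "stage_summary", ve.stage_summary_table(variants, calls, series), index=True
        )
        tallies = []
        for i, label in enumerate(series.labels[1:], start=1):
            events = [
                (c.variant_key, by_variant.get(c.variant_key, []))
                for c in calls
                if c.acquired_stage == i and c.selected
            ]
            tallies.append(ve.tally_consequences(events, label))
        reports["consequence_tallies"] = writer.table(
            "consequence_tallies", ve.consequence_tally_table(tallies), index=True
        )
        reports["classification"] = writer.table(
            "classification", ve.classification_table(calls, by_variant, series)
        )

        gene_calls_by_stage: dict[str, list[cna.CnaGeneCall]] = {}
        if cfg.region_counts:
            stage_name = "cna_expression"
            table = stage_io.read_region_counts(cfg.region_counts)
            missing = set(series.labels) - set(table.counts.columns)
            if missing:
                raise ConfigurationError(f"region counts missing for stages {sorted(missing)}")
            genes = stage_io.read_gene_models(cfg.gene_models) if cfg.gene_models else []
            expression = stage_io.read_expression(cfg.expression) if cfg.expression else []
            segments: list[cna.CnaSegmentCall] = []
            for i, label in enumerate(series.labels[1:], start=1):
                ref = series.labels[0] if cfg.cna_reference == "parental" else series.labels[i - 1]
                seg = cna.call_cna_from_table(table, label, ref, alpha=cfg.cna_alpha)
                segments.extend(seg)
                gene_calls_by_stage[label] = cna.map_to_genes(seg, genes)
            final_label = series.labels[-1]
            final_calls = gene_calls_by_stage.get(final_label, [])
            all_gene_calls: list[cna.CnaGeneCall] = []
            for label in series.labels[1:]:
                all_gene_calls.extend(
                    cna.expression_concordance(
                        gene_calls_by_stage[label], expression, final_calls
                    )
                )
            gene_calls_by_stage = {
                label: [c for c in all_gene_calls if c.stage_label == label]
                for label in series.labels[1:]
            }
            reports["cna_segments"] = writer.table(
                "cna_segments",
                cna.segment_calls_table([s for s in segments if s.direction != "neutral"]),
            )
            reports["cna_genes"] = writer.table("cna_genes", cna.gene_calls_table(all_gene_calls))

        stage_name = "gene_prioritization"
        candidates_by_stage: dict[str, set[str]] = {label: set() for label in series.labels[1:]}
        for c in calls:
            if c.acquired_stage is None or not c.selected:
                continue
            anns = by_variant.get(c.variant_key, [])
            if anns and ve.triage_class(anns) == "A":
                label = series.labels[c.acquired_stage]
                candidates_by_stage[label].update(a.gene_id for a in anns)
        for label, gene_calls in gene_calls_by_stage.items():
            candidates_by_stage[label].update(
                c.gene_id for c in gene_calls if c.concordant_expression
            )
        overall = set().union(*candidates_by_stage.values()) if candidates_by_stage else set()

        if cfg.network is not None:
            network = stage_io.read_network(cfg.network)
            seeds = stage_io.read_gene_list(cfg.seed_genes)
            scores = prio.rwr_scores(network, seeds, restart_prob=cfg.restart_prob)
            rankings: list[prio.PriorityScore] = []
            for label in series.labels[1:]:
                rankings.extend(prio.rank_candidates(scores, candidates_by_stage[label], label))
            rankings.extend(prio.rank_candidates(scores, overall, "overall"))
            reports["rankings"] = writer.table("rankings", prio.ranking_table(rankings))

        if cfg.hallmarks is not None:
            hallmark_map = stage_io.read_hallmark_map(cfg.hallmarks)
            counts, unmapped = prio.map_hallmarks(overall, hallmark_map)
            df = pd.DataFrame(
                [{"category": c, "n_genes": n} for c, n in counts.items()]
            )
            reports["hallmark_counts"] = writer.table("hallmark_counts", df)
            writer.json("hallmark_unmapped", sorted(unmapped))

        if cfg.enrichment_terms is not None and cfg.gene_models is not None:
            term_df = pd.read_csv(cfg.enrichment_terms, sep="\t")
            terms = {
                t: set(g["gene_id"]) for t, g in term_df.groupby("term")
            }
            background = {g.gene_id for g in stage_io.read_gene_models(cfg.gene_models)}
            inside = overall & background
            dropped = overall - background
            if dropped:
                logger.warning("enrichment: candidates outside background dropped: %s",
                               sorted(dropped))
            if inside:
                enr = prio.enrich_gene_sets(
                    inside, terms, background, alpha=cfg.enrichment_alpha
                )
                reports["enrichment"] = writer.table("enrichment", enr)

        stage_name = "run_log"
        inputs = {
            "vcf": cfg.vcf,
            "annotations": cfg.annotations,
            **{f"region_counts:{k}": v for k, v in cfg.region_counts.items()},
            "gene_models": cfg.gene_models,
            "expression": cfg.expression,
            "network": cfg.network,
            "seed_genes": cfg.seed_genes,
            "hallmarks": cfg.hallmarks,
            "enrichment_terms": cfg.enrichment_terms,
        }
        log = {
            "config_sha256": _sha256(Path(config_path)),
            "seed": cfg.seed,
            "stages": list(series.labels),
            "input_sha256": {
                k: _sha256(p) for k, p in inputs.items() if p is not None
            },
            "reports": sorted(str(p.name) for p in reports.values()),
        }
        reports["run_log"] = writer.json("run_log", log)
    except TaxevoError as exc:
        writer.rollback()
        raise type(exc)(f"pipeline stage {stage_name!r} failed: {exc}") from exc
    except Exception:
        writer.rollback()
        raise
    return reports
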