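"""Region log-ratio copy-number detection and expression-concordance rescue.

Copy-number changes between a test sub-line and a reference stage are scored
per capture region: read counts are normalised to a common library size
(counts per million), stabilised with a 0.5 pseudocount, and compared as
log2 ratios.  Significance comes from an empirical null over all regions —
most regions are copy-neutral, so a robust (median/MAD) z-score with BH
correction flags outlying gains and losses.  Because every comparison uses
the parental or a preceding stage as reference, any detected change is by
construction acquired.

An early-stage copy-number call that is not re-detected in the final
resistant stage may still be real: if the overlapping gene's final-stage
expression moved in the concordant direction (up for a gain, down for a
loss, and significantly so), the call is rescued as persistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConsistencyError, EstimationError, ValidationError
from .stage_io import ExpressionRecord, GeneModel, RegionCountTable

logger = logging.getLogger(__name__)

MIN_REGIONS_FOR_NULL = 20
_CPM_SCALE = 1e6
_MAD_TO_SIGMA = 1.4826  # consistency factor for a normal null


@dataclass(frozen=True)
class CnaSegmentCall:
    stage_label: str
    reference_label: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    log2_ratio: float
    p_value: float
    q_value: float
    direction: str  # gain | loss | neutral

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss", "neutral"):
            raise ValidationError(f"direction: {self.direction!r}")
        if self.direction == "gain" and not self.log2_ratio > 0:
            raise ValidationError("gain requires log2_ratio > 0")
        if self.direction == "loss" and not self.log2_ratio < 0:
            raise ValidationError("loss requires log2_ratio < 0")
        if not (0 <= self.p_value <= 1 and 0 <= self.q_value <= 1):
            raise ValidationError("p/q values must lie in [0,1]")


@dataclass(frozen=True)
class CnaGeneCall:
    gene_id: str
    stage_label: str
    direction: str  # gain | loss
    log2_ratio: float
    concordant_expression: bool = False
    persistent: bool = False


def region_log_ratios(
    test_counts: Sequence[int] | np.ndarray,
    reference_counts: Sequence[int] | np.ndarray,
    regions: Optional[pd.DataFrame] = None,
) -> np.ndarray:
    """Per-region log2 ratio of library-normalised test over reference depth.

    Counts are scaled to counts-per-million before a 0.5 pseudocount is
    added, which makes the ratios exactly invariant to multiplying either
    library by a constant and exactly antisymmetric under swapping test and
    reference.
    """
    t = np.asarray(test_counts, dtype=float)
    c = np.asarray(reference_counts, dtype=float)
    if t.shape != c.shape:
        raise ConsistencyError(f"count vectors differ in length: {t.shape} vs {c.shape}")
    if regions is not None and len(regions) != len(t):
        raise ConsistencyError("regions table does not match count vectors")
    if t.sum() <= 0 or c.sum() <= 0:
        raise ValidationError("total counts must be positive in both libraries")
    t_norm = t * (_CPM_SCALE / t.sum())
    c_norm = c * (_CPM_SCALE / c.sum())
    return np.log2(t_norm + 0.5) - np.log2(c_norm + 0.5)


def call_cna(
    ratios: np.ndarray,
    regions: pd.DataFrame,
    stage_label: str,
    reference_label: str,
    alpha: float = 0.05,
) -> list[CnaSegmentCall]:
    """Call gains/losses against the empirical null of all region ratios.

    The null is centred at the median ratio with spread 1.4826*MAD; two-sided
    normal p-values are BH-adjusted across regions and regions with
    q <= alpha are called in the direction of their ratio.  A degenerate
    null (MAD = 0) yields no calls rather than dividing by zero.
    """
    ratios = np.asarray(ratios, dtype=float)
    if len(ratios) < MIN_REGIONS_FOR_NULL:
        raise EstimationError(
            f"need >= {MIN_REGIONS_FOR_NULL} regions to estimate the null, got {len(ratios)}"
        )
    if len(regions) != len(ratios):
        raise ConsistencyError("regions table does not match ratio vector")
    center = float(np.median(ratios))
    mad = float(np.median(np.abs(ratios - center)))
    if mad == 0.0:
        logger.warning("degenerate ratio null (MAD = 0); calling no gains/losses")
        p = np.ones_like(ratios)
        q = np.ones_like(ratios)
    else:
        z = (ratios - center) / (_MAD_TO_SIGMA * mad)
        p = 2.0 * stats.norm.sf(np.abs(z))
        q = multipletests(p, method="fdr_bh")[1]
    calls = []
    for i, row in enumerate(regions.itertuples(index=False)):
        if q[i] <= alpha and ratios[i] != 0.0:
            direction = "gain" if ratios[i] > 0 else "loss"
        else:
            direction = "neutral"
        calls.append(
            CnaSegmentCall(
                stage_label=stage_label,
                reference_label=reference_label,
                chrom=row.chrom,
                start=row.start,
                end=row.end,
                log2_ratio=float(ratios[i]),
                p_value=float(p[i]),
                q_value=float(q[i]),
                direction=direction,
            )
        )
    return calls


def call_cna_from_table(
    table: RegionCountTable,
    stage_label: str,
    reference_label: str,
    alpha: float = 0.05,
) -> list[CnaSegmentCall]:
    """Ratio computation plus significance calling straight from a count table."""
    ratios = region_log_ratios(
        table.stage(stage_label), table.stage(reference_label), table.regions
    )
    return call_cna(ratios, table.regions, stage_label, reference_label, alpha=alpha)


def map_to_genes(
    calls: Iterable[CnaSegmentCall], gene_models: Sequence[GeneModel]
) -> list[CnaGeneCall]:
    """Link non-neutral segments to every gene they overlap by >= 1 base.

    A segment spanning k genes emits k gene calls.  Coordinates are 1-based
    inclusive on both sides.
    """
    trees: dict[str, IntervalTree] = {}
    for gene in gene_models:
        # half-open tree coordinates: [start, end+1)
        trees.setdefault(gene.chrom, IntervalTree()).addi(gene.start, gene.end + 1, gene)
    out: list[CnaGeneCall] = []
    for call in calls:
        if call.direction == "neutral":
            continue
        tree = trees.get(call.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(call.start, call.end + 1), key=lambda iv: iv.data.gene_id)
        for iv in hits:
            out.append(
                CnaGeneCall(
                    gene_id=iv.data.gene_id,
                    stage_label=call.stage_label,
                    direction=call.direction,
                    log2_ratio=call.log2_ratio,
                )
            )
    return out


def expression_concordance(
    gene_calls: Iterable[CnaGeneCall],
    expression: Sequence[ExpressionRecord],
    final_calls: Iterable[CnaGeneCall],
) -> list[CnaGeneCall]:
    """Flag concordant expression and decide persistence for each gene call.

    Concordance requires a significant final-vs-parental fold change in the
    direction of the copy-number change (up for gains, down for losses).
    A call is persistent when re-detected in the final stage in the same
    direction, or rescued by concordant expression.  Genes missing from the
    expression table are simply non-concordant (logged, not an error).
    """
    expr = {r.gene_id: r for r in expression}
    final = {(c.gene_id, c.direction) for c in final_calls}
    out = []
    for call in gene_calls:
        rec = expr.get(call.gene_id)
        if rec is None:
            logger.info("gene %s absent from expression table", call.gene_id)
            concordant = False
        elif call.direction == "gain":
            concordant = rec.significant and rec.log2fc > 0
        else:
            concordant = rec.significant and rec.log2fc < 0
        persistent = (call.gene_id, call.direction) in final or concordant
        out.append(replace(call, concordant_expression=concordant, persistent=persistent))
    return out


def segment_calls_table(calls: Sequence[CnaSegmentCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "stage": c.stage_label,
                "reference": c.reference_label,
                "log2_ratio": c.log2_ratio,
                "p_value": c.p_value,
                "q_value": c.q_value,
                "direction": c.direction,
            }
            for c in calls
        ],
        columns=[
            "chrom", "start", "end", "stage", "reference",
            "log2_ratio", "p_value", "q_value", "direction",
        ],
    )


def gene_calls_table(calls: Sequence[CnaGeneCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "stage": c.stage_label,
                "direction": c.direction,
                "log2_ratio": c.log2_ratio,
                "concordant_expression": int(c.concordant_expression),
                "persistent": int(c.persistent),
            }
            for c in calls
        ],
        columns=["gene_id", "stage", "direction", "log2_ratio",
                 "concordant_expression", "persistent"],
    )
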