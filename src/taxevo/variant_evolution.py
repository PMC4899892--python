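"""Acquired-variant calling, selective-event filtering and A/B/C triage.

The classification follows the staged-evolution logic of the resistance
models: a variant is *acquired* at the earliest stage where it is called but
was absent — with adequate read depth (>4) and zero reads supporting the
alternative allele — in the stage immediately preceding it.  If the only
candidate transitions have inadequate or unknown preceding depth the variant
is *unassessable*.  An acquired variant that remains called in every later
stage up to and including the final resistant stage is a *selective event*;
an acquired variant that disappears again is *transient* and excluded from
downstream analysis.

Selective events are triaged into three functional classes:

* Class A — likely functional: truncating/splice-disrupting/initiator/TF
  binding-site events, and missense predicted deleterious by SIFT or
  PolyPhen or falling in an annotated protein domain;
* Class B — indeterminate without functional follow-up: in-frame indels,
  benign missense, splice-region and regulatory-type events;
* Class C — likely silent: synonymous, UTR, intronic, intergenic and other
  non-coding consequences.

A variant's label is the most severe (A < B < C) over its transcript
annotations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError, VocabularyError
from .stage_io import AnnotatedConsequence, StageSeries, VariantObservation

MIN_PRECEDING_DEPTH = 5  # "greater than four" reads in the preceding stage

# Class membership for unconditional terms; missense is conditional (see
# classify_annotation).  The vocabulary is closed: unknown terms are errors.
_CLASS_A_TERMS = frozenset(
    {
        "splice_donor_variant",
        "splice_acceptor_variant",
        "stop_gained",
        "stop_lost",
        "frameshift_variant",
        "initiator_codon_variant",
        "TF_binding_site_variant",
    }
)
_CLASS_B_TERMS = frozenset(
    {
        "inframe_insertion",
        "inframe_deletion",
        "splice_region_variant",
        "incomplete_terminal_codon_variant",
        "mature_miRNA_variant",
        "NMD_transcript_variant",
        "regulatory_region_variant",
        "feature_elongation",
        "feature_truncation",
    }
)
_CLASS_C_TERMS = frozenset(
    {
        "synonymous_variant",
        "stop_retained_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "non_coding_exon_variant",
        "nc_transcript_variant",
        "intron_variant",
        "upstream_gene_variant",
        "downstream_gene_variant",
        "intergenic_variant",
    }
)

CONSEQUENCE_VOCABULARY = frozenset(
    _CLASS_A_TERMS | _CLASS_B_TERMS | _CLASS_C_TERMS | {"missense_variant"}
)

_SEVERITY = {"A": 0, "B": 1, "C": 2}


@dataclass(frozen=True)
class AcquisitionCall:
    """Per-variant acquisition/selection outcome."""

    variant_key: str
    acquired_stage: Optional[int]
    assessable: bool
    selected: bool = False
    transient: bool = False

    def __post_init__(self) -> None:
        if self.acquired_stage is not None and not self.assessable:
            raise ValidationError("acquired_stage set on an unassessable call")
        if self.selected and self.transient:
            raise ValidationError("selected and transient are mutually exclusive")
        if (self.selected or self.transient) and self.acquired_stage is None:
            raise ValidationError("selected/transient require an acquisition stage")


@dataclass(frozen=True)
class ConsequenceTally:
    """Per-stage counts of selective-event annotations by consequence term."""

    stage_label: str
    counts: Mapping[str, int]
    total: int


def call_acquired(variant: VariantObservation, series: StageSeries) -> AcquisitionCall:
    """Locate the earliest acquisition of a variant along the stage series.

    A stage ``i >= 1`` is an acquisition when the variant is called at ``i``,
    not called at ``i-1``, and the preceding stage has depth >= 5 with zero
    alternative reads.  Candidate transitions whose preceding depth is <= 4
    or unknown cannot be assessed; if no assessable acquisition exists but
    such a transition does, the variant is flagged unassessable.  Variants
    called in the parental stage are never acquired.
    """
    n = len(series)
    if n < 2:
        raise ConfigurationError("stage series must have at least two stages")
    if len(variant.called) != n:
        raise ConfigurationError(
            f"{variant.key}: observations cover {len(variant.called)} stages, series has {n}"
        )
    if variant.called[0]:
        return AcquisitionCall(variant.key, acquired_stage=None, assessable=True)
    unassessable_seen = False
    for i in range(1, n):
        if not (variant.called[i] and not variant.called[i - 1]):
            continue
        depth = variant.depth[i - 1]
        alt = variant.alt_depth[i - 1]
        if depth is None or depth < MIN_PRECEDING_DEPTH or alt is None:
            unassessable_seen = True
            continue
        if alt == 0:
            return AcquisitionCall(variant.key, acquired_stage=i, assessable=True)
        # prior evidence of the allele: assessed, but not an acquisition
    return AcquisitionCall(variant.key, acquired_stage=None, assessable=not unassessable_seen)


def call_selected(
    call: AcquisitionCall, variant: VariantObservation, series: StageSeries
) -> AcquisitionCall:
    """Split acquired variants into selective events and transient events.

    Selected means called at every stage after acquisition, including the
    final resistant stage; acquisition at the final stage is vacuously
    selected.  Acquired but not selected is transient.
    """
    if call.acquired_stage is None:
        return call
    persists = all(variant.called[j] for j in range(call.acquired_stage + 1, len(series)))
    return replace(call, selected=persists, transient=not persists)


def classify_variant(variant: VariantObservation, series: StageSeries) -> AcquisitionCall:
    """Convenience: acquisition and selection in one call."""
    return call_selected(call_acquired(variant, series), variant, series)


def classify_annotation(annotation: AnnotatedConsequence) -> str:
    """Class of a single variant-transcript annotation (A, B or C)."""
    term = annotation.consequence_term
    if term == "missense_variant":
        damaging = (
            annotation.sift == "deleterious"
            or annotation.polyphen in ("probably_damaging", "possibly_damaging")
            or annotation.in_domain
        )
        return "A" if damaging else "B"
    if term in _CLASS_A_TERMS:
        return "A"
    if term in _CLASS_B_TERMS:
        return "B"
    if term in _CLASS_C_TERMS:
        return "C"
    raise VocabularyError(f"unknown consequence term {term!r}")


def triage_class(annotations: Sequence[AnnotatedConsequence]) -> str:
    """Variant-level label: the most severe class over all annotations."""
    if not annotations:
        raise ValidationError("triage requires at least one annotation")
    return min((classify_annotation(a) for a in annotations), key=_SEVERITY.__getitem__)


def tally_consequences(
    events: Iterable[tuple[str, Sequence[AnnotatedConsequence]]], stage_label: str
) -> ConsequenceTally:
    """Count selective-event annotations per consequence term for one stage.

    ``events`` are (variant key, annotations) pairs already restricted to
    variants acquired at this stage and selected; every annotation counts
    once, so the total equals the number of input annotations.
    """
    counts: Counter[str] = Counter({term: 0 for term in sorted(CONSEQUENCE_VOCABULARY)})
    total = 0
    for _key, annotations in events:
        for a in annotations:
            if a.consequence_term not in CONSEQUENCE_VOCABULARY:
                raise VocabularyError(f"unknown consequence term {a.consequence_term!r}")
            counts[a.consequence_term] += 1
            total += 1
    return ConsequenceTally(stage_label=stage_label, counts=dict(counts), total=total)


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def _is_indel(variant: VariantObservation) -> bool:
    return len(variant.ref) != len(variant.alt)


def stage_summary_table(
    variants: Sequence[VariantObservation],
    calls: Sequence[AcquisitionCall],
    series: StageSeries,
) -> pd.DataFrame:
    """Per-stage acquired/selected counts, split into SNVs and indels.

    Rows: acquired_snvs, selected_snvs, acquired_indels, selected_indels;
    one column per non-parental stage.
    """
    by_key = {v.key: v for v in variants}
    labels = series.labels[1:]
    data = {label: dict.fromkeys(
        ["acquired_snvs", "selected_snvs", "acquired_indels", "selected_indels"], 0
    ) for label in labels}
    for call in calls:
        if call.acquired_stage is None:
            continue
        label = series.labels[call.acquired_stage]
        kind = "indels" if _is_indel(by_key[call.variant_key]) else "snvs"
        data[label][f"acquired_{kind}"] += 1
        if call.selected:
            data[label][f"selected_{kind}"] += 1
    return pd.DataFrame(data, columns=list(labels))


def consequence_tally_table(
    tallies: Sequence[ConsequenceTally],
) -> pd.DataFrame:
    """Stack per-stage tallies into one table with a Total row."""
    cols = {t.stage_label: t.counts for t in tallies}
    df = pd.DataFrame(cols).fillna(0).astype(int)
    df = df.sort_index()
    df.loc["Total"] = [t.total for t in tallies]
    df.index.name = "consequence_term"
    return df


def classification_table(
    calls: Sequence[AcquisitionCall],
    annotations_by_variant: Mapping[str, Sequence[AnnotatedConsequence]],
    series: StageSeries,
) -> pd.DataFrame:
    """Per-variant classification: acquisition stage, selection, class label."""
    rows = []
    for call in calls:
        anns = annotations_by_variant.get(call.variant_key, ())
        rows.append(
            {
                "variant_key": call.variant_key,
                "assessable": int(call.assessable),
                "acquired_stage": (
                    series.labels[call.acquired_stage] if call.acquired_stage is not None else "."
                ),
                "selected": int(call.selected),
                "transient": int(call.transient),
                "class": triage_class(list(anns)) if anns else ".",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["variant_key", "assessable", "acquired_stage", "selected", "transient", "class"],
    )
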