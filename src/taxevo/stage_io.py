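"""Readers and writers for every external format the pipeline touches.

The internal coordinate convention is 1-based inclusive everywhere (the
native convention of VCF and gene annotation); BED's 0-based half-open
intervals are converted at the boundary, in both directions, so that
write/read is an exact round trip.  Readers reject malformed input rather
than repairing it.  Chromosome names are normalised to the un-prefixed
dialect ("chr7" -> "7") at read time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd
import pysam

from .errors import (
    ConfigurationError,
    ConsistencyError,
    ParseError,
    ValidationError,
    VocabularyError,
)

logger = logging.getLogger(__name__)

STAGE_ROLES = ("parental", "intermediate", "final")

HALLMARK_CATEGORIES = tuple(f"H{i}" for i in range(1, 12))
"""The eleven acquired-capability (cancer hallmark) categories H1..H11."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix: ``chr7`` and ``7`` are the same axis."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class Stage:
    """One point of the resistance-development timeline.

    ``docetaxel_nM`` is the selection dose the sub-line was growing at when
    it was isolated; ``passage_range`` the (first, last) passage numbers at
    that dose where known; ``doubling_time_days`` the measured population
    doubling time, if any.
    """

    label: str
    docetaxel_nM: float
    role: str = "intermediate"
    passage_range: Optional[tuple[int, int]] = None
    doubling_time_days: Optional[float] = None

    def __post_init__(self) -> None:
        if self.role not in STAGE_ROLES:
            raise ValidationError(f"role: {self.role!r} not one of {STAGE_ROLES}")
        if self.docetaxel_nM < 0:
            raise ValidationError(f"docetaxel_nM: negative dose {self.docetaxel_nM}")


@dataclass(frozen=True)
class StageSeries:
    """The ordered timeline parental -> intermediate sub-lines -> final resistant."""

    stages: tuple[Stage, ...]

    def __post_init__(self) -> None:
        stages = tuple(self.stages)
        object.__setattr__(self, "stages", stages)
        if len(stages) < 2:
            raise ValidationError("stages: a series needs at least two stages")
        if stages[0].role != "parental" or any(s.role == "parental" for s in stages[1:]):
            raise ValidationError("stages: exactly one parental stage, and it must come first")
        if stages[-1].role != "final" or any(s.role == "final" for s in stages[:-1]):
            raise ValidationError("stages: exactly one final stage, and it must come last")
        doses = [s.docetaxel_nM for s in stages]
        if any(b < a for a, b in zip(doses, doses[1:])):
            raise ValidationError("docetaxel_nM: concentrations must be non-decreasing")
        if len({s.label for s in stages}) != len(stages):
            raise ValidationError("label: stage labels must be unique")

    def __len__(self) -> int:
        return len(self.stages)

    def __iter__(self):
        return iter(self.stages)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.stages)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class VariantObservation:
    """One variant's per-stage evidence.

    ``depth``/``alt_depth`` entries are ``None`` when the caller reported no
    DP/AD for that stage — unknown depth is deliberately distinct from depth
    zero, because the acquisition rule needs positive evidence of adequate
    coverage in the preceding stage.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    called: tuple[bool, ...]
    depth: tuple[Optional[int], ...]
    alt_depth: tuple[Optional[int], ...]
    genotype_only: bool = False

    def __post_init__(self) -> None:
        n = len(self.called)
        if not (len(self.depth) == len(self.alt_depth) == n):
            raise ValidationError("per-stage vectors must have equal length")
        for d, a in zip(self.depth, self.alt_depth):
            if d is not None and a is not None and not (0 <= a <= d):
                raise ValidationError(f"alt_depth: {a} outside [0, depth={d}]")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class AnnotatedConsequence:
    """One variant-transcript consequence with its functional evidence."""

    variant_key: str
    gene_id: str
    transcript_id: str
    consequence_term: str
    sift: str = "absent"  # deleterious | tolerated | absent
    polyphen: str = "absent"  # probably_damaging | possibly_damaging | benign | absent
    in_domain: bool = False

    def __post_init__(self) -> None:
        if self.sift not in ("deleterious", "tolerated", "absent"):
            raise ValidationError(f"sift: unknown label {self.sift!r}")
        if self.polyphen not in ("probably_damaging", "possibly_damaging", "benign", "absent"):
            raise ValidationError(f"polyphen: unknown label {self.polyphen!r}")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"start: {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand: {self.strand!r} not one of +/-")


@dataclass(frozen=True)
class ExpressionRecord:
    """Final-vs-parental expression log2 fold change for one gene."""

    gene_id: str
    log2fc: float
    significant: bool

    def __post_init__(self) -> None:
        if not pd.notna(self.log2fc) or self.log2fc in (float("inf"), float("-inf")):
            raise ValidationError(f"log2fc: non-finite value for {self.gene_id}")


@dataclass
class RegionCountTable:
    """Read-depth counts over a shared set of regions, one column per stage.

    ``regions`` holds chrom/start/end in the internal 1-based inclusive
    convention; ``counts`` is indexed like ``regions`` with one integer
    column per stage label.
    """

    regions: pd.DataFrame
    counts: pd.DataFrame

    def stage(self, label: str) -> pd.Series:
        return self.counts[label]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _gt_carries_alt(gt, alt_index: int) -> Optional[bool]:
    if gt is None or all(a is None for a in gt):
        return None
    return any(a == alt_index for a in gt if a is not None)


def read_multistage_vcf(path: str | Path, series: StageSeries) -> list[VariantObservation]:
    """Read a multi-sample VCF whose sample columns are the stage series.

    Sample names must match the stage labels in order.  Multi-allelic records
    are split into biallelic observations at read time.  "Called" is taken
    from GT when present; when a record has no GT it falls back to
    ``alt_depth > 0`` with a warning.
    """
    path = Path(path)
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if samples != list(series.labels):
            raise ConfigurationError(
                f"VCF samples {samples} do not match stage labels {list(series.labels)}"
            )
        out: list[VariantObservation] = []
        gt_fallback_warned = False
        for rec in vcf:
            try:
                alts = rec.alts or ()
                for ai, alt in enumerate(alts, start=1):
                    called, depths, alt_depths = [], [], []
                    for sample in samples:
                        fmt = rec.samples[sample]
                        dp = fmt.get("DP")
                        ad = fmt.get("AD")
                        a = None
                        if ad is not None and len(ad) > ai and ad[ai] is not None:
                            a = int(ad[ai])
                        d = int(dp) if dp is not None else None
                        gt = fmt.get("GT")
                        c = _gt_carries_alt(gt, ai)
                        if c is None:
                            if not gt_fallback_warned:
                                warnings.warn(
                                    f"{path.name}: record without GT; defining "
                                    "'called' as alt_depth > 0",
                                    stacklevel=2,
                                )
                                gt_fallback_warned = True
                            c = bool(a) if a is not None else False
                        called.append(bool(c))
                        depths.append(d)
                        alt_depths.append(a)
                    out.append(
                        VariantObservation(
                            chrom=normalize_chrom(rec.chrom),
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            called=tuple(called),
                            depth=tuple(depths),
                            alt_depth=tuple(alt_depths),
                        )
                    )
            except (ValueError, TypeError, ValidationError) as exc:
                raise ParseError(f"{path}: malformed record at {rec.chrom}:{rec.pos}: {exc}") from exc
    return out


def write_multistage_vcf(
    path: str | Path,
    variants: Iterable[VariantObservation],
    series: StageSeries,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write observations as an uncompressed multi-sample VCF v4.2."""
    variants = list(variants)
    header = pysam.VariantHeader()
    contigs: dict[str, int] = dict(contig_lengths or {})
    for v in variants:
        need = v.pos + len(v.ref) + 1
        if contigs.get(v.chrom, 0) < need:
            contigs[v.chrom] = need
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for label in series.labels:
        header.add_sample(label)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            rec = vcf.new_record(contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt))
            for i, label in enumerate(series.labels):
                fmt = rec.samples[label]
                fmt["GT"] = (0, 1) if v.called[i] else (0, 0)
                if v.depth[i] is not None:
                    fmt["DP"] = v.depth[i]
                    if v.alt_depth[i] is not None:
                        fmt["AD"] = (v.depth[i] - v.alt_depth[i], v.alt_depth[i])
            vcf.write(rec)


# ---------------------------------------------------------------------------
# annotation table
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = [
    "variant_key",
    "gene_id",
    "transcript_id",
    "consequence_term",
    "sift",
    "polyphen",
    "in_domain",
]


def read_annotation_table(path: str | Path) -> list[AnnotatedConsequence]:
    """Read the per-variant consequence table (VEP-style TSV).

    Consequence terms outside the closed vocabulary are rejected, not
    coerced; SIFT/PolyPhen use ``.`` for absent.
    """
    from .variant_evolution import CONSEQUENCE_VOCABULARY

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    unknown = sorted(set(df["consequence_term"]) - set(CONSEQUENCE_VOCABULARY))
    if unknown:
        raise VocabularyError(f"{path}: unknown consequence terms {unknown}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            AnnotatedConsequence(
                variant_key=row.variant_key,
                gene_id=row.gene_id,
                transcript_id=row.transcript_id,
                consequence_term=row.consequence_term,
                sift="absent" if row.sift in (".", "", None) else row.sift,
                polyphen="absent" if row.polyphen in (".", "", None) else row.polyphen,
                in_domain=str(row.in_domain) in ("1", "True", "true"),
            )
        )
    return out


def write_annotation_table(path: str | Path, annotations: Iterable[AnnotatedConsequence]) -> None:
    rows = [
        {
            "variant_key": a.variant_key,
            "gene_id": a.gene_id,
            "transcript_id": a.transcript_id,
            "consequence_term": a.consequence_term,
            "sift": "." if a.sift == "absent" else a.sift,
            "polyphen": "." if a.polyphen == "absent" else a.polyphen,
            "in_domain": int(a.in_domain),
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED region counts
# ---------------------------------------------------------------------------

def bed_to_internal(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


def internal_to_bed(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open (inverse of :func:`bed_to_internal`)."""
    return start1 - 1, end1


def _read_bed_counts(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "count"],
            dtype={"chrom": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df[["start", "end", "count"]].isna().any().any():
        raise ParseError(f"{path}: missing start/end/count fields")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    starts, ends = zip(*(bed_to_internal(s, e) for s, e in zip(df["start"], df["end"])))
    df["start"], df["end"] = starts, ends
    return df


def read_region_counts(paths: Mapping[str, str | Path]) -> RegionCountTable:
    """Read one BED3+count file per stage into a shared region/count table.

    The interval sets must be identical across stages; any disagreement is a
    consistency error rather than an attempted merge.
    """
    if not paths:
        raise ConfigurationError("region counts: no stage files given")
    tables = {label: _read_bed_counts(p) for label, p in paths.items()}
    labels = list(tables)
    ref = tables[labels[0]][["chrom", "start", "end"]]
    for label in labels[1:]:
        other = tables[label][["chrom", "start", "end"]]
        if not ref.equals(other):
            raise ConsistencyError(
                f"region definitions differ between stages {labels[0]!r} and {label!r}"
            )
    counts = pd.DataFrame({label: tables[label]["count"].astype(int) for label in labels})
    return RegionCountTable(regions=ref.copy(), counts=counts)


def write_region_counts(paths: Mapping[str, str | Path], table: RegionCountTable) -> None:
    for label, path in paths.items():
        df = table.regions.copy()
        starts, ends = zip(*(internal_to_bed(s, e) for s, e in zip(df["start"], df["end"])))
        df["start"], df["end"] = starts, ends
        df["count"] = table.counts[label].astype(int)
        df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# simple tables
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["gene_id", "symbol", "chrom", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return [
        GeneModel(
            gene_id=r.gene_id,
            symbol=r.symbol,
            chrom=normalize_chrom(r.chrom),
            start=int(r.start),
            end=int(r.end),
            strand=r.strand,
        )
        for r in df.itertuples(index=False)
    ]


def write_gene_models(path: str | Path, genes: Iterable[GeneModel]) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "symbol": g.symbol,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> list[ExpressionRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ["gene_id", "log2fc", "significant"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return [
        ExpressionRecord(gene_id=r.gene_id, log2fc=float(r.log2fc), significant=bool(r.significant))
        for r in df.itertuples(index=False)
    ]


def write_expression(path: str | Path, records: Iterable[ExpressionRecord]) -> None:
    pd.DataFrame(
        [
            {"gene_id": r.gene_id, "log2fc": repr(r.log2fc), "significant": int(r.significant)}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_network(path: str | Path) -> nx.Graph:
    """Read a whitespace-delimited weighted edge list ``geneA geneB weight``."""
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 'geneA geneB weight'")
            a, b, w = parts
            try:
                weight = float(w)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric weight {w!r}") from exc
            if a == b:
                raise ValidationError(f"{path}:{lineno}: self-loop on {a}")
            if weight <= 0:
                raise ValidationError(f"{path}:{lineno}: non-positive weight {weight}")
            graph.add_edge(a, b, weight=weight)
    return graph


def write_network(path: str | Path, graph: nx.Graph) -> None:
    with open(path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a} {b} {data.get('weight', 1.0)!r}\n")


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(path: str | Path, genes: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for gene in sorted(genes):
            fh.write(gene + "\n")


def read_hallmark_map(path: str | Path) -> dict[str, set[str]]:
    """Read the gene -> hallmark-categories map (two-column TSV, one row per pair)."""
    df = pd.read_csv(path, sep="\t", names=["gene_id", "category"], header=0)
    bad = sorted(set(df["category"]) - set(HALLMARK_CATEGORIES))
    if bad:
        raise ValidationError(f"{path}: categories outside H1..H11: {bad}")
    out: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.gene_id, set()).add(r.category)
    return out


def write_hallmark_map(path: str | Path, mapping: Mapping[str, set[str]]) -> None:
    rows = [
        {"gene_id": g, "category": c}
        for g in sorted(mapping)
        for c in sorted(mapping[g])
    ]
    pd.DataFrame(rows, columns=["gene_id", "category"]).to_csv(path, sep="\t", index=False)
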