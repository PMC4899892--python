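"""Truth-labelled synthetic multi-stage resistance datasets.

The generator emulates the statistical shape of a stepwise drug-resistance
selection experiment read out by exome sequencing: an ordered series of
stages (parental, intermediate sub-lines, final resistant), variants planted
as pre-existing, acquired-and-selected, acquired-but-transient, or absent,
with read evidence drawn as ``depth ~ Poisson(mean_depth)`` and alternative
reads ``~ Binomial(depth, vaf_clonal)`` in carrier stages or
``Binomial(depth, error_rate)`` otherwise.  Regional read counts carry
planted copy-number gains/losses (depth scaled by ``2**log2_effect`` from
the planted stage onward), final-vs-parental expression shifts are coupled
to planted copy-number genes with configurable probability, and a weighted
gene network is wired so that chosen candidate genes sit close to the seed
set.  Every planted feature is recorded in a TruthTable so downstream
recovery can be measured exactly.

Planted acquired variants are constructed to satisfy the acquisition rule:
all stages before acquisition have depth of at least five and zero
alternative reads.  Elsewhere the flat ``error_rate`` occasionally puts a
stray alternative read in a non-carrier stage, so the zero-alternative-reads
assessability branch is exercised by pre-existing and transient patterns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .stage_io import (
    AnnotatedConsequence,
    ExpressionRecord,
    GeneModel,
    HALLMARK_CATEGORIES,
    RegionCountTable,
    Stage,
    StageSeries,
    VariantObservation,
    write_annotation_table,
    write_expression,
    write_gene_list,
    write_gene_models,
    write_hallmark_map,
    write_multistage_vcf,
    write_network,
    write_region_counts,
)
from .variant_evolution import triage_class

REGION_LENGTH = 1_000

# Default draw weights over the consequence vocabulary; heavy on silent
# terms, as in real exomes, but with mass on every triage branch.
DEFAULT_CONSEQUENCE_WEIGHTS: dict[str, float] = {
    "intron_variant": 0.25,
    "upstream_gene_variant": 0.09,
    "downstream_gene_variant": 0.09,
    "nc_transcript_variant": 0.07,
    "synonymous_variant": 0.06,
    "NMD_transcript_variant": 0.05,
    "3_prime_UTR_variant": 0.04,
    "non_coding_exon_variant": 0.04,
    "regulatory_region_variant": 0.035,
    "5_prime_UTR_variant": 0.03,
    "missense_variant": 0.12,
    "splice_region_variant": 0.03,
    "feature_elongation": 0.02,
    "feature_truncation": 0.02,
    "intergenic_variant": 0.02,
    "frameshift_variant": 0.01,
    "stop_gained": 0.008,
    "inframe_insertion": 0.005,
    "inframe_deletion": 0.005,
    "splice_acceptor_variant": 0.004,
    "splice_donor_variant": 0.004,
    "stop_retained_variant": 0.003,
    "stop_lost": 0.002,
    "mature_miRNA_variant": 0.002,
    "incomplete_terminal_codon_variant": 0.002,
    "initiator_codon_variant": 0.002,
    "TF_binding_site_variant": 0.002,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a synthetic resistance series."""

    n_stages: int = 6
    stage_labels: Optional[tuple[str, ...]] = None
    docetaxel_concentrations: Optional[tuple[float, ...]] = None
    n_variants: int = 500
    fraction_acquired: float = 0.4
    fraction_selected_given_acquired: float = 0.5
    mean_depth: float = 30.0
    vaf_clonal: float = 0.5
    error_rate: float = 0.001
    n_regions: int = 200
    region_mean_depth: float = 100.0
    n_planted_cna: int = 5
    cna_log2_effect: float = 1.0
    expression_coupling: float = 0.8
    n_network_genes: int = 300
    n_seed_genes: int = 10
    n_planted_proximal: int = 5
    consequence_weights: Optional[Mapping[str, float]] = None
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stages < 2:
            raise ValidationError("n_stages: must be >= 2")
        for name in ("fraction_acquired", "fraction_selected_given_acquired",
                     "vaf_clonal", "error_rate", "expression_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}: {v} outside [0, 1]")
        if self.vaf_clonal == 0.0:
            raise ValidationError("vaf_clonal: must be in (0, 1]")
        if self.mean_depth <= 0:
            raise ValidationError("mean_depth: must be > 0")
        if self.region_mean_depth <= 0:
            raise ValidationError("region_mean_depth: must be > 0")
        for name in ("n_variants", "n_regions", "n_planted_cna", "n_network_genes",
                     "n_seed_genes", "n_planted_proximal"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name}: must be non-negative")
        if self.n_planted_cna > self.n_regions:
            raise ValidationError("n_planted_cna: exceeds n_regions")
        if self.n_planted_proximal > self.n_regions:
            raise ValidationError("n_planted_proximal: exceeds n_regions")
        if self.n_network_genes < self.n_regions + self.n_seed_genes:
            raise ValidationError(
                "n_network_genes: must cover the region genes plus the seed set"
            )
        if self.stage_labels is not None and len(self.stage_labels) != self.n_stages:
            raise ValidationError("stage_labels: length must equal n_stages")
        if (self.docetaxel_concentrations is not None
                and len(self.docetaxel_concentrations) != self.n_stages):
            raise ValidationError("docetaxel_concentrations: length must equal n_stages")

    def series(self) -> StageSeries:
        labels = self.stage_labels or tuple(f"S{i}" for i in range(self.n_stages))
        if self.docetaxel_concentrations is not None:
            doses = self.docetaxel_concentrations
        elif self.n_stages == 6:
            doses = (0.0, 0.27, 1.2, 7.5, 45.0, 65.0)  # MCF-7-like escalation
        else:
            doses = tuple(float(i) for i in range(self.n_stages))
        roles = ["parental"] + ["intermediate"] * (self.n_stages - 2) + ["final"]
        return StageSeries(
            stages=tuple(
                Stage(label=l, docetaxel_nM=d, role=r) for l, d, r in zip(labels, doses, roles)
            )
        )


@dataclass
class TruthTable:
    """Ground truth of everything planted by the generator."""

    variants: pd.DataFrame  # variant_key, acquired_stage (nullable), selected, transient, class_label
    regions: pd.DataFrame  # region_index, chrom, start, end, direction, stage
    expression: pd.DataFrame  # gene_id, direction (planted coupled shifts only)
    network: pd.DataFrame  # gene_id, seed_proximal


@dataclass
class SimulationOutput:
    config: SimulationConfig
    series: StageSeries
    variants: list[VariantObservation]
    annotations: list[AnnotatedConsequence]
    region_counts: RegionCountTable
    gene_models: list[GeneModel]
    expression: list[ExpressionRecord]
    network: nx.Graph
    seeds: set[str]
    hallmarks: dict[str, set[str]]
    annotation_terms: dict[str, set[str]]
    truth: TruthTable


def _poisson_at_least(rng: np.random.Generator, lam: float, minimum: int) -> int:
    for _ in range(1000):
        d = int(rng.poisson(lam))
        if d >= minimum:
            return d
    return minimum


def _gene_id(region_index: int) -> str:
    return f"G{region_index:04d}"


def _simulate_variants(config, series, rng):
    n = config.n_variants
    n_stages = config.n_stages
    categories = np.full(n, "absent", dtype=object)
    acquired_mask = rng.random(n) < config.fraction_acquired
    selected_mask = acquired_mask & (rng.random(n) < config.fraction_selected_given_acquired)
    transient_mask = acquired_mask & ~selected_mask
    if n_stages == 2:
        # no room for a later disappearance: every acquisition persists
        selected_mask = acquired_mask
        transient_mask = np.zeros(n, dtype=bool)
    baseline_mask = ~acquired_mask & (rng.random(n) < 0.5)
    categories[baseline_mask] = "baseline"
    categories[selected_mask] = "selected"
    categories[transient_mask] = "transient"

    variants: list[VariantObservation] = []
    truth_rows = []
    bases = np.array(list("ACGT"))
    for v in range(n):
        region = v % config.n_regions if config.n_regions else 0
        slot = v // max(config.n_regions, 1)
        pos = region * REGION_LENGTH + 1 + (slot * 7) % REGION_LENGTH
        ref = str(rng.choice(bases))
        if rng.random() < 0.15:  # indel
            alt = ref + str(rng.choice(bases))
            if rng.random() < 0.5:
                ref, alt = alt, ref
        else:
            alt = str(rng.choice([b for b in bases if b != ref]))
        cat = categories[v]
        if cat == "selected":
            acq = int(rng.integers(1, n_stages))
            carrier = [acq <= s for s in range(n_stages)]
        elif cat == "transient":
            acq = int(rng.integers(1, n_stages - 1))
            drop = int(rng.integers(acq + 1, n_stages))
            carrier = [acq <= s < drop for s in range(n_stages)]
        elif cat == "baseline":
            acq = None
            carrier = [True] * n_stages
        else:
            acq = None
            carrier = [False] * n_stages
        called, depths, alts = [], [], []
        for s in range(n_stages):
            if carrier[s]:
                d = _poisson_at_least(rng, config.mean_depth, 1)
                a = max(1, int(rng.binomial(d, config.vaf_clonal)))
                c = True
            elif acq is not None and s < acq:
                # pre-acquisition: adequate depth, no trace of the allele
                d = _poisson_at_least(rng, config.mean_depth, 5)
                a = 0
                c = False
            else:
                d = int(rng.poisson(config.mean_depth))
                a = int(rng.binomial(d, config.error_rate)) if d else 0
                c = False
            called.append(c)
            depths.append(d)
            alts.append(a)
        obs = VariantObservation(
            chrom="1", pos=pos, ref=ref, alt=alt,
            called=tuple(called), depth=tuple(depths), alt_depth=tuple(alts),
        )
        variants.append(obs)
        truth_rows.append(
            {
                "variant_key": obs.key,
                "acquired_stage": acq,
                "selected": cat == "selected",
                "transient": cat == "transient",
                "gene_id": _gene_id(region),
            }
        )
    truth = pd.DataFrame(
        truth_rows, columns=["variant_key", "acquired_stage", "selected", "transient", "gene_id"]
    )
    truth["acquired_stage"] = truth["acquired_stage"].astype("Int64")
    return variants, truth


def _simulate_annotations(config, variants, truth_variants, rng):
    weights = dict(config.consequence_weights or DEFAULT_CONSEQUENCE_WEIGHTS)
    terms = sorted(weights)
    p = np.array([weights[t] for t in terms], dtype=float)
    p = p / p.sum()
    annotations: list[AnnotatedConsequence] = []
    class_labels = []
    gene_by_key = dict(zip(truth_variants["variant_key"], truth_variants["gene_id"]))
    for obs in variants:
        gene = gene_by_key[obs.key]
        n_ann = 1 + int(rng.integers(0, 3))
        anns = []
        for j in range(n_ann):
            term = str(rng.choice(terms, p=p))
            if term == "missense_variant":
                sift = str(rng.choice(["deleterious", "tolerated", "absent"], p=[0.4, 0.5, 0.1]))
                polyphen = str(
                    rng.choice(
                        ["probably_damaging", "possibly_damaging", "benign", "absent"],
                        p=[0.25, 0.15, 0.5, 0.1],
                    )
                )
                in_domain = bool(rng.random() < 0.3)
            else:
                sift = polyphen = "absent"
                in_domain = False
            anns.append(
                AnnotatedConsequence(
                    variant_key=obs.key,
                    gene_id=gene,
                    transcript_id=f"{gene}.t{j}",
                    consequence_term=term,
                    sift=sift,
                    polyphen=polyphen,
                    in_domain=in_domain,
                )
            )
        annotations.extend(anns)
        class_labels.append(triage_class(anns))
    return annotations, class_labels


def _simulate_regions(config, series, rng):
    regions = pd.DataFrame(
        {
            "chrom": ["1"] * config.n_regions,
            "start": [r * REGION_LENGTH + 1 for r in range(config.n_regions)],
            "end": [(r + 1) * REGION_LENGTH for r in range(config.n_regions)],
        }
    )
    planted_idx = rng.choice(config.n_regions, size=config.n_planted_cna, replace=False)
    planted_idx = np.sort(planted_idx)
    directions = rng.choice(["gain", "loss"], size=config.n_planted_cna)
    stages = rng.integers(1, config.n_stages, size=config.n_planted_cna)
    effect = {}
    for idx, direction, stage in zip(planted_idx, directions, stages):
        signed = abs(config.cna_log2_effect) * (1 if direction == "gain" else -1)
        effect[int(idx)] = (signed, int(stage))
    counts = {}
    for s, stage in enumerate(series):
        lam = np.full(config.n_regions, config.region_mean_depth)
        for idx, (signed, from_stage) in effect.items():
            if s >= from_stage:
                lam[idx] *= 2.0 ** signed
        counts[stage.label] = rng.poisson(lam).astype(int)
    truth = pd.DataFrame(
        {
            "region_index": planted_idx.astype(int),
            "chrom": "1",
            "start": [int(regions.loc[i, "start"]) for i in planted_idx],
            "end": [int(regions.loc[i, "end"]) for i in planted_idx],
            "direction": directions,
            "stage": stages.astype(int),
            "gene_id": [_gene_id(int(i)) for i in planted_idx],
        }
    )
    return RegionCountTable(regions=regions, counts=pd.DataFrame(counts)), truth


def _simulate_expression(config, region_truth, rng):
    planted = dict(zip(region_truth["gene_id"], region_truth["direction"]))
    records = []
    truth_rows = []
    for r in range(config.n_regions):
        gene = _gene_id(r)
        direction = planted.get(gene)
        if direction is not None and rng.random() < config.expression_coupling:
            magnitude = abs(rng.normal(1.5, 0.3)) + 0.3
            log2fc = magnitude if direction == "gain" else -magnitude
            records.append(ExpressionRecord(gene_id=gene, log2fc=float(log2fc), significant=True))
            truth_rows.append({"gene_id": gene, "direction": direction})
        else:
            records.append(
                ExpressionRecord(
                    gene_id=gene,
                    log2fc=float(rng.normal(0.0, 0.2)),
                    significant=bool(rng.random() < 0.05),
                )
            )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "direction"])
    return records, truth


def _simulate_network(config, rng):
    region_genes = [_gene_id(r) for r in range(config.n_regions)]
    n_extra = config.n_network_genes - config.n_regions
    extra = [f"N{i:04d}" for i in range(n_extra)]
    nodes = region_genes + extra
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    seeds = set(str(g) for g in rng.choice(extra, size=config.n_seed_genes, replace=False))
    proximal = set(
        str(g) for g in rng.choice(region_genes, size=config.n_planted_proximal, replace=False)
    )
    # random background, average degree ~4
    n_edges = 2 * config.n_network_genes
    for _ in range(n_edges):
        a, b = rng.choice(len(nodes), size=2, replace=False)
        u, v = nodes[int(a)], nodes[int(b)]
        if not graph.has_edge(u, v):
            graph.add_edge(u, v, weight=float(np.round(rng.uniform(0.5, 1.5), 6)))
    # wire planted candidates tightly to the seed set
    seed_list = sorted(seeds)
    for gene in sorted(proximal):
        picked = rng.choice(len(seed_list), size=min(3, len(seed_list)), replace=False)
        for i in picked:
            graph.add_edge(gene, seed_list[int(i)], weight=5.0)
    truth = pd.DataFrame(
        {"gene_id": nodes, "seed_proximal": [g in proximal for g in nodes]}
    )
    return graph, seeds, truth


def _simulate_hallmarks(config, rng):
    hallmarks: dict[str, set[str]] = {}
    terms: dict[str, set[str]] = {f"T{i:02d}": set() for i in range(10)}
    for r in range(config.n_regions):
        gene = _gene_id(r)
        if rng.random() < 0.4:
            k = 1 + int(rng.integers(0, 2))
            cats = rng.choice(len(HALLMARK_CATEGORIES), size=k, replace=False)
            hallmarks[gene] = {HALLMARK_CATEGORIES[int(c)] for c in cats}
        term = f"T{int(rng.integers(0, 10)):02d}"
        terms[term].add(gene)
    return hallmarks, {t: g for t, g in terms.items() if g}


def generate_stage_series(config: SimulationConfig) -> SimulationOutput:
    """Generate a complete truth-labelled multi-stage dataset.

    Deterministic given ``config.random_seed``: one seed sequence spawns an
    independent child stream per component.
    """
    series = config.series()
    children = np.random.SeedSequence(config.random_seed).spawn(6)
    rngs = [np.random.default_rng(c) for c in children]

    variants, truth_variants = _simulate_variants(config, series, rngs[0])
    annotations, class_labels = _simulate_annotations(config, variants, truth_variants, rngs[1])
    truth_variants = truth_variants.assign(class_label=class_labels)
    region_counts, truth_regions = _simulate_regions(config, series, rngs[2])
    expression, truth_expression = _simulate_expression(config, truth_regions, rngs[3])
    network, seeds, truth_network = _simulate_network(config, rngs[4])
    hallmarks, annotation_terms = _simulate_hallmarks(config, rngs[5])

    gene_models = [
        GeneModel(
            gene_id=_gene_id(r),
            symbol=_gene_id(r),
            chrom="1",
            start=r * REGION_LENGTH + 1,
            end=(r + 1) * REGION_LENGTH,
            strand="+" if r % 2 == 0 else "-",
        )
        for r in range(config.n_regions)
    ]
    return SimulationOutput(
        config=config,
        series=series,
        variants=variants,
        annotations=annotations,
        region_counts=region_counts,
        gene_models=gene_models,
        expression=expression,
        network=network,
        seeds=seeds,
        hallmarks=hallmarks,
        annotation_terms=annotation_terms,
        truth=TruthTable(
            variants=truth_variants,
            regions=truth_regions,
            expression=truth_expression,
            network=truth_network,
        ),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(output: SimulationOutput, directory: str | Path) -> dict[str, str]:
    """Write the full bundle to ``directory``; returns {path: sha256} manifest.

    Also drops ``manifest.json`` alongside the files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series = output.series

    paths: dict[str, Path] = {
        "vcf": directory / "variants.vcf",
        "annotations": directory / "annotations.tsv",
        "gene_models": directory / "gene_models.tsv",
        "expression": directory / "expression.tsv",
        "network": directory / "network.txt",
        "seed_genes": directory / "seed_genes.txt",
        "hallmarks": directory / "hallmarks.tsv",
        "terms": directory / "terms.tsv",
        "truth_variants": directory / "truth_variants.tsv",
        "truth_regions": directory / "truth_regions.tsv",
        "truth_expression": directory / "truth_expression.tsv",
        "truth_network": directory / "truth_network.tsv",
    }
    region_paths = {s.label: directory / f"regions_{s.label}.bed" for s in series}

    write_multistage_vcf(paths["vcf"], output.variants, series)
    write_annotation_table(paths["annotations"], output.annotations)
    write_gene_models(paths["gene_models"], output.gene_models)
    write_expression(paths["expression"], output.expression)
    write_network(paths["network"], output.network)
    write_gene_list(paths["seed_genes"], output.seeds)
    write_hallmark_map(paths["hallmarks"], output.hallmarks)
    write_region_counts(region_paths, output.region_counts)
    term_rows = [
        {"term": t, "gene_id": g}
        for t in sorted(output.annotation_terms)
        for g in sorted(output.annotation_terms[t])
    ]
    pd.DataFrame(term_rows, columns=["term", "gene_id"]).to_csv(
        paths["terms"], sep="\t", index=False
    )
    output.truth.variants.to_csv(paths["truth_variants"], sep="\t", index=False)
    output.truth.regions.to_csv(paths["truth_regions"], sep="\t", index=False)
    output.truth.expression.to_csv(paths["truth_expression"], sep="\t", index=False)
    output.truth.network.to_csv(paths["truth_network"], sep="\t", index=False)

    all_paths = list(paths.values()) + list(region_paths.values())
    manifest = {str(p.relative_to(directory)): _sha256(p) for p in sorted(all_paths)}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def write_pipeline_config(output: SimulationOutput, directory: str | Path) -> Path:
    """Write a ready-to-run pipeline YAML next to a fixture bundle."""
    directory = Path(directory)
    config = {
        "series": [
            {"label": s.label, "docetaxel_nM": s.docetaxel_nM, "role": s.role}
            for s in output.series
        ],
        "inputs": {
            "vcf": "variants.vcf",
            "annotations": "annotations.tsv",
            "region_counts": {
                s.label: f"regions_{s.label}.bed" for s in output.series
            },
            "gene_models": "gene_models.tsv",
            "expression": "expression.tsv",
            "network": "network.txt",
            "seed_genes": "seed_genes.txt",
            "hallmarks": "hallmarks.tsv",
            "enrichment_terms": "terms.tsv",
        },
        "parameters": {"cna_alpha": 0.05, "cna_reference": "parental", "restart_prob": 0.5},
        "out_dir": "reports",
        "seed": output.config.random_seed,
    }
    path = directory / "pipeline.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return path
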