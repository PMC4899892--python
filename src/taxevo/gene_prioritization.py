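"""Network-based candidate-gene ranking, hallmark mapping and enrichment.

Candidate resistance genes (Class A selective events and expression-
concordant copy-number genes) are scored by random walk with restart (RWR)
on a weighted functional network, anchored at a curated set of genes already
associated with taxane resistance.  The walker's steady state

    p = (1 - r) * W @ p + r * p0

with column-normalised adjacency ``W``, restart probability ``r`` and ``p0``
uniform over the seed set, measures each gene's proximity to the seeds;
candidates are ranked by that score per stage and overall.  Degree-zero
(dangling) nodes hand their outgoing mass back to ``p0`` so the score vector
stays a probability distribution at every iteration.

The module also tallies candidates against the eleven cancer-hallmark
categories (H1..H11) and runs a hypergeometric over-representation test with
Benjamini-Hochberg correction across annotation terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ValidationError
from .stage_io import HALLMARK_CATEGORIES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PriorityScore:
    gene_id: str
    score: float
    rank: int  # 1-based
    scope: str  # stage label or "overall"


def _validate_network(network: nx.Graph) -> None:
    if any(u == v for u, v in network.edges):
        raise ValidationError("network contains self-loops")
    if any(d.get("weight", 1.0) <= 0 for _, _, d in network.edges(data=True)):
        raise ValidationError("network contains non-positive edge weights")


def rwr_scores(
    network: nx.Graph,
    seeds: Iterable[str],
    restart_prob: float = 0.5,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> dict[str, float]:
    """Steady-state random-walk-with-restart scores for every network node.

    Iterates ``p <- (1-r) * (W @ p + dangling_mass * p0) + r * p0`` until the
    L1 change drops below ``tol``.  Scores sum to one.
    """
    seeds = set(seeds)
    if not seeds:
        raise ConfigurationError("seed set is empty")
    if not 0 < restart_prob <= 1:
        raise ConfigurationError(f"restart_prob {restart_prob} outside (0, 1]")
    _validate_network(network)
    missing = sorted(seeds - set(network.nodes))
    if missing:
        raise ConfigurationError(f"seed genes absent from the network: {missing}")

    nodes = sorted(network.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    adj = nx.to_scipy_sparse_array(network, nodelist=nodes, weight="weight", format="csc")
    col_sums = np.asarray(adj.sum(axis=0)).ravel()
    dangling = col_sums == 0
    inv = np.divide(1.0, col_sums, out=np.zeros_like(col_sums), where=~dangling)
    W = adj @ sparse.diags(inv)

    p0 = np.zeros(n)
    for g in seeds:
        p0[index[g]] = 1.0 / len(seeds)
    p = p0.copy()
    r = restart_prob
    for _ in range(max_iter):
        dangling_mass = p[dangling].sum()
        p_next = (1.0 - r) * (W @ p + dangling_mass * p0) + r * p0
        if np.abs(p_next - p).sum() < tol:
            p = p_next
            break
        p = p_next
    return {g: float(p[index[g]]) for g in nodes}


def rwr_scores_direct(
    network: nx.Graph, seeds: Iterable[str], restart_prob: float = 0.5
) -> dict[str, float]:
    """Closed-form steady state by solving ``(I - (1-r) W') p = r p0`` densely.

    ``W'`` is the column-normalised adjacency with dangling columns replaced
    by ``p0``.  Exact up to linear-algebra round-off; intended for small
    networks and as a cross-check of the iterative solver.
    """
    seeds = set(seeds)
    if not seeds:
        raise ConfigurationError("seed set is empty")
    _validate_network(network)
    nodes = sorted(network.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    A = nx.to_numpy_array(network, nodelist=nodes, weight="weight")
    col_sums = A.sum(axis=0)
    p0 = np.zeros(n)
    for g in seeds:
        p0[index[g]] = 1.0 / len(seeds)
    W = np.zeros((n, n))
    for j in range(n):
        W[:, j] = p0 if col_sums[j] == 0 else A[:, j] / col_sums[j]
    r = restart_prob
    p = np.linalg.solve(np.eye(n) - (1.0 - r) * W, r * p0)
    return {g: float(p[index[g]]) for g in nodes}


def rank_candidates(
    scores: Mapping[str, float], candidates: Iterable[str], scope: str
) -> list[PriorityScore]:
    """Rank candidate genes by descending score, ties broken lexicographically.

    Candidates absent from the scored network are excluded with a warning.
    """
    present, absent = [], []
    for gene in set(candidates):
        (present if gene in scores else absent).append(gene)
    if absent:
        logger.warning("%s: candidates absent from network excluded: %s", scope, sorted(absent))
    ordered = sorted(present, key=lambda g: (-scores[g], g))
    return [
        PriorityScore(gene_id=g, score=scores[g], rank=i, scope=scope)
        for i, g in enumerate(ordered, start=1)
    ]


def map_hallmarks(
    genes: Iterable[str], hallmarks: Mapping[str, set[str]]
) -> tuple[dict[str, int], set[str]]:
    """Per-category gene counts plus the set of unmapped genes.

    A gene mapped to several categories contributes to each of them.
    """
    for gene, cats in hallmarks.items():
        bad = set(cats) - set(HALLMARK_CATEGORIES)
        if bad:
            raise ValidationError(f"hallmark map: {gene} has categories outside H1..H11: {sorted(bad)}")
    counts = {c: 0 for c in HALLMARK_CATEGORIES}
    unmapped = set()
    for gene in set(genes):
        cats = hallmarks.get(gene)
        if not cats:
            unmapped.add(gene)
            continue
        for c in cats:
            counts[c] += 1
    return counts, unmapped


def enrich_gene_sets(
    candidates: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    background: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of candidates in each term's gene set.

    For a term with K background genes, N background genes in total and n
    candidates, the p-value is the upper tail P(X >= k) of the observed
    overlap k; q-values are BH-adjusted across terms.
    """
    candidates = set(candidates)
    background = set(background)
    outside = sorted(candidates - background)
    if outside:
        raise ValidationError(f"candidates outside the background set: {outside}")
    if not annotation:
        raise ValidationError("no annotation terms given")
    terms = sorted(annotation)
    rows = []
    for term in terms:
        term_genes = set(annotation[term]) & background
        k = len(candidates & term_genes)
        p = float(stats.hypergeom.sf(k - 1, len(background), len(term_genes), len(candidates)))
        rows.append({"term": term, "term_size": len(term_genes), "overlap": k, "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["significant"] = (df["q_value"] <= alpha).astype(int)
    return df


def ranking_table(rankings: Sequence[PriorityScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"scope": r.scope, "rank": r.rank, "gene_id": r.gene_id, "score": r.score}
            for r in rankings
        ],
        columns=["scope", "rank", "gene_id", "score"],
    )
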