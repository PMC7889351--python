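"""Hypergeometric over-representation of a gene set against a GMT collection."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from innatome_miner.catalog import canonicalize_symbol

logger = logging.getLogger(__name__)

MIN_PATHWAY_SIZE = 3


@dataclass
class EnrichmentRow:
    pathway: str
    overlap_count: int
    pathway_size: int
    universe_size: int
    query_size: int
    p_value: float
    bh_fdr: float


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """BH step-up adjusted p-values, in input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_last, i in enumerate(reversed(order)):
        rank = m - rank_from_last
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = running
    return adjusted


def hypergeom_enrich(
    query: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric enrichment of ``query`` per pathway.

    Pathways are intersected with the universe first; those smaller than
    :data:`MIN_PATHWAY_SIZE` after intersection are skipped (logged).  Rows
    come back sorted ascending by p-value with BH FDR across the tested
    pathways.
    """
    universe_set = {canonicalize_symbol(g) for g in universe}
    if not universe_set:
        raise ValueError("universe must be non-empty")
    query_set = {canonicalize_symbol(g) for g in query}
    if not query_set:
        raise ValueError("query must be non-empty")
    stray = query_set - universe_set
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:10]}")

    M = len(universe_set)
    n = len(query_set)
    tested: list[tuple[str, int, int, float]] = []
    for name, genes in collection.items():
        pathway = {canonicalize_symbol(g) for g in genes} & universe_set
        K = len(pathway)
        if K < MIN_PATHWAY_SIZE:
            logger.info("skipping pathway %r (size %d < %d in universe)", name, K, MIN_PATHWAY_SIZE)
            continue
        k = len(pathway & query_set)
        # upper tail: P[X >= k] for X ~ Hypergeom(M, K, n)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        p = min(p, 1.0)
        tested.append((name, k, K, p))

    fdrs = benjamini_hochberg([p for _, _, _, p in tested])
    rows = [
        EnrichmentRow(
            pathway=name,
            overlap_count=k,
            pathway_size=K,
            universe_size=M,
            query_size=n,
            p_value=p,
            bh_fdr=fdr,
        )
        for (name, k, K, p), fdr in zip(tested, fdrs)
    ]
    rows.sort(key=lambda r: (r.p_value, r.pathway))
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])
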