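"""Profiling of DEG sets against catalogs: headline fractions, composition
comparisons, Venn partitions and targeted gene-panel scans."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from innatome_miner._util import round_half_up
from innatome_miner.catalog import GeneCatalog, canonicalize_symbol, _SCHEME_COLUMNS, _SCHEME_VOCAB
from innatome_miner.degcall import DEFAULT_THRESHOLD, Contrast


def percent_of_catalog(count: int, total: int, decimals: int = 1) -> float:
    """100*count/total rendered half-up at ``decimals`` (e.g. 77/1376 -> 5.6)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0 or count > total:
        raise ValueError(f"count must lie in [0, total], got {count}/{total}")
    return round_half_up(100.0 * count / total, decimals)


@dataclass
class ModulatedSet:
    """Genes called up or down in one dataset, relative to a catalog."""

    dataset_id: str
    direction: str  # "up" | "down"
    genes: set[str]
    catalog_total: int

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if self.catalog_total < len(self.genes):
            raise ValueError("catalog_total smaller than the gene set")

    @property
    def percent(self) -> float:
        return percent_of_catalog(len(self.genes), self.catalog_total, 1)


@dataclass
class CompositionRow:
    category: str
    subset_count: int
    subset_pct: float
    background_count: int
    background_pct: float
    p_value: float
    flagged: bool


@dataclass
class CompositionComparison:
    scheme: str
    alpha: float
    rows: list[CompositionRow]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def compare_composition(
    subset: Iterable[str],
    catalog: GeneCatalog,
    scheme: str = "location",
    alpha: float = 0.05,
    bh: bool = False,
) -> CompositionComparison:
    """Compare the category composition of a subset against the whole catalog.

    Per category, a two-sided Fisher exact test on the 2x2 table
    (in-category vs not) x (in-subset vs rest-of-catalog).  The background
    column reports the full catalog (subset included).  ``bh`` applies a
    Benjamini-Hochberg correction before flagging (off by default: one
    flag per category at raw alpha).
    """
    members = {canonicalize_symbol(s) for s in subset}
    if not members:
        raise ValueError("subset must be non-empty")
    stray = members - catalog.genes
    if stray:
        raise ValueError(f"subset members not in catalog: {sorted(stray)}")
    column = _SCHEME_COLUMNS[scheme]
    total = len(catalog.genes)
    n_subset = len(members)
    rest = catalog.genes - members

    raw: list[tuple[str, int, int, float]] = []
    for category in _SCHEME_VOCAB[scheme]:
        in_cat = {
            g
            for g in catalog.genes
            if catalog.annotations.get(g, {}).get(column) == category
        }
        a = len(in_cat & members)
        b = len(in_cat & rest)
        c = n_subset - a
        d = len(rest) - b
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        raw.append((category, a, len(in_cat), float(p)))

    if bh:
        order = sorted(range(len(raw)), key=lambda i: raw[i][3])
        m = len(raw)
        adjusted = [0.0] * m
        running = 1.0
        for rank_from_last, i in enumerate(reversed(order)):
            rank = m - rank_from_last
            running = min(running, raw[i][3] * m / rank)
            adjusted[i] = running
        effective = adjusted
    else:
        effective = [p for _, _, _, p in raw]

    rows = [
        CompositionRow(
            category=category,
            subset_count=a,
            subset_pct=percent_of_catalog(a, n_subset, 2),
            background_count=k,
            background_pct=percent_of_catalog(k, total, 2),
            p_value=p,
            flagged=eff < alpha,
        )
        for (category, a, k, p), eff in zip(raw, effective)
    ]
    return CompositionComparison(scheme=scheme, alpha=alpha, rows=rows)


def venn_partition(
    sets: Sequence[tuple[str, Iterable[str]]],
) -> dict[frozenset[str], int]:
    """Exclusive region counts for 2..5 named sets.

    Keys are the non-empty subsets of set names; the value for key K is the
    number of elements that belong to exactly the sets in K.  Region counts
    sum to the size of the union.
    """
    if not 2 <= len(sets) <= 5:
        raise ValueError(f"venn_partition supports 2-5 sets, got {len(sets)}")
    names = [name for name, _ in sets]
    if len(set(names)) != len(names):
        raise ValueError("set names must be unique")
    membership = {name: set(values) for name, values in sets}

    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[frozenset(combo)] = 0
    union = set().union(*membership.values())
    for element in union:
        key = frozenset(n for n in names if element in membership[n])
        regions[key] += 1
    return regions


@dataclass
class PanelScanResult:
    """Counts of panel genes responding up/down per contrast and pooled."""

    panel_name: str
    panel_size: int
    per_contrast: dict[str, tuple[frozenset[str], frozenset[str]]]
    pooled_up: frozenset[str] = field(default_factory=frozenset)
    pooled_down: frozenset[str] = field(default_factory=frozenset)

    @property
    def n_up(self) -> int:
        return len(self.pooled_up)

    @property
    def n_down(self) -> int:
        return len(self.pooled_down)

    @property
    def ratio_down_over_up(self) -> float | None:
        return self.n_down / self.n_up if self.n_up else None

    @property
    def ratio_up_over_down(self) -> float | None:
        return self.n_up / self.n_down if self.n_down else None

    def percent_down(self, decimals: int = 1) -> float:
        return percent_of_catalog(self.n_down, self.panel_size, decimals)

    def percent_up(self, decimals: int = 1) -> float:
        return percent_of_catalog(self.n_up, self.panel_size, decimals)


def panel_scan(
    contrasts: Sequence[Contrast],
    panel: GeneCatalog,
    threshold: float = DEFAULT_THRESHOLD,
) -> PanelScanResult:
    """Scan a gene panel across contrasts for up/down responses.

    Pooled counts across contrasts are unique genes (a gene moving in two
    datasets counts once per direction).
    """
    if len(panel.genes) == 0:
        raise ValueError("panel must be non-empty")
    per_contrast: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    pooled_up: set[str] = set()
    pooled_down: set[str] = set()
    for contrast in contrasts:
        up: set[str] = set()
        down: set[str] = set()
        for symbol, fc in contrast.fc_by_symbol().items():
            if symbol not in panel.genes:
                continue
            if fc >= threshold:
                up.add(symbol)
            elif fc <= -threshold:
                down.add(symbol)
        per_contrast[contrast.dataset_id] = (frozenset(up), frozenset(down))
        pooled_up |= up
        pooled_down |= down
    return PanelScanResult(
        panel_name=panel.name,
        panel_size=len(panel.genes),
        per_contrast=per_contrast,
        pooled_up=frozenset(pooled_up),
        pooled_down=frozenset(pooled_down),
    )
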