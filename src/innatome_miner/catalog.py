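"""Gene catalogs: loading, validation, canonicalization and composition summaries.

A catalog is a named set of gene symbols with optional per-gene category
annotations.  Two annotation schemes are supported for composition tables:
subcellular *location* (5 classes) and *function* (14 classes).  Panels may
additionally carry a trained-immunity ``pathway`` or a heat-shock ``family``
label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from innatome_miner._util import round_half_up

logger = logging.getLogger(__name__)

SPECIES_TAGS = ("human", "mouse", "rat", "agnostic")

LOCATION_CLASSES = (
    "cytoplasm",
    "extracellular space",
    "nucleus",
    "plasma membrane",
    "other",
)

FUNCTION_CLASSES = (
    "cytokine",
    "enzyme",
    "g-protein-coupled receptor",
    "growth factor",
    "ion channel",
    "kinase",
    "ligand-dependent nuclear receptor",
    "other",
    "peptidase",
    "phosphatase",
    "transcription regulator",
    "translation regulator",
    "transmembrane receptor",
    "transporter",
)

PATHWAY_CLASSES = ("glycolysis", "acetyl-CoA", "mevalonate", "epigenetic")

FAMILY_CLASSES = ("HSP90", "DNAJ/HSP40", "small HSP", "HSP70")

_SCHEME_COLUMNS = {"location": "location_class", "function": "function_class"}
_SCHEME_VOCAB = {"location": LOCATION_CLASSES, "function": FUNCTION_CLASSES}
_OPTIONAL_VOCAB = {"pathway": PATHWAY_CLASSES, "family": FAMILY_CLASSES}


def canonicalize_symbol(symbol: str, species: str = "agnostic") -> str:
    """Return the canonical (uppercase, stripped) form of a gene symbol.

    Human symbols are all-caps while rodent symbols are Title-case; matching
    across species is by the canonical uppercase form only (no ortholog
    mapping — a documented limitation).
    """
    if species not in SPECIES_TAGS:
        raise ValueError(f"unknown species tag: {species!r}")
    if symbol is None:
        raise ValueError("gene symbol must be non-empty")
    canon = str(symbol).strip().upper()
    if not canon:
        raise ValueError("gene symbol must be non-empty")
    return canon


@dataclass
class GeneCatalog:
    """A named set of canonical gene symbols with optional annotations.

    ``annotations`` maps a symbol to a dict holding any of the keys
    ``location_class``, ``function_class``, ``pathway``, ``family``.
    """

    name: str
    species: str
    genes: set[str]
    annotations: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species not in SPECIES_TAGS:
            raise ValueError(f"unknown species tag: {self.species!r}")
        self.genes = {canonicalize_symbol(g, self.species) for g in self.genes}
        for symbol, labels in self.annotations.items():
            if symbol not in self.genes:
                raise ValueError(f"annotated symbol {symbol!r} is not a catalog member")
            for key, value in labels.items():
                vocab = dict(_OPTIONAL_VOCAB)
                vocab["location_class"] = LOCATION_CLASSES
                vocab["function_class"] = FUNCTION_CLASSES
                if key not in vocab:
                    raise ValueError(f"unknown annotation key {key!r} for {symbol!r}")
                if value not in vocab[key]:
                    raise ValueError(
                        f"unknown {key} label {value!r} for symbol {symbol!r}"
                    )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return canonicalize_symbol(symbol) in self.genes

    def annotated_under(self, scheme: str) -> set[str]:
        """Symbols carrying a label for ``scheme`` ('location' or 'function')."""
        column = _SCHEME_COLUMNS[scheme]
        return {s for s, lab in self.annotations.items() if column in lab}

    def to_frame(self) -> pd.DataFrame:
        """Catalog as a TSV-shaped frame, sorted by symbol for round-tripping."""
        columns = ["symbol", "location_class", "function_class", "pathway", "family"]
        rows = []
        for symbol in sorted(self.genes):
            labels = self.annotations.get(symbol, {})
            rows.append(
                {
                    "symbol": symbol,
                    **{c: labels.get(c, "") for c in columns[1:]},
                }
            )
        return pd.DataFrame(rows, columns=columns)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class CategoryComposition:
    """Per-category counts and half-up-rendered percentages over a gene subset."""

    scheme: str
    counts: dict[str, int]
    percents: dict[str, float]
    total: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(self.counts),
                "count": list(self.counts.values()),
                "percent": [self.percents[c] for c in self.counts],
            }
        )


def load_catalog(
    path: str | Path,
    species: str = "agnostic",
    name: str | None = None,
) -> GeneCatalog:
    """Load a catalog TSV (header required, one row per gene).

    Recognized columns: ``symbol`` (required) plus any of ``location_class``,
    ``function_class``, ``pathway``, ``family``.  Duplicate symbols are
    collapsed (first annotation wins) with a logged warning; an unknown
    category label or an empty file is a hard error.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "symbol" not in frame.columns:
        raise ValueError(f"{path}: catalog file must have a 'symbol' column")
    if len(frame) == 0:
        raise ValueError(f"{path}: catalog file has no gene rows")

    annotation_columns = [
        c
        for c in ("location_class", "function_class", "pathway", "family")
        if c in frame.columns
    ]
    vocab = {
        "location_class": LOCATION_CLASSES,
        "function_class": FUNCTION_CLASSES,
        **_OPTIONAL_VOCAB,
    }

    genes: set[str] = set()
    annotations: dict[str, dict[str, str]] = {}
    n_dup = 0
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        record = row._asdict()
        symbol = canonicalize_symbol(record["symbol"], species)
        if symbol in genes:
            n_dup += 1
            continue
        genes.add(symbol)
        labels: dict[str, str] = {}
        for column in annotation_columns:
            value = record[column].strip()
            if not value:
                continue
            if value not in vocab[column]:
                raise ValueError(
                    f"{path} line {idx}: unknown {column} label {value!r} "
                    f"for symbol {symbol!r}"
                )
            labels[column] = value
        if labels:
            annotations[symbol] = labels
    if n_dup:
        logger.warning("%s: collapsed %d duplicate symbol row(s)", path, n_dup)

    return GeneCatalog(
        name=name or path.stem, species=species, genes=genes, annotations=annotations
    )


def category_composition(
    catalog: GeneCatalog,
    subset: Iterable[str] | None = None,
    scheme: str = "location",
) -> CategoryComposition:
    """Count the members of ``subset`` (default: all genes) per category.

    Percentages are 100*count/|subset| rendered half-up to two decimals.
    Every subset member must be a catalog gene annotated under ``scheme``.
    """
    if scheme not in _SCHEME_COLUMNS:
        raise ValueError(f"scheme must be 'location' or 'function', got {scheme!r}")
    column = _SCHEME_COLUMNS[scheme]
    if subset is None:
        members = set(catalog.genes)
    else:
        members = {canonicalize_symbol(s) for s in subset}
        stray = members - catalog.genes
        if stray:
            raise ValueError(f"subset members not in catalog: {sorted(stray)}")
    missing = sorted(
        s for s in members if column not in catalog.annotations.get(s, {})
    )
    if missing:
        raise ValueError(
            f"subset members without a {scheme} annotation: {missing}"
        )

    counts = {category: 0 for category in _SCHEME_VOCAB[scheme]}
    for symbol in members:
        counts[catalog.annotations[symbol][column]] += 1
    total = len(members)
    percents = {
        category: round_half_up(100.0 * n / total, 2) if total else 0.0
        for category, n in counts.items()
    }
    return CategoryComposition(scheme=scheme, counts=counts, percents=percents, total=total)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT pathway collection: name <tab> description <tab> genes...

    Returns a mapping from pathway name to its canonicalized gene set.
    """
    collection: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line: {line[:80]!r}")
            name = fields[0]
            collection[name] = {
                canonicalize_symbol(g) for g in fields[2:] if g.strip()
            }
    return collection
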