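"""Chromatin long-range interaction (CLRI) distance analysis.

Interaction tables (4DGenome-style tabulated text) are anchored to gene
transcription start sites; each cis interaction contributes one signed
base-pair distance from the TSS to the partner locus.  The adopted sign
convention: a partner upstream of the promoter *in gene orientation* is
negative.  Distance distributions of gene sets are compared with the
two-sample Kolmogorov-Smirnov test.

Coordinates are 0-based half-open internally; source files are 1-based
inclusive and converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from innatome_miner.catalog import canonicalize_symbol

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "InteractorAChr",
    "InteractorAStart",
    "InteractorAEnd",
    "InteractorBChr",
    "InteractorBStart",
    "InteractorBEnd",
    "Agg_Gene_A",
    "Agg_Gene_B",
)


@dataclass(frozen=True)
class Locus:
    chrom: str
    start: int  # 0-based
    end: int  # half-open

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"degenerate locus {self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, chrom: str, position: int) -> bool:
        return self.chrom == chrom and self.start <= position < self.end


@dataclass(frozen=True)
class GeneAnchor:
    symbol: str
    chrom: str
    tss: int  # 0-based
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class InteractionRecord:
    interactor_a: Locus
    interactor_b: Locus
    genes_a: frozenset[str]
    genes_b: frozenset[str]
    detection_method: str = ""
    cell_tissue: str = ""

    @property
    def is_cis(self) -> bool:
        return self.interactor_a.chrom == self.interactor_b.chrom


@dataclass
class SignedDistanceSet:
    """Signed TSS-to-partner distances for one labelled gene set."""

    label: str
    distances: list[int]

    def ecdf(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted support points and cumulative fractions (monotone 0..1)."""
        x = np.sort(np.asarray(self.distances))
        y = np.arange(1, len(x) + 1) / len(x)
        return x, y


@dataclass
class CoverageReport:
    missing_genes: tuple[str, ...] = ()
    n_trans: int = 0
    n_dropped_ambiguous: int = 0


def _split_genes(cell: str) -> frozenset[str]:
    tokens = [t for chunk in str(cell).split(";") for t in chunk.split(",")]
    return frozenset(
        canonicalize_symbol(t) for t in tokens if t.strip() and t.strip() != "NA"
    )


def load_interactions(path: str | Path) -> tuple[list[InteractionRecord], int]:
    """Parse a 4DGenome-style interaction TSV.

    1-based inclusive coordinates become 0-based half-open (start shifts by
    -1).  Malformed rows (non-numeric or empty intervals) are skipped and
    counted; a missing required column is a hard error.

    Returns (records, n_skipped).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")

    records: list[InteractionRecord] = []
    n_skipped = 0
    for row in frame.itertuples(index=False):
        rec = row._asdict()
        try:
            locus_a = Locus(
                rec["InteractorAChr"],
                int(rec["InteractorAStart"]) - 1,
                int(rec["InteractorAEnd"]),
            )
            locus_b = Locus(
                rec["InteractorBChr"],
                int(rec["InteractorBStart"]) - 1,
                int(rec["InteractorBEnd"]),
            )
        except (ValueError, TypeError):
            n_skipped += 1
            continue
        records.append(
            InteractionRecord(
                interactor_a=locus_a,
                interactor_b=locus_b,
                genes_a=_split_genes(rec["Agg_Gene_A"]),
                genes_b=_split_genes(rec["Agg_Gene_B"]),
                detection_method=rec.get("Detection_Method", ""),
                cell_tissue=rec.get("Cell_Tissue", ""),
            )
        )
    if n_skipped:
        logger.warning("%s: skipped %d malformed row(s)", path, n_skipped)
    return records, n_skipped


def write_interactions(records: Sequence[InteractionRecord], path: str | Path) -> None:
    """Write records back to 1-based inclusive 4DGenome-style TSV."""
    rows = []
    for r in records:
        rows.append(
            {
                "InteractorAChr": r.interactor_a.chrom,
                "InteractorAStart": r.interactor_a.start + 1,
                "InteractorAEnd": r.interactor_a.end,
                "InteractorBChr": r.interactor_b.chrom,
                "InteractorBStart": r.interactor_b.start + 1,
                "InteractorBEnd": r.interactor_b.end,
                "Agg_Gene_A": ";".join(sorted(r.genes_a)),
                "Agg_Gene_B": ";".join(sorted(r.genes_b)),
                "Detection_Method": r.detection_method,
                "Cell_Tissue": r.cell_tissue,
            }
        )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + ["Detection_Method", "Cell_Tissue"]).to_csv(
        path, sep="\t", index=False
    )


def load_anchors(path: str | Path) -> dict[str, GeneAnchor]:
    """Read gene anchors from BED6 (chrom, start, end, name, score, strand).

    The TSS is the start for '+' genes and end-1 for '-' genes (BED is
    already 0-based half-open).
    """
    anchors: dict[str, GeneAnchor] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: BED6 requires 6 columns, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            symbol = canonicalize_symbol(name)
            tss = int(start) if strand == "+" else int(end) - 1
            anchors[symbol] = GeneAnchor(symbol=symbol, chrom=chrom, tss=tss, strand=strand)
    return anchors


def signed_distance(
    record: InteractionRecord,
    anchor: GeneAnchor,
    partner_side: str,
    strand_aware: bool = True,
    flip_sign: bool = False,
    mode: str = "midpoint",
) -> int:
    """Signed base pairs from the anchor TSS to one interactor of a record.

    Negative means the partner lies upstream of the promoter in gene
    orientation (for '-' strand genes the raw genomic offset is negated).
    ``flip_sign`` inverts the convention; ``mode='nearest_edge'`` measures to
    the closest interval edge instead of the midpoint.
    """
    if partner_side not in ("A", "B"):
        raise ValueError("partner_side must be 'A' or 'B'")
    partner = record.interactor_a if partner_side == "A" else record.interactor_b
    if partner.chrom != anchor.chrom:
        raise ValueError(
            f"trans interaction: partner on {partner.chrom}, anchor on {anchor.chrom}"
        )
    if mode == "midpoint":
        point = partner.midpoint
    elif mode == "nearest_edge":
        if anchor.tss < partner.start:
            point = partner.start
        elif anchor.tss >= partner.end:
            point = partner.end - 1
        else:
            point = anchor.tss
    else:
        raise ValueError(f"unknown mode {mode!r}")
    d = point - anchor.tss
    if strand_aware and anchor.strand == "-":
        d = -d
    if flip_sign:
        d = -d
    return int(d)


def distance_set(
    records: Sequence[InteractionRecord],
    genes: Iterable[str],
    anchors: Mapping[str, GeneAnchor],
    label: str = "",
    strand_aware: bool = True,
    flip_sign: bool = False,
    mode: str = "midpoint",
) -> tuple[SignedDistanceSet, CoverageReport]:
    """Collect signed partner distances for every record touching ``genes``.

    For each record whose gene-association field names a requested gene, the
    distance runs from that gene's TSS to the *other* interactor.  When both
    interactors name the gene, the partner is the interactor not containing
    the TSS; records where neither or both contain it are dropped and
    counted.  Trans records are excluded and counted; genes without an
    anchor are reported, not fatal.
    """
    wanted = {canonicalize_symbol(g) for g in genes}
    missing = tuple(sorted(wanted - set(anchors)))
    wanted -= set(missing)

    distances: list[int] = []
    n_trans = 0
    n_ambiguous = 0
    for record in records:
        hits = (record.genes_a | record.genes_b) & wanted
        for gene in sorted(hits):
            anchor = anchors[gene]
            if not record.is_cis:
                n_trans += 1
                continue
            if record.interactor_a.chrom != anchor.chrom:
                n_trans += 1
                continue
            in_a = gene in record.genes_a
            in_b = gene in record.genes_b
            if in_a and in_b:
                contains_a = record.interactor_a.contains(anchor.chrom, anchor.tss)
                contains_b = record.interactor_b.contains(anchor.chrom, anchor.tss)
                if contains_a == contains_b:
                    n_ambiguous += 1
                    continue
                side = "B" if contains_a else "A"
            else:
                side = "B" if in_a else "A"
            distances.append(
                signed_distance(
                    record,
                    anchor,
                    side,
                    strand_aware=strand_aware,
                    flip_sign=flip_sign,
                    mode=mode,
                )
            )
    report = CoverageReport(
        missing_genes=missing, n_trans=n_trans, n_dropped_ambiguous=n_ambiguous
    )
    return SignedDistanceSet(label=label, distances=distances), report


def ks_compare(
    a: SignedDistanceSet | Sequence[float],
    b: SignedDistanceSet | Sequence[float],
) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D is the supremum ECDF gap; p is the asymptotic approximation.  Both
    samples must be non-empty.
    """
    xs = a.distances if isinstance(a, SignedDistanceSet) else list(a)
    ys = b.distances if isinstance(b, SignedDistanceSet) else list(b)
    if not len(xs) or not len(ys):
        raise ValueError("both distance sets must be non-empty")
    result = stats.ks_2samp(xs, ys, alternative="two-sided", method="asymp")
    return float(result.statistic), float(result.pvalue)
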