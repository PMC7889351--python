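"""Expression contrasts: signed fold change, probe collapsing, QC, DEG calling.

A contrast is one treatment-vs-control comparison.  Differential expression
is called purely by signed fold change (default cutoff 1.5, boundary
inclusive); significance columns in input files are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from innatome_miner.catalog import GeneCatalog, canonicalize_symbol

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 1.5

GENE_COLUMNS = ["symbol", "signed_fc"]


def signed_fold_change(treat_mean: float, control_mean: float) -> float:
    """Signed expression ratio with magnitude >= 1.

    Returns treat/control when treat >= control and -(control/treat)
    otherwise, so down-regulation is encoded as a negative ratio (e.g. a
    halving is -2.0, not 0.5).  Both inputs must be positive linear-scale
    values.
    """
    if treat_mean <= 0 or control_mean <= 0:
        raise ValueError(
            f"expression means must be positive, got ({treat_mean}, {control_mean})"
        )
    if treat_mean >= control_mean:
        return treat_mean / control_mean
    return -(control_mean / treat_mean)


def signed_fc_array(treat: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Vectorized :func:`signed_fold_change`."""
    treat = np.asarray(treat, dtype=float)
    control = np.asarray(control, dtype=float)
    if np.any(treat <= 0) or np.any(control <= 0):
        raise ValueError("expression means must be positive")
    return np.where(treat >= control, treat / control, -(control / treat))


@dataclass
class QcReport:
    """Housekeeping-gene QC: per-gene signed fold changes and a pass flag."""

    values: dict[str, float | None]
    qc_threshold: float
    missing: tuple[str, ...] = ()

    @property
    def max_abs_fc(self) -> float | None:
        present = [abs(v) for v in self.values.values() if v is not None]
        return max(present) if present else None

    @property
    def passed(self) -> bool:
        if self.missing:
            return False
        return all(
            v is not None and abs(v) < self.qc_threshold for v in self.values.values()
        )


@dataclass
class Contrast:
    """Gene-level signed fold changes for one treatment-vs-control comparison."""

    dataset_id: str
    species: str
    frame: pd.DataFrame  # columns: symbol, signed_fc (+ optional means)
    ambiguous: frozenset[str] = frozenset()
    qc: QcReport | None = None

    def __post_init__(self) -> None:
        missing = [c for c in GENE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"contrast frame missing columns: {missing}")

    def fc_by_symbol(self) -> dict[str, float]:
        return dict(zip(self.frame["symbol"], self.frame["signed_fc"]))

    @property
    def genes(self) -> set[str]:
        return set(self.frame["symbol"])

    def inverted(self) -> "Contrast":
        """The contrast with treatment and control roles swapped."""
        frame = self.frame.copy()
        frame["signed_fc"] = -frame["signed_fc"]
        if {"treat_mean", "control_mean"} <= set(frame.columns):
            frame[["treat_mean", "control_mean"]] = frame[
                ["control_mean", "treat_mean"]
            ].to_numpy()
        return Contrast(
            dataset_id=self.dataset_id,
            species=self.species,
            frame=frame,
            ambiguous=self.ambiguous,
            qc=None,
        )


@dataclass
class DegResult:
    """Disjoint up/down gene sets called at a fold-change threshold."""

    up: set[str]
    down: set[str]
    threshold: float = DEFAULT_THRESHOLD
    ambiguous: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets must be disjoint")


def collapse_probes(frame: pd.DataFrame) -> tuple[pd.DataFrame, set[str], int]:
    """Collapse a per-probe table to one record per gene symbol.

    Each gene keeps the probe with the largest |signed_fc|.  A gene whose
    top-magnitude probes tie with opposite signs is flagged ambiguous (it
    keeps the positive value but should be excluded from DEG calls).  Rows
    without a symbol are dropped and counted.

    Returns (gene_frame, ambiguous_symbols, n_dropped).
    """
    work = frame.copy()
    symbols = work["symbol"].astype(str).str.strip()
    keep = symbols != ""
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d probe row(s) without a gene symbol", n_dropped)
    work = work.loc[keep].copy()
    work["symbol"] = symbols[keep].str.upper()

    records: list[dict] = []
    ambiguous: set[str] = set()
    for symbol, group in work.groupby("symbol", sort=True):
        fc = group["signed_fc"].to_numpy(dtype=float)
        magnitude = np.abs(fc)
        best = magnitude.max()
        at_best = fc[magnitude == best]
        if (at_best > 0).any() and (at_best < 0).any():
            ambiguous.add(symbol)
            chosen = best
        else:
            chosen = at_best[0]
        record = {"symbol": symbol, "signed_fc": float(chosen)}
        row = group.iloc[int(np.argmax(magnitude))]
        for col in ("treat_mean", "control_mean"):
            if col in group.columns:
                record[col] = float(row[col])
        records.append(record)
    gene_frame = pd.DataFrame(records, columns=list(records[0]) if records else GENE_COLUMNS)
    return gene_frame, ambiguous, n_dropped


def load_contrast(
    path: str | Path,
    dataset_id: str | None = None,
    species: str = "agnostic",
    precomputed_fc: bool = False,
    log2: bool = False,
) -> Contrast:
    """Load a contrast TSV and collapse it to gene level.

    Expected columns: ``feature_id``, ``symbol`` and either
    (``treat_mean``, ``control_mean``) or, with ``precomputed_fc``, a
    ``signed_fc`` column.  ``log2`` converts log2-scale means to linear
    before ratioing.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    if "symbol" not in frame.columns:
        raise ValueError(f"{path}: contrast file must have a 'symbol' column")
    if precomputed_fc:
        if "signed_fc" not in frame.columns:
            raise ValueError(f"{path}: --precomputed-fc requires a 'signed_fc' column")
        frame["signed_fc"] = frame["signed_fc"].astype(float)
    else:
        for col in ("treat_mean", "control_mean"):
            if col not in frame.columns:
                raise ValueError(f"{path}: contrast file must have a {col!r} column")
        treat = frame["treat_mean"].astype(float).to_numpy()
        control = frame["control_mean"].astype(float).to_numpy()
        if log2:
            treat = np.exp2(treat)
            control = np.exp2(control)
            frame["treat_mean"] = treat
            frame["control_mean"] = control
        frame["signed_fc"] = signed_fc_array(treat, control)
    gene_frame, ambiguous, _ = collapse_probes(frame)
    return Contrast(
        dataset_id=dataset_id or path.stem,
        species=species,
        frame=gene_frame,
        ambiguous=frozenset(ambiguous),
    )


def housekeeping_qc(
    contrast: Contrast,
    housekeeping: GeneCatalog,
    qc_threshold: float = DEFAULT_THRESHOLD,
) -> QcReport:
    """Check that every housekeeping gene is present and near-unchanged.

    A missing gene fails the report (reason recorded) rather than raising.
    """
    fc = contrast.fc_by_symbol()
    values: dict[str, float | None] = {}
    missing: list[str] = []
    for symbol in sorted(housekeeping.genes):
        if symbol in fc:
            values[symbol] = float(fc[symbol])
        else:
            values[symbol] = None
            missing.append(symbol)
    return QcReport(values=values, qc_threshold=qc_threshold, missing=tuple(missing))


class QcError(RuntimeError):
    """Raised when DEGs are requested on a QC-failing contrast."""

    def __init__(self, report: QcReport, dataset_id: str):
        self.report = report
        super().__init__(
            f"housekeeping QC failed for {dataset_id} "
            f"(missing={list(report.missing)}, max|fc|={report.max_abs_fc})"
        )


def call_degs(
    contrast: Contrast,
    catalog: GeneCatalog | Iterable[str] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    override_qc: bool = False,
) -> DegResult:
    """Call up/down-regulated catalog genes at |signed_fc| >= threshold.

    The boundary is inclusive: a gene at exactly +threshold is called up.
    Genes flagged ambiguous by probe collapsing are excluded and reported.
    Requires a passing QC report on the contrast unless ``override_qc``.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if contrast.qc is not None and not contrast.qc.passed and not override_qc:
        raise QcError(contrast.qc, contrast.dataset_id)
    if contrast.qc is not None and not contrast.qc.passed and override_qc:
        logger.warning("QC override: calling DEGs on failing contrast %s", contrast.dataset_id)

    if catalog is None:
        members = contrast.genes
    elif isinstance(catalog, GeneCatalog):
        members = catalog.genes
    else:
        members = {canonicalize_symbol(g) for g in catalog}

    up: set[str] = set()
    down: set[str] = set()
    ambiguous: set[str] = set()
    for symbol, fc in contrast.fc_by_symbol().items():
        if symbol not in members:
            continue
        if symbol in contrast.ambiguous:
            if abs(fc) >= threshold:
                ambiguous.add(symbol)
            continue
        if fc >= threshold:
            up.add(symbol)
        elif fc <= -threshold:
            down.add(symbol)
    return DegResult(up=up, down=down, threshold=threshold, ambiguous=ambiguous)


def write_contrast(contrast: Contrast, path: str | Path) -> None:
    """Write a gene-level contrast back to TSV (symbol sorted)."""
    frame = contrast.frame.sort_values("symbol")
    frame.to_csv(path, sep="\t", index=False)
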