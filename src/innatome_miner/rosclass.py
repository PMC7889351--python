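"""Rule-based four-group ROS-dependency classification.

Evidence comes from perturbation contrasts of two knockout types: cells
deficient in the ROS-generating oxidase NOX2 and cells deficient in the
antioxidant transcription factor Nrf2.  A gene going down when NOX2 is lost,
or up when Nrf2 is lost, is evidence that ROS promotes it; the opposite
directions are evidence that ROS suppresses it.  Conflicting evidence makes
a gene "uncertain"; no evidence makes it "independent".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from innatome_miner.catalog import canonicalize_symbol
from innatome_miner.degcall import DEFAULT_THRESHOLD, Contrast
from innatome_miner.profile import percent_of_catalog

KO_TYPES = ("NOX2", "Nrf2")
GROUPS = ("promoted", "suppressed", "uncertain", "independent")


class EvidenceRecord(NamedTuple):
    dataset_id: str
    ko_type: str  # "NOX2" | "Nrf2"
    direction: str  # "up" | "down" | "unchanged"


@dataclass
class RosEvidence:
    gene: str
    records: list[EvidenceRecord]


def classify_gene(
    records: Iterable[EvidenceRecord],
    strict_and: bool = False,
) -> str:
    """Assign one of promoted/suppressed/uncertain/independent.

    Default OR-of-evidence mode: promoted evidence is (down in a NOX2
    dataset) or (up in an Nrf2 dataset); suppressed evidence is the mirror
    image.  A gene with only promoted evidence is promoted, only suppressed
    evidence suppressed, both kinds uncertain, neither independent.

    ``strict_and`` additionally requires supporting evidence from *both*
    knockout types before calling promoted or suppressed; single-sided
    evidence falls back to uncertain.
    """
    records = list(records)
    if not records:
        raise ValueError("at least one evidence record is required")
    promoted_types: set[str] = set()
    suppressed_types: set[str] = set()
    for rec in records:
        if rec.ko_type not in KO_TYPES:
            raise ValueError(f"unknown ko_type {rec.ko_type!r}")
        if rec.direction not in ("up", "down", "unchanged"):
            raise ValueError(f"unknown direction {rec.direction!r}")
        if rec.direction == "unchanged":
            continue
        if (rec.ko_type == "NOX2") == (rec.direction == "down"):
            promoted_types.add(rec.ko_type)
        else:
            suppressed_types.add(rec.ko_type)

    has_promoted = bool(promoted_types)
    has_suppressed = bool(suppressed_types)
    if has_promoted and has_suppressed:
        return "uncertain"
    if has_promoted:
        if strict_and and promoted_types != set(KO_TYPES):
            return "uncertain"
        return "promoted"
    if has_suppressed:
        if strict_and and suppressed_types != set(KO_TYPES):
            return "uncertain"
        return "suppressed"
    return "independent"


@dataclass
class RosClassification:
    """Per-gene groups plus group counts/percentages (1-decimal half-up)."""

    groups: dict[str, str]

    @property
    def counts(self) -> dict[str, int]:
        out = {g: 0 for g in GROUPS}
        for group in self.groups.values():
            out[group] += 1
        return out

    @property
    def percents(self) -> dict[str, float]:
        n = len(self.groups)
        return {g: percent_of_catalog(c, n, 1) for g, c in self.counts.items()}

    @property
    def ros_related_pct(self) -> float:
        """Percentage of genes with any ROS response (100 minus independent)."""
        n = len(self.groups)
        return percent_of_catalog(n - self.counts["independent"], n, 1)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"symbol": list(self.groups), "group": list(self.groups.values())}
        ).sort_values("symbol", ignore_index=True)


def _direction(fc: float | None, threshold: float) -> str:
    if fc is None:
        return "unchanged"
    if fc >= threshold:
        return "up"
    if fc <= -threshold:
        return "down"
    return "unchanged"


def classify_set(
    genes: Iterable[str],
    nox2: Sequence[Contrast] = (),
    nrf2: Sequence[Contrast] = (),
    threshold: float = DEFAULT_THRESHOLD,
    strict_and: bool = False,
) -> RosClassification:
    """Classify a gene set from NOX2-KO and Nrf2-KO contrasts.

    Each contrast contributes one evidence record per gene (genes missing
    from a platform contribute "unchanged").  Needs at least one dataset of
    at least one knockout type.
    """
    members = sorted({canonicalize_symbol(g) for g in genes})
    if not members:
        raise ValueError("gene set must be non-empty")
    if not nox2 and not nrf2:
        raise ValueError("need at least one NOX2 or Nrf2 contrast")

    panels = [("NOX2", c) for c in nox2] + [("Nrf2", c) for c in nrf2]
    fc_maps = [(ko, c.dataset_id, c.fc_by_symbol()) for ko, c in panels]

    groups: dict[str, str] = {}
    for gene in members:
        records = [
            EvidenceRecord(dataset_id, ko, _direction(fc.get(gene), threshold))
            for ko, dataset_id, fc in fc_maps
        ]
        groups[gene] = classify_gene(records, strict_and=strict_and)
    return RosClassification(groups=groups)
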