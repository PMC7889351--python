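"""Cross-dataset directional concordance and mechanism ranking.

Given reference DEG sets (genes a treatment moved up or down) and a panel of
perturbation contrasts (shear stress, hyperthermia, cytokine KO/treatment,
checkpoint-receptor overexpression, ROS-pathway KO), each reference gene is
binned by its direction in each perturbation; mechanisms are then ranked by
the pooled fraction of reference genes responsive in at least one of their
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from innatome_miner._util import round_half_up
from innatome_miner.degcall import DEFAULT_THRESHOLD, Contrast
from innatome_miner.profile import ModulatedSet, percent_of_catalog


@dataclass
class ConcordanceCell:
    """How one reference DEG set responds in one perturbation contrast.

    Genes absent from the perturbation platform are counted separately as
    ``n_unmeasured``; the four bins partition the reference set.  Percentages
    use the full reference size as denominator and 1-decimal half-up rendering.
    """

    reference_id: str
    reference_direction: str
    reference_size: int
    reference_genes: frozenset[str]
    perturbation_id: str
    genes_up: frozenset[str]
    genes_down: frozenset[str]
    n_unchanged: int
    n_unmeasured: int

    @property
    def n_up(self) -> int:
        return len(self.genes_up)

    @property
    def n_down(self) -> int:
        return len(self.genes_down)

    @property
    def pct_up(self) -> float:
        return percent_of_catalog(self.n_up, self.reference_size, 1)

    @property
    def pct_down(self) -> float:
        return percent_of_catalog(self.n_down, self.reference_size, 1)

    def __post_init__(self) -> None:
        parts = self.n_up + self.n_down + self.n_unchanged + self.n_unmeasured
        if parts != self.reference_size:
            raise ValueError(
                f"bins do not partition the reference set: {parts} != {self.reference_size}"
            )


def concordance(
    reference: ModulatedSet,
    perturbation: Contrast,
    threshold: float = DEFAULT_THRESHOLD,
) -> ConcordanceCell:
    """Bin each reference gene by its signed fold change in the perturbation."""
    if not reference.genes:
        raise ValueError("reference gene set must be non-empty")
    fc = perturbation.fc_by_symbol()
    up: set[str] = set()
    down: set[str] = set()
    unchanged = 0
    unmeasured = 0
    for gene in reference.genes:
        if gene not in fc:
            unmeasured += 1
        elif fc[gene] >= threshold:
            up.add(gene)
        elif fc[gene] <= -threshold:
            down.add(gene)
        else:
            unchanged += 1
    return ConcordanceCell(
        reference_id=reference.dataset_id,
        reference_direction=reference.direction,
        reference_size=len(reference.genes),
        reference_genes=frozenset(reference.genes),
        perturbation_id=perturbation.dataset_id,
        genes_up=frozenset(up),
        genes_down=frozenset(down),
        n_unchanged=unchanged,
        n_unmeasured=unmeasured,
    )


def concordance_matrix(
    references: Sequence[ModulatedSet],
    perturbations: Sequence[Contrast],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[ConcordanceCell]:
    """Full reference x perturbation cross-product, row-major."""
    if not references or not perturbations:
        raise ValueError("need at least one reference and one perturbation")
    return [
        concordance(ref, pert, threshold)
        for ref in references
        for pert in perturbations
    ]


def matrix_frame(cells: Sequence[ConcordanceCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reference_id": c.reference_id,
                "direction": c.reference_direction,
                "reference_size": c.reference_size,
                "perturbation_id": c.perturbation_id,
                "n_up": c.n_up,
                "n_down": c.n_down,
                "n_unchanged": c.n_unchanged,
                "n_unmeasured": c.n_unmeasured,
                "pct_up": c.pct_up,
                "pct_down": c.pct_down,
            }
            for c in cells
        ]
    )


@dataclass
class MechanismRanking:
    """Mechanisms ordered by pooled responsive fraction (descending, ties by name)."""

    fractions: dict[str, float]
    order: list[str]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mechanism": self.order, "related_pct": [self.fractions[m] for m in self.order]}
        )


def rank_mechanisms(
    cells: Sequence[ConcordanceCell],
    grouping: Mapping[str, str],
) -> MechanismRanking:
    """Rank mechanisms by the fraction of reference genes they move.

    A reference gene is "responsive" to a mechanism when |signed_fc| crossed
    the threshold in at least one of that mechanism's datasets (union
    semantics), so duplicating a dataset cannot change the ranking.  The
    denominator pools unique genes over all reference sets appearing in the
    matrix.
    """
    if not cells:
        raise ValueError("empty concordance matrix")
    unassigned = {c.perturbation_id for c in cells} - set(grouping)
    if unassigned:
        raise ValueError(f"perturbations without a mechanism: {sorted(unassigned)}")

    all_reference: set[str] = set()
    responsive: dict[str, set[str]] = {}
    mechanisms = sorted(set(grouping[c.perturbation_id] for c in cells))
    for mech in mechanisms:
        responsive[mech] = set()
    for cell in cells:
        all_reference |= cell.reference_genes
        mech = grouping[cell.perturbation_id]
        responsive[mech] |= cell.genes_up | cell.genes_down

    denominator = len(all_reference)
    fractions = {
        mech: round_half_up(100.0 * len(genes) / denominator, 1)
        for mech, genes in responsive.items()
    }
    order = sorted(fractions, key=lambda m: (-fractions[m], m))
    return MechanismRanking(fractions=fractions, order=order)
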