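"""Seeded synthetic-data generation with exported ground truth.

Every input class the analysis modules consume can be emulated here:
probe-level expression contrasts with stable housekeeping genes and planted
up/down genes, perturbation contrast panels with planted concordance
fractions, NOX2-KO/Nrf2-KO panels with a planted four-group ROS structure,
and interaction tables with planted signed distance distributions.  All
randomness flows from a single integer seed; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from innatome_miner.degcall import Contrast, housekeeping_qc, signed_fc_array
from innatome_miner.profile import ModulatedSet
from innatome_miner.resources import HOUSEKEEPING_GENES, housekeeping_catalog

# Plausible linear-scale microarray intensity baseline (irrelevant to ratios).
BASELINE_MEANLOG = 7.0
BASELINE_SDLOG = 1.0

# Housekeeping ratios are planted strictly inside this magnitude band.
HOUSEKEEPING_MAX_ABS_FC = 1.28


@dataclass
class ExpressionTruth:
    """Planted ground truth for one generated contrast."""

    up: frozenset[str]
    down: frozenset[str]
    effect_size: float


@dataclass
class ExpressionConfig:
    seed: int = 0
    dataset_id: str = "synth-contrast"
    n_genes: int = 1376
    n_up: int = 77
    n_down: int = 39
    effect_size: float = 2.0
    noise_sigma: float = 0.0  # log-normal sigma applied to the treat/control ratio
    probes_per_gene: int = 1
    gene_prefix: str = "IG"

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("planted up+down genes exceed n_genes")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")


def _housekeeping_ratios(rng: np.random.Generator) -> dict[str, float]:
    """Signed housekeeping ratios planted well inside the QC band."""
    out = {}
    for gene in HOUSEKEEPING_GENES:
        magnitude = float(rng.uniform(1.0, HOUSEKEEPING_MAX_ABS_FC))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out[gene] = sign * magnitude
    return out


def gen_expression(config: ExpressionConfig) -> tuple[Contrast, pd.DataFrame, ExpressionTruth]:
    """Generate a probe-level contrast with planted DEGs and housekeeping genes.

    Returns (gene-level Contrast with QC attached, probe-level frame, truth).
    At zero noise every non-planted gene sits at ratio exactly 1, so DEG
    calls recover the planted sets exactly.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"{config.gene_prefix}{i:04d}" for i in range(1, config.n_genes + 1)]
    order = rng.permutation(config.n_genes)
    up = frozenset(genes[i] for i in order[: config.n_up])
    down = frozenset(genes[i] for i in order[config.n_up : config.n_up + config.n_down])

    ratios = {}
    for gene in genes:
        if gene in up:
            base = config.effect_size
        elif gene in down:
            base = 1.0 / config.effect_size
        else:
            base = 1.0
        noise = float(np.exp(rng.normal(0.0, config.noise_sigma))) if config.noise_sigma else 1.0
        ratios[gene] = base * noise
    for gene, signed in _housekeeping_ratios(rng).items():
        ratios[gene] = signed if signed > 0 else -1.0 / signed

    rows = []
    probe = 0
    for gene, ratio in ratios.items():
        for _ in range(config.probes_per_gene):
            probe += 1
            control = float(rng.lognormal(BASELINE_MEANLOG, BASELINE_SDLOG))
            rows.append(
                {
                    "feature_id": f"probe_{probe:06d}",
                    "symbol": gene,
                    "treat_mean": control * ratio,
                    "control_mean": control,
                }
            )
    probe_frame = pd.DataFrame(rows)
    probe_frame["signed_fc"] = signed_fc_array(
        probe_frame["treat_mean"].to_numpy(), probe_frame["control_mean"].to_numpy()
    )

    from innatome_miner.degcall import collapse_probes  # local to avoid cycle at import

    gene_frame, ambiguous, _ = collapse_probes(probe_frame)
    contrast = Contrast(
        dataset_id=config.dataset_id,
        species="agnostic",
        frame=gene_frame,
        ambiguous=frozenset(ambiguous),
    )
    contrast.qc = housekeeping_qc(contrast, housekeeping_catalog())
    truth = ExpressionTruth(up=up, down=down, effect_size=config.effect_size)
    return contrast, probe_frame, truth


@dataclass
class PerturbationSpec:
    """How many genes of each reference set a perturbation moves, and its mechanism."""

    dataset_id: str
    mechanism: str
    moved_up: dict[str, int] = field(default_factory=dict)  # reference_id -> count
    moved_down: dict[str, int] = field(default_factory=dict)


@dataclass
class SuiteTruth:
    """Planted per-perturbation responsive genes: dataset_id -> (up, down)."""

    moved: dict[str, tuple[frozenset[str], frozenset[str]]]
    grouping: dict[str, str]


def gen_perturbation_suite(
    references: Mapping[str, ModulatedSet],
    specs: Sequence[PerturbationSpec],
    seed: int = 0,
    effect_size: float = 2.0,
    noise_sigma: float = 0.0,
) -> tuple[list[Contrast], SuiteTruth]:
    """Generate perturbation contrasts with planted concordance counts.

    Each spec yields one contrast covering the union of all reference genes
    plus the housekeeping panel; exactly the requested numbers of each
    reference's genes are planted up/down, the rest stay at ratio 1 (plus
    optional log-normal noise).
    """
    if effect_size < 1:
        raise ValueError("effect_size must be >= 1")
    all_genes = sorted(set().union(*(r.genes for r in references.values())))

    contrasts: list[Contrast] = []
    moved: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    grouping: dict[str, str] = {}
    rng = np.random.default_rng(seed)
    for spec in specs:
        up: set[str] = set()
        down: set[str] = set()
        for ref_id, n in sorted(spec.moved_up.items()):
            pool = sorted(references[ref_id].genes - up - down)
            if n > len(pool):
                raise ValueError(f"{spec.dataset_id}: cannot move {n} genes up in {ref_id}")
            up |= set(map(str, rng.choice(pool, size=n, replace=False)))
        for ref_id, n in sorted(spec.moved_down.items()):
            pool = sorted(references[ref_id].genes - up - down)
            if n > len(pool):
                raise ValueError(f"{spec.dataset_id}: cannot move {n} genes down in {ref_id}")
            down |= set(map(str, rng.choice(pool, size=n, replace=False)))

        rows = []
        ratios = {g: 1.0 for g in all_genes}
        ratios.update({g: effect_size for g in up})
        ratios.update({g: 1.0 / effect_size for g in down})
        for gene, signed in _housekeeping_ratios(rng).items():
            ratios[gene] = signed if signed > 0 else -1.0 / signed
        for i, (gene, ratio) in enumerate(ratios.items(), start=1):
            noise = (
                float(np.exp(rng.normal(0.0, noise_sigma)))
                if noise_sigma and gene not in HOUSEKEEPING_GENES
                else 1.0
            )
            control = float(rng.lognormal(BASELINE_MEANLOG, BASELINE_SDLOG))
            rows.append(
                {
                    "feature_id": f"probe_{i:06d}",
                    "symbol": gene,
                    "treat_mean": control * ratio * noise,
                    "control_mean": control,
                }
            )
        frame = pd.DataFrame(rows)
        frame["signed_fc"] = signed_fc_array(
            frame["treat_mean"].to_numpy(), frame["control_mean"].to_numpy()
        )
        contrast = Contrast(
            dataset_id=spec.dataset_id,
            species="agnostic",
            frame=frame[["symbol", "signed_fc", "treat_mean", "control_mean"]],
        )
        contrast.qc = housekeeping_qc(contrast, housekeeping_catalog())
        contrasts.append(contrast)
        moved[spec.dataset_id] = (frozenset(up), frozenset(down))
        grouping[spec.dataset_id] = spec.mechanism

    return contrasts, SuiteTruth(moved=moved, grouping=grouping)


ROS_GROUP_DIRECTIONS = {
    # group -> (direction in NOX2-KO, direction in Nrf2-KO)
    "promoted": ("down", "up"),
    "suppressed": ("up", "down"),
    "uncertain": ("down", "down"),  # conflicting evidence
    "independent": ("unchanged", "unchanged"),
}


def gen_ros_panels(
    genes: Sequence[str],
    group_counts: Mapping[str, int],
    seed: int = 0,
    effect_size: float = 2.0,
) -> tuple[Contrast, Contrast, dict[str, str]]:
    """Generate one NOX2-KO and one Nrf2-KO contrast with planted ROS groups.

    ``group_counts`` maps promoted/suppressed/uncertain/independent to the
    number of genes planted in that group; counts must sum to len(genes).

    Returns (nox2_contrast, nrf2_contrast, gene -> group assignment).
    """
    total = sum(group_counts.values())
    if total != len(genes):
        raise ValueError(f"group counts sum to {total}, expected {len(genes)}")
    unknown = set(group_counts) - set(ROS_GROUP_DIRECTIONS)
    if unknown:
        raise ValueError(f"unknown ROS groups: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(sorted(genes)))
    assignment: dict[str, str] = {}
    cursor = 0
    for group in ("promoted", "suppressed", "uncertain", "independent"):
        count = group_counts.get(group, 0)
        for gene in shuffled[cursor : cursor + count]:
            assignment[gene] = group
        cursor += count

    def build(dataset_id: str, which: int) -> Contrast:
        rows = []
        for gene in sorted(assignment):
            direction = ROS_GROUP_DIRECTIONS[assignment[gene]][which]
            ratio = {
                "up": effect_size,
                "down": 1.0 / effect_size,
                "unchanged": 1.0,
            }[direction]
            control = float(rng.lognormal(BASELINE_MEANLOG, BASELINE_SDLOG))
            rows.append(
                {
                    "symbol": gene,
                    "treat_mean": control * ratio,
                    "control_mean": control,
                }
            )
        frame = pd.DataFrame(rows)
        frame["signed_fc"] = signed_fc_array(
            frame["treat_mean"].to_numpy(), frame["control_mean"].to_numpy()
        )
        return Contrast(dataset_id=dataset_id, species="agnostic", frame=frame)

    return build("NOX2-KO-synth", 0), build("Nrf2-KO-synth", 1), assignment


@dataclass
class OffsetSpec:
    """Signed-distance distribution for one gene set's interaction partners.

    Magnitudes are |normal(location, scale)|; the sign is positive
    (downstream) with probability (1+sign_bias)/2, so sign_bias=+1 plants
    everything downstream, -1 everything upstream, 0 symmetric.
    """

    location: float
    scale: float
    sign_bias: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.sign_bias <= 1.0:
            raise ValueError("sign_bias must lie in [-1, 1]")


@dataclass
class InteractionTruth:
    """Planted distances per gene-set label, plus injected bad-row counts."""

    distances: dict[str, list[int]]
    n_trans_injected: int
    n_malformed_injected: int


def gen_interactions(
    gene_sets: Mapping[str, Sequence[str]],
    offsets: Mapping[str, OffsetSpec],
    n_per_set: int = 98,
    seed: int = 0,
    n_trans: int = 0,
    n_malformed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, InteractionTruth]:
    """Generate a 1-based interaction table and BED6 anchors with known offsets.

    Each gene-set label draws ``n_per_set`` signed offsets from its
    :class:`OffsetSpec`; interaction records are laid out so that the signed
    TSS-to-partner distance (strand-aware midpoint convention) equals the
    planted offset exactly.  ``n_trans`` trans-chromosomal and
    ``n_malformed`` empty-interval rows are appended for parser tests.

    Returns (interaction frame, BED6 anchor frame, truth).
    """
    if n_per_set < 0 or n_trans < 0 or n_malformed < 0:
        raise ValueError("row counts must be non-negative")
    missing = set(gene_sets) - set(offsets)
    if missing:
        raise ValueError(f"gene sets without an offset spec: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    base = 200_000_000  # keeps every planted partner coordinate positive
    anchor_rows = []
    interaction_rows = []
    truth: dict[str, list[int]] = {label: [] for label in gene_sets}

    chrom_index = 0
    all_genes: list[tuple[str, str]] = []  # (label, gene)
    for label, genes in gene_sets.items():
        for gene in genes:
            all_genes.append((label, gene))

    anchors: dict[str, tuple[str, int, str]] = {}
    for label, gene in all_genes:
        chrom_index += 1
        chrom = f"chr{chrom_index}"
        strand = "+" if rng.random() < 0.5 else "-"
        tss = base + int(rng.integers(0, 1_000_000))
        anchors[gene] = (chrom, tss, strand)
        start = tss if strand == "+" else tss - 999
        anchor_rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + 1000,
                "name": gene,
                "score": 0,
                "strand": strand,
            }
        )

    for label, genes in gene_sets.items():
        spec = offsets[label]
        if not len(genes):
            continue
        for i in range(n_per_set):
            gene = genes[i % len(genes)]
            chrom, tss, strand = anchors[gene]
            magnitude = abs(float(rng.normal(spec.location, spec.scale)))
            magnitude = max(int(round(magnitude)), 2_000)  # keep partner off the anchor
            sign = 1 if rng.random() < (1.0 + spec.sign_bias) / 2.0 else -1
            d = sign * magnitude
            genomic = d if strand == "+" else -d
            point = tss + genomic
            half = 50
            start0, end0 = point - half, point + half  # 0-based; midpoint == point
            interaction_rows.append(
                {
                    "InteractorAChr": chrom,
                    "InteractorAStart": (tss - 500) + 1,
                    "InteractorAEnd": tss + 500,
                    "InteractorBChr": chrom,
                    "InteractorBStart": start0 + 1,
                    "InteractorBEnd": end0,
                    "Agg_Gene_A": gene,
                    "Agg_Gene_B": "",
                    "Detection_Method": "Hi-C",
                    "Cell_Tissue": "synthetic",
                }
            )
            truth[label].append(d)

    for k in range(n_trans):
        label, gene = all_genes[k % len(all_genes)]
        chrom, tss, strand = anchors[gene]
        interaction_rows.append(
            {
                "InteractorAChr": chrom,
                "InteractorAStart": (tss - 500) + 1,
                "InteractorAEnd": tss + 500,
                "InteractorBChr": "chrT",
                "InteractorBStart": 1_000_001,
                "InteractorBEnd": 1_002_000,
                "Agg_Gene_A": gene,
                "Agg_Gene_B": "",
                "Detection_Method": "Hi-C",
                "Cell_Tissue": "synthetic",
            }
        )
    for k in range(n_malformed):
        label, gene = all_genes[k % len(all_genes)]
        chrom, tss, strand = anchors[gene]
        interaction_rows.append(
            {
                "InteractorAChr": chrom,
                "InteractorAStart": tss + 500,  # empty interval: end <= start
                "InteractorAEnd": tss - 500,
                "InteractorBChr": chrom,
                "InteractorBStart": 1_000_001,
                "InteractorBEnd": 1_002_000,
                "Agg_Gene_A": gene,
                "Agg_Gene_B": "",
                "Detection_Method": "Hi-C",
                "Cell_Tissue": "synthetic",
            }
        )

    interaction_frame = pd.DataFrame(interaction_rows)
    anchor_frame = pd.DataFrame(anchor_rows)
    return (
        interaction_frame,
        anchor_frame,
        InteractionTruth(
            distances=truth, n_trans_injected=n_trans, n_malformed_injected=n_malformed
        ),
    )


def write_bed(anchor_frame: pd.DataFrame, path: str | Path) -> None:
    anchor_frame.to_csv(path, sep="\t", header=False, index=False)


def write_probe_table(probe_frame: pd.DataFrame, path: str | Path) -> None:
    probe_frame.to_csv(path, sep="\t", index=False)
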