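"""Full-study orchestration: QC -> DEG calling -> profiling -> enrichment ->
mechanism concordance/ranking -> ROS classification -> CLRI analysis.

The run configuration is a YAML file naming input paths and thresholds; the
output is a versioned JSON report plus per-stage TSVs.  Report contents are
a pure function of inputs and configuration (no timestamps inside the
report), so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from innatome_miner import __version__
from innatome_miner.catalog import GeneCatalog, load_catalog, read_gmt
from innatome_miner.clri import distance_set, ks_compare, load_anchors, load_interactions
from innatome_miner.degcall import (
    DEFAULT_THRESHOLD,
    Contrast,
    call_degs,
    housekeeping_qc,
    load_contrast,
)
from innatome_miner.enrich import hypergeom_enrich
from innatome_miner.mechanism import concordance_matrix, matrix_frame, rank_mechanisms
from innatome_miner.profile import ModulatedSet, compare_composition, panel_scan
from innatome_miner.resources import build_innatome_catalog, housekeeping_catalog
from innatome_miner.rosclass import classify_set

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}/{code}] {message}")


@dataclass
class RunConfig:
    """Validated paths and thresholds for one pipeline run."""

    contrasts: list[dict[str, str]]  # each: {path, dataset_id?, species?}
    outdir: str
    catalog: str | None = None  # catalog TSV; default: built-in composition catalog
    panels: dict[str, str] = field(default_factory=dict)  # name -> catalog TSV
    gmt: str | None = None
    perturbations: list[dict[str, str]] = field(default_factory=list)
    # each: {path, dataset_id?, mechanism, ko_type?}
    interactions: str | None = None
    anchors: str | None = None
    threshold: float = DEFAULT_THRESHOLD
    qc_threshold: float = DEFAULT_THRESHOLD
    override_qc: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
        config = cls(**raw)
        config.validate()
        return config

    def validate(self) -> None:
        if self.threshold <= 1 or self.qc_threshold <= 1:
            raise ValueError("thresholds must be > 1")
        if not self.contrasts:
            raise ValueError("at least one contrast is required")
        for entry in self.contrasts + self.perturbations:
            if not Path(entry["path"]).exists():
                raise FileNotFoundError(entry["path"])
        for path in (self.catalog, self.gmt, self.interactions, self.anchors):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)
        for path in self.panels.values():
            if not Path(path).exists():
                raise FileNotFoundError(path)


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_listed_contrast(entry: dict[str, str]) -> Contrast:
    return load_contrast(
        entry["path"],
        dataset_id=entry.get("dataset_id"),
        species=entry.get("species", "agnostic"),
    )


def run(config: RunConfig) -> dict[str, Any]:
    """Execute every configured stage and write the report bundle.

    Stages with missing optional inputs are recorded as "skipped"; a stage
    failure aborts the run with a :class:`StageError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "threshold": config.threshold,
        "stages": {},
    }

    checksums = {}
    for entry in config.contrasts + config.perturbations:
        checksums[entry["path"]] = _checksum(entry["path"])
    report["input_checksums"] = checksums

    # --- catalog ----------------------------------------------------------
    try:
        if config.catalog:
            catalog = load_catalog(config.catalog, name="innatome")
        else:
            catalog = build_innatome_catalog()
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise StageError("catalog", "load-failed", str(exc)) from exc

    # --- QC + DEG calling -------------------------------------------------
    hk = housekeeping_catalog()
    contrasts: dict[str, Contrast] = {}
    degs: dict[str, Any] = {}
    references: list[ModulatedSet] = []
    stage: dict[str, Any] = {}
    for entry in config.contrasts:
        try:
            contrast = _load_listed_contrast(entry)
            contrast.qc = housekeeping_qc(contrast, hk, config.qc_threshold)
            result = call_degs(
                contrast, catalog, config.threshold, override_qc=config.override_qc
            )
        except Exception as exc:
            raise StageError("degcall", "call-failed", f"{entry['path']}: {exc}") from exc
        contrasts[contrast.dataset_id] = contrast
        degs[contrast.dataset_id] = result
        for direction, genes in (("up", result.up), ("down", result.down)):
            references.append(
                ModulatedSet(
                    dataset_id=contrast.dataset_id,
                    direction=direction,
                    genes=genes,
                    catalog_total=len(catalog.genes),
                )
            )
        stage[contrast.dataset_id] = {
            "qc_pass": contrast.qc.passed,
            "qc_max_abs_fc": contrast.qc.max_abs_fc,
            "n_up": len(result.up),
            "n_down": len(result.down),
            "pct_up": ModulatedSet(
                contrast.dataset_id, "up", result.up, len(catalog.genes)
            ).percent,
            "pct_down": ModulatedSet(
                contrast.dataset_id, "down", result.down, len(catalog.genes)
            ).percent,
            "up": sorted(result.up),
            "down": sorted(result.down),
            "ambiguous": sorted(result.ambiguous),
        }
    report["stages"]["degcall"] = stage

    # --- composition profiling -------------------------------------------
    annotated = bool(catalog.annotations)
    if annotated:
        stage = {}
        for dataset_id, result in degs.items():
            entry_out: dict[str, Any] = {}
            for direction, genes in (("up", result.up), ("down", result.down)):
                if not genes:
                    entry_out[direction] = None
                    continue
                per_scheme = {}
                for scheme in ("location", "function"):
                    comparison = compare_composition(genes, catalog, scheme)
                    per_scheme[scheme] = [vars(r) for r in comparison.rows]
                entry_out[direction] = per_scheme
            stage[dataset_id] = entry_out
        report["stages"]["profile"] = stage
    else:
        report["stages"]["profile"] = {"status": "skipped", "reason": "catalog unannotated"}

    # --- panel scans ------------------------------------------------------
    if config.panels:
        stage = {}
        for name, path in config.panels.items():
            panel = load_catalog(path, name=name)
            scan = panel_scan(list(contrasts.values()), panel, config.threshold)
            stage[name] = {
                "panel_size": scan.panel_size,
                "n_up": scan.n_up,
                "n_down": scan.n_down,
                "pct_up": scan.percent_up(),
                "pct_down": scan.percent_down(),
                "ratio_down_over_up": scan.ratio_down_over_up,
                "ratio_up_over_down": scan.ratio_up_over_down,
            }
        report["stages"]["panels"] = stage
    else:
        report["stages"]["panels"] = {"status": "skipped", "reason": "no panels configured"}

    # --- enrichment -------------------------------------------------------
    if config.gmt:
        collection = read_gmt(config.gmt)
        stage = {}
        for dataset_id, result in degs.items():
            per_direction = {}
            for direction, genes in (("up", result.up), ("down", result.down)):
                if not genes:
                    per_direction[direction] = []
                    continue
                rows = hypergeom_enrich(genes, collection, catalog.genes)
                per_direction[direction] = [vars(r) for r in rows]
            stage[dataset_id] = per_direction
        report["stages"]["enrich"] = stage
    else:
        report["stages"]["enrich"] = {"status": "skipped", "reason": "no GMT configured"}

    # --- mechanism concordance + ranking ---------------------------------
    if config.perturbations:
        try:
            pert_contrasts = [_load_listed_contrast(e) for e in config.perturbations]
            grouping = {
                c.dataset_id: e["mechanism"]
                for c, e in zip(pert_contrasts, config.perturbations)
            }
            nonempty = [r for r in references if r.genes]
            cells = concordance_matrix(nonempty, pert_contrasts, config.threshold)
            ranking = rank_mechanisms(cells, grouping)
        except Exception as exc:
            raise StageError("mechanism", "concordance-failed", str(exc)) from exc
        matrix_frame(cells).to_csv(outdir / "concordance_matrix.tsv", sep="\t", index=False)
        report["stages"]["mechanism"] = {
            "ranking": ranking.order,
            "related_pct": ranking.fractions,
        }

        # ROS classification from KO-typed perturbations
        nox2 = [
            c
            for c, e in zip(pert_contrasts, config.perturbations)
            if e.get("ko_type") == "NOX2"
        ]
        nrf2 = [
            c
            for c, e in zip(pert_contrasts, config.perturbations)
            if e.get("ko_type") == "Nrf2"
        ]
        if nox2 or nrf2:
            stage = {}
            for ref in nonempty:
                classification = classify_set(
                    ref.genes, nox2, nrf2, threshold=config.threshold
                )
                stage[f"{ref.dataset_id}:{ref.direction}"] = {
                    "counts": classification.counts,
                    "percents": classification.percents,
                    "ros_related_pct": classification.ros_related_pct,
                }
            report["stages"]["rosclass"] = stage
        else:
            report["stages"]["rosclass"] = {
                "status": "skipped",
                "reason": "no KO-typed perturbations",
            }
    else:
        report["stages"]["mechanism"] = {
            "status": "skipped",
            "reason": "no perturbations configured",
        }
        report["stages"]["rosclass"] = {
            "status": "skipped",
            "reason": "no perturbations configured",
        }

    # --- CLRI -------------------------------------------------------------
    if config.interactions and config.anchors:
        try:
            records, n_skipped = load_interactions(config.interactions)
            anchors = load_anchors(config.anchors)
            sets = {}
            for ref in references:
                if not ref.genes:
                    continue
                label = f"{ref.dataset_id}:{ref.direction}"
                dist, coverage = distance_set(records, ref.genes, anchors, label=label)
                sets[label] = (dist, coverage)
            stage = {"n_malformed_skipped": n_skipped, "sets": {}, "ks": {}}
            for label, (dist, coverage) in sets.items():
                stage["sets"][label] = {
                    "n_distances": len(dist.distances),
                    "n_trans": coverage.n_trans,
                    "missing_genes": list(coverage.missing_genes),
                }
            for dataset_id in contrasts:
                a = sets.get(f"{dataset_id}:up")
                b = sets.get(f"{dataset_id}:down")
                if a and b and a[0].distances and b[0].distances:
                    d_stat, p = ks_compare(a[0], b[0])
                    stage["ks"][dataset_id] = {"D": d_stat, "p": p}
            report["stages"]["clri"] = stage
        except Exception as exc:
            raise StageError("clri", "analysis-failed", str(exc)) from exc
    else:
        report["stages"]["clri"] = {
            "status": "skipped",
            "reason": "interaction or anchor file not configured",
        }

    with open(outdir / "report.json", "w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
    return report
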