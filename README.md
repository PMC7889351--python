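# innatome-miner

A tested pipeline for comparative profiling of innate-immunity gene
expression across treatment-vs-control microarray contrasts:

- **DEG calling** purely by signed fold change (magnitude ≥ 1, negative =
  down-regulation; default cutoff 1.5, boundary inclusive) with a
  four-gene housekeeping QC gate (CHMP2A, PSMB4, ACTB, GAPDH).
- **Catalog profiling**: composition of called gene sets over 5
  subcellular-location and 14 functional-type categories, per-category
  Fisher exact comparison against the catalog background, Venn region
  partitions, and targeted panel scans (trained-immunity, heat-shock,
  oxidative/antioxidative panels).
- **Enrichment**: hypergeometric over-representation against GMT pathway
  collections within a configurable universe.
- **Mechanism attribution**: cross-dataset directional concordance of
  reference DEG sets in perturbation contrasts (shear stress, mild
  hyperthermia, cytokine KO/treatment, checkpoint-receptor
  overexpression), with mechanisms ranked by the pooled fraction of
  reference genes responsive in ≥ 1 of their datasets.
- **ROS-dependency classification**: a rule-based four-group classifier
  (promoted / suppressed / uncertain / independent) driven by response
  directions in NOX2-KO and Nrf2-KO contrasts.
- **CLRI analysis**: signed TSS-to-partner distances from 4DGenome-style
  chromatin interaction tables (negative = upstream in gene orientation),
  compared between gene sets with the two-sample Kolmogorov–Smirnov test.
- **Synthetic data**: seeded generators for every input class with
  exported ground truth, used throughout the test suite.

## CLI

```sh
innatome-miner synth --seed 1 --out bundle/            # synthetic study bundle + truth.json
innatome-miner degs --contrast bundle/contrast.tsv --out degs.json
innatome-miner enrich --query genes.txt --gmt pathways.gmt --out enrich.tsv
innatome-miner mechanisms --manifest suite.yaml --out matrix.tsv
innatome-miner rosclass --genes genes.txt --nox2 nox2.tsv --nrf2 nrf2.tsv --out ros.tsv
innatome-miner clri --interactions int.tsv --anchors anchors.bed \
    --up-genes up.txt --down-genes down.txt --out distances.tsv
innatome-miner run --config run.yaml                   # full pipeline -> report.json
```

Contrast TSVs carry `feature_id`, `symbol`, `treat_mean`, `control_mean`
(linear scale; `--log2` converts) or a precomputed `signed_fc`.  Gene
catalogs are TSVs with a `symbol` column plus optional `location_class`,
`function_class`, `pathway`, `family` annotations.  Interaction tables use
4DGenome-style columns (1-based inclusive, converted internally to 0-based
half-open); gene anchors are BED6 with the TSS taken strand-aware.

## Notes on conventions

- Percent rendering is round-half-up: 2 decimals in composition tables,
  1 decimal in headline fractions.
- Cross-species gene matching is by canonical uppercase symbol only (no
  ortholog mapping) — a documented limitation.
- The default reference catalog (`innatome_miner.resources`) rebuilds the
  1376-gene InnateDB-derived composition with placeholder symbols; supply
  your own annotated catalog TSV to work with real symbols.
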