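import numpy as np
import pandas as pd
import pytest

from innatome_miner.clri import (
    GeneAnchor,
    InteractionRecord,
    Locus,
    SignedDistanceSet,
    distance_set,
    ks_compare,
    load_anchors,
    load_interactions,
    signed_distance,
    write_interactions,
)
from innatome_miner.synth import OffsetSpec, gen_interactions, write_bed


def make_record(chrom_a, a0, a1, chrom_b, b0, b1, genes_a=(), genes_b=()):
    """Record from 0-based half-open coordinates."""
    return InteractionRecord(
        interactor_a=Locus(chrom_a, a0, a1),
        interactor_b=Locus(chrom_b, b0, b1),
        genes_a=frozenset(genes_a),
        genes_b=frozenset(genes_b),
    )


def ks_d_oracle(xs, ys):
    """Brute-force ECDF sweep over all pooled points."""
    xs, ys = np.sort(xs), np.sort(ys)
    best = 0.0
    for point in np.concatenate([xs, ys]):
        fa = np.searchsorted(xs, point, side="right") / len(xs)
        fb = np.searchsorted(ys, point, side="right") / len(ys)
        best = max(best, abs(fa - fb))
    return best


class TestLoadInteractions:
    def write(self, tmp_path, body):
        header = (
            "InteractorAChr\tInteractorAStart\tInteractorAEnd\t"
            "InteractorBChr\tInteractorBStart\tInteractorBEnd\t"
            "Agg_Gene_A\tAgg_Gene_B\tDetection_Method\tCell_Tissue\n"
        )
        path = tmp_path / "int.tsv"
        path.write_text(header + body)
        return path

    def test_coordinate_conversion(self, tmp_path):
        path = self.write(
            tmp_path,
            "chr1\t101\t200\tchr1\t501\t600\tGENEA\t\tHi-C\tcell\n"
            "chr2\t11\t20\tchr2\t31\t40\tGENEB\tGENEC\t4C\tcell\n"
            "chr3\t1\t5\tchr4\t1\t5\t\t\tHi-C\tcell\n",
        )
        records, n_skipped = load_interactions(path)
        assert n_skipped == 0
        assert len(records) == 3
        # 1-based inclusive [101,200] -> 0-based half-open [100,200)
        assert records[0].interactor_a.start == 100
        assert records[0].interactor_a.end == 200
        assert records[1].genes_b == {"GENEC"}
        assert not records[2].is_cis

    def test_malformed_rows_skipped_and_counted(self, tmp_path):
        path = self.write(
            tmp_path,
            "chr1\t101\t200\tchr1\t501\t600\tG1\t\tHi-C\tc\n"
            "chr1\t200\t100\tchr1\t501\t600\tG1\t\tHi-C\tc\n"  # end <= start
            "chr1\tfoo\t200\tchr1\t501\t600\tG1\t\tHi-C\tc\n",  # non-numeric
        )
        records, n_skipped = load_interactions(path)
        assert len(records) == 1
        assert n_skipped == 2

    def test_missing_column_is_hard_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("InteractorAChr\tInteractorAStart\nchr1\t100\n")
        with pytest.raises(ValueError, match="missing required column"):
            load_interactions(path)

    def test_round_trip(self, tmp_path):
        path = self.write(
            tmp_path, "chr1\t101\t200\tchr1\t501\t600\tGENEA\tGENEB\tHi-C\tcell\n"
        )
        records, _ = load_interactions(path)
        out = tmp_path / "out.tsv"
        write_interactions(records, out)
        reloaded, _ = load_interactions(out)
        assert reloaded == records


class TestSignedDistance:
    def test_upstream_partner_negative(self):
        anchor = GeneAnchor("G", "chr1", 1000, "+")
        record = make_record("chr1", 900, 1100, "chr1", 300, 500, genes_a=("G",))
        assert signed_distance(record, anchor, "B") == -600

    def test_downstream_partner_positive(self):
        anchor = GeneAnchor("G", "chr1", 1000, "+")
        record = make_record("chr1", 900, 1100, "chr1", 4000, 6000, genes_a=("G",))
        assert signed_distance(record, anchor, "B") == 4000

    def test_minus_strand_negates(self):
        anchor = GeneAnchor("G", "chr1", 1000, "-")
        record = make_record("chr1", 900, 1100, "chr1", 300, 500, genes_a=("G",))
        assert signed_distance(record, anchor, "B") == 600

    def test_strand_agnostic_mode(self):
        anchor = GeneAnchor("G", "chr1", 1000, "-")
        record = make_record("chr1", 900, 1100, "chr1", 300, 500, genes_a=("G",))
        assert signed_distance(record, anchor, "B", strand_aware=False) == -600

    def test_flip_sign_covers_other_convention(self):
        anchor = GeneAnchor("G", "chr1", 1000, "+")
        record = make_record("chr1", 900, 1100, "chr1", 300, 500, genes_a=("G",))
        assert signed_distance(record, anchor, "B", flip_sign=True) == 600

    def test_trans_partner_is_error(self):
        anchor = GeneAnchor("G", "chr2", 1000, "+")
        record = make_record("chr1", 900, 1100, "chr1", 300, 500)
        with pytest.raises(ValueError, match="trans"):
            signed_distance(record, anchor, "B")


class TestDistanceSet:
    def test_two_cis_records_two_distances(self):
        anchors = {"G": GeneAnchor("G", "chr1", 1000, "+")}
        records = [
            make_record("chr1", 900, 1100, "chr1", 300, 500, genes_a=("G",)),
            make_record("chr1", 900, 1100, "chr1", 4000, 6000, genes_a=("G",)),
        ]
        dist, report = distance_set(records, {"G"}, anchors)
        assert sorted(dist.distances) == [-600, 4000]
        assert report.n_trans == 0

    def test_both_interactors_named_partner_is_non_tss_side(self):
        anchors = {"G": GeneAnchor("G", "chr1", 1000, "+")}
        record = make_record(
            "chr1", 900, 1100, "chr1", 4000, 6000, genes_a=("G",), genes_b=("G",)
        )
        dist, _ = distance_set([record], {"G"}, anchors)
        assert dist.distances == [4000]

    def test_both_interactors_contain_tss_dropped(self):
        anchors = {"G": GeneAnchor("G", "chr1", 1000, "+")}
        record = make_record(
            "chr1", 900, 1100, "chr1", 950, 1050, genes_a=("G",), genes_b=("G",)
        )
        dist, report = distance_set([record], {"G"}, anchors)
        assert dist.distances == []
        assert report.n_dropped_ambiguous == 1

    def test_trans_records_excluded_and_counted(self):
        anchors = {"G": GeneAnchor("G", "chr1", 1000, "+")}
        records = [make_record("chr1", 900, 1100, "chr2", 300, 500, genes_a=("G",))]
        dist, report = distance_set(records, {"G"}, anchors)
        assert dist.distances == []
        assert report.n_trans == 1

    def test_missing_anchor_reported_not_fatal(self):
        dist, report = distance_set([], {"NOANCHOR"}, {})
        assert report.missing_genes == ("NOANCHOR",)
        assert dist.distances == []

    def test_planted_offsets_recovered_exactly(self):
        gene_sets = {"up": [f"U{i}" for i in range(5)], "down": [f"D{i}" for i in range(5)]}
        offsets = {
            "up": OffsetSpec(location=50_000, scale=10_000, sign_bias=1.0),
            "down": OffsetSpec(location=50_000, scale=10_000, sign_bias=-1.0),
        }
        frame, anchors_frame, truth = gen_interactions(gene_sets, offsets, n_per_set=20, seed=4)
        import tempfile, pathlib

        with tempfile.TemporaryDirectory() as tmp:
            tmp = pathlib.Path(tmp)
            frame.to_csv(tmp / "int.tsv", sep="\t", index=False)
            write_bed(anchors_frame, tmp / "anchors.bed")
            records, _ = load_interactions(tmp / "int.tsv")
            anchors = load_anchors(tmp / "anchors.bed")
        for label in gene_sets:
            dist, _ = distance_set(records, gene_sets[label], anchors, label=label)
            assert sorted(dist.distances) == sorted(truth.distances[label])

    def test_reflection_negates_distances_and_keeps_d(self):
        rng = np.random.default_rng(17)
        a = rng.integers(-10**6, 10**6, size=40).tolist()
        b = rng.integers(-10**6, 10**6, size=35).tolist()
        d1, _ = ks_compare(a, b)
        d2, _ = ks_compare([-x for x in a], [-x for x in b])
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestLoadAnchors:
    def test_tss_strand_rules(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr1\t100\t200\tGPLUS\t0\t+\nchr1\t100\t200\tGMINUS\t0\t-\n")
        anchors = load_anchors(path)
        assert anchors["GPLUS"].tss == 100
        assert anchors["GMINUS"].tss == 199

    def test_short_line_is_error(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr1\t100\t200\tG\n")
        with pytest.raises(ValueError):
            load_anchors(path)


class TestKsCompare:
    def test_identical_samples_d_zero(self):
        xs = list(range(10))
        d, p = ks_compare(xs, list(xs))
        assert d == 0.0

    def test_disjoint_supports_d_one(self):
        d, p = ks_compare(list(range(1, 11)), list(range(101, 111)))
        assert d == pytest.approx(1.0)
        assert p < 1e-4

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])

    def test_matches_ecdf_sweep_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n, m = rng.integers(2, 51), rng.integers(2, 51)
            xs = rng.normal(0, 1, size=n)
            ys = rng.normal(rng.uniform(-1, 1), 1, size=m)
            d, _ = ks_compare(xs.tolist(), ys.tolist())
            assert d == pytest.approx(ks_d_oracle(xs, ys), abs=1e-12)

    def test_ecdf_export_monotone(self):
        rng = np.random.default_rng(32)
        dist = SignedDistanceSet("x", rng.integers(-100, 100, size=50).tolist())
        xs, ys = dist.ecdf()
        assert np.all(np.diff(xs) >= 0)
        assert np.all(np.diff(ys) > 0) or len(set(ys)) == len(ys)
        assert ys[0] > 0 and ys[-1] == pytest.approx(1.0)
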