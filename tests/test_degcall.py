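import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import contrast_from_fc, contrast_from_means
from innatome_miner.catalog import GeneCatalog
from innatome_miner.degcall import (
    QcError,
    call_degs,
    collapse_probes,
    housekeeping_qc,
    load_contrast,
    signed_fold_change,
    write_contrast,
)
from innatome_miner.synth import ExpressionConfig, gen_expression

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "treat,control,expected",
        [(3.0, 2.0, 1.5), (2.0, 3.0, -1.5), (5.0, 5.0, 1.0)],
    )
    def test_examples(self, treat, control, expected):
        assert signed_fold_change(treat, control) == pytest.approx(expected)

    @pytest.mark.parametrize("treat,control", [(0.0, 1.0), (1.0, 0.0), (-1.0, 2.0)])
    def test_nonpositive_rejected(self, treat, control):
        with pytest.raises(ValueError):
            signed_fold_change(treat, control)

    @given(positive, positive)
    def test_antisymmetry_and_magnitude(self, treat, control):
        fc = signed_fold_change(treat, control)
        swapped = signed_fold_change(control, treat)
        assert abs(fc) >= 1.0
        if treat != control:
            assert fc == pytest.approx(-swapped)


class TestCollapseProbes:
    def test_max_magnitude_wins(self):
        frame = pd.DataFrame(
            {"feature_id": ["p1", "p2"], "symbol": ["A", "A"], "signed_fc": [1.4, 1.8]}
        )
        collapsed, ambiguous, dropped = collapse_probes(frame)
        assert collapsed.loc[collapsed.symbol == "A", "signed_fc"].iloc[0] == 1.8
        assert not ambiguous and dropped == 0

    def test_opposite_sign_tie_is_ambiguous(self):
        frame = pd.DataFrame(
            {"feature_id": ["p1", "p2"], "symbol": ["A", "A"], "signed_fc": [1.6, -1.6]}
        )
        _, ambiguous, _ = collapse_probes(frame)
        assert ambiguous == {"A"}

    def test_symbolless_rows_dropped_and_counted(self):
        frame = pd.DataFrame(
            {"feature_id": ["p1", "p2"], "symbol": ["A", ""], "signed_fc": [1.2, 2.0]}
        )
        collapsed, _, dropped = collapse_probes(frame)
        assert dropped == 1
        assert list(collapsed["symbol"]) == ["A"]

    def test_matches_bruteforce_groupby_oracle(self):
        rng = np.random.default_rng(7)
        symbols = rng.choice([f"G{i}" for i in range(30)], size=200)
        sign = rng.choice([-1.0, 1.0], size=200)
        fc = sign * rng.uniform(1.0, 4.0, size=200)
        frame = pd.DataFrame(
            {"feature_id": [f"p{i}" for i in range(200)], "symbol": symbols, "signed_fc": fc}
        )
        collapsed, ambiguous, _ = collapse_probes(frame)
        # oracle: exhaustive per-gene scan
        for symbol in set(symbols):
            values = fc[symbols == symbol]
            best = max(abs(v) for v in values)
            winners = {v for v in values if abs(v) == best}
            got = collapsed.loc[collapsed.symbol == symbol, "signed_fc"].iloc[0]
            if len({v > 0 for v in winners}) == 2:
                assert symbol in ambiguous
            else:
                assert got in winners
                assert symbol not in ambiguous


class TestHousekeepingQc:
    def test_reference_values_pass(self, housekeeping):
        # per-gene ratios all inside the threshold band
        contrast = contrast_from_fc(
            {"CHMP2A": 1.160, "PSMB4": 1.087, "ACTB": 1.128, "GAPDH": 1.284, "X": 3.0}
        )
        report = housekeeping_qc(contrast, housekeeping)
        assert report.passed
        assert report.max_abs_fc == pytest.approx(1.284)

    def test_breach_fails(self, housekeeping):
        contrast = contrast_from_fc(
            {"CHMP2A": -1.6, "PSMB4": 1.0, "ACTB": 1.0, "GAPDH": 1.0}
        )
        assert not housekeeping_qc(contrast, housekeeping).passed

    def test_missing_gene_fails_without_raising(self, housekeeping):
        contrast = contrast_from_fc({"CHMP2A": 1.0, "PSMB4": 1.0, "ACTB": 1.0})
        report = housekeeping_qc(contrast, housekeeping)
        assert not report.passed
        assert report.missing == ("GAPDH",)

    def test_boundary_is_exclusive(self, housekeeping):
        contrast = contrast_from_fc(
            {"CHMP2A": 1.5, "PSMB4": 1.0, "ACTB": 1.0, "GAPDH": 1.0}
        )
        assert not housekeeping_qc(contrast, housekeeping, qc_threshold=1.5).passed

    def test_synthetic_generator_always_passes(self):
        contrast, _, _ = gen_expression(ExpressionConfig(seed=11, n_genes=50, n_up=5, n_down=5))
        assert contrast.qc is not None and contrast.qc.passed


class TestCallDegs:
    def make_catalog(self, genes):
        return GeneCatalog(name="c", species="agnostic", genes=set(genes))

    def test_boundary_inclusive(self):
        contrast = contrast_from_fc({"A": 1.5, "B": -1.5, "C": 1.49, "D": -1.49})
        result = call_degs(contrast, self.make_catalog("ABCD"))
        assert result.up == {"A"}
        assert result.down == {"B"}

    def test_all_below_threshold_empty(self):
        contrast = contrast_from_fc({f"G{i}": 1.49 for i in range(10)})
        result = call_degs(contrast, self.make_catalog([f"G{i}" for i in range(10)]))
        assert not result.up and not result.down

    def test_matches_direct_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(100)]
        fc = {g: float(rng.choice([-1, 1]) * rng.uniform(1.0, 3.0)) for g in genes}
        contrast = contrast_from_fc(fc)
        result = call_degs(contrast, self.make_catalog(genes), threshold=1.5)
        assert result.up == {g for g, v in fc.items() if v >= 1.5}
        assert result.down == {g for g, v in fc.items() if v <= -1.5}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        fc = {f"G{i}": float(rng.choice([-1, 1]) * rng.uniform(1.0, 3.0)) for i in range(200)}
        contrast = contrast_from_fc(fc)
        catalog = self.make_catalog(fc)
        previous = call_degs(contrast, catalog, threshold=1.2)
        for threshold in (1.5, 1.8, 2.4):
            current = call_degs(contrast, catalog, threshold=threshold)
            assert current.up <= previous.up
            assert current.down <= previous.down
            previous = current

    def test_swap_antisymmetry(self):
        rows = [(f"G{i}", float(2 + i), float(3 + (i % 5))) for i in range(40)]
        contrast = contrast_from_means(rows)
        catalog = self.make_catalog([r[0] for r in rows])
        forward = call_degs(contrast, catalog)
        backward = call_degs(contrast.inverted(), catalog)
        assert forward.up == backward.down
        assert forward.down == backward.up

    def test_ambiguous_genes_excluded(self):
        frame = pd.DataFrame(
            {"feature_id": ["p1", "p2"], "symbol": ["A", "A"], "signed_fc": [2.0, -2.0]}
        )
        collapsed, ambiguous, _ = collapse_probes(frame)
        from innatome_miner.degcall import Contrast

        contrast = Contrast("t", "agnostic", collapsed, ambiguous=frozenset(ambiguous))
        result = call_degs(contrast, self.make_catalog("A"))
        assert not result.up and not result.down
        assert result.ambiguous == {"A"}

    def test_qc_gate(self, housekeeping):
        contrast = contrast_from_fc(
            {"CHMP2A": -1.6, "PSMB4": 1.0, "ACTB": 1.0, "GAPDH": 1.0, "A": 2.0}
        )
        contrast.qc = housekeeping_qc(contrast, housekeeping)
        with pytest.raises(QcError):
            call_degs(contrast, self.make_catalog("A"))
        result = call_degs(contrast, self.make_catalog("A"), override_qc=True)
        assert result.up == {"A"}


class TestLoadContrast:
    def test_load_and_roundtrip(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text(
            "feature_id\tsymbol\ttreat_mean\tcontrol_mean\n"
            "p1\tA\t3.0\t2.0\n"
            "p2\tB\t2.0\t3.0\n"
        )
        contrast = load_contrast(path)
        fc = contrast.fc_by_symbol()
        assert fc["A"] == pytest.approx(1.5)
        assert fc["B"] == pytest.approx(-1.5)
        out = tmp_path / "out.tsv"
        write_contrast(contrast, out)
        reloaded = load_contrast(out, precomputed_fc=True)
        assert reloaded.fc_by_symbol() == pytest.approx(fc)

    def test_log2_conversion(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("feature_id\tsymbol\ttreat_mean\tcontrol_mean\np1\tA\t3.0\t2.0\n")
        contrast = load_contrast(path, log2=True)
        assert contrast.fc_by_symbol()["A"] == pytest.approx(2.0)

    def test_missing_column_is_error(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("feature_id\tsymbol\ttreat_mean\np1\tA\t3.0\n")
        with pytest.raises(ValueError, match="control_mean"):
            load_contrast(path)
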