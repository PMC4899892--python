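"""Region log-ratio calling, gene mapping and expression-concordance rescue."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxevo.cna_expression import (
    CnaGeneCall,
    CnaSegmentCall,
    call_cna,
    call_cna_from_table,
    expression_concordance,
    map_to_genes,
    region_log_ratios,
)
from taxevo.errors import EstimationError, ValidationError
from taxevo.stage_io import ExpressionRecord, GeneModel


def region_frame(n, chrom="1", length=1000):
    return pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "start": [i * length + 1 for i in range(n)],
            "end": [(i + 1) * length for i in range(n)],
        }
    )


class TestLogRatios:
    def test_equal_counts_give_zero(self):
        c = np.array([100, 200, 300, 50])
        assert np.allclose(region_log_ratios(c, c), 0.0)

    def test_doubled_region_is_plus_one(self):
        rng = np.random.default_rng(0)
        ref = rng.poisson(1000, size=200)
        test = ref.copy()
        test[7] = 2 * ref[7]
        ratios = region_log_ratios(test, ref)
        assert abs(ratios[7] - 1.0) < 0.05

    @given(log2_scale=st.integers(-6, 6))
    @settings(max_examples=20, deadline=None)
    def test_library_size_invariance_bit_exact_for_power_of_two(self, log2_scale):
        scale = 2.0 ** log2_scale
        rng = np.random.default_rng(1)
        ref = rng.poisson(100, size=50) + 1
        test = rng.poisson(100, size=50) + 1
        base = region_log_ratios(test, ref)
        assert np.array_equal(base, region_log_ratios(test * scale, ref))
        assert np.array_equal(base, region_log_ratios(test, ref * scale))

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_library_size_invariance_arbitrary_scale(self, scale):
        rng = np.random.default_rng(1)
        ref = rng.poisson(100, size=50) + 1
        test = rng.poisson(100, size=50) + 1
        base = region_log_ratios(test, ref)
        assert np.allclose(base, region_log_ratios(test * scale, ref), atol=1e-12)
        assert np.allclose(base, region_log_ratios(test, ref * scale), atol=1e-12)

    def test_swap_negates_ratios(self):
        rng = np.random.default_rng(2)
        ref = rng.poisson(100, size=50) + 1
        test = rng.poisson(100, size=50) + 1
        assert np.allclose(
            region_log_ratios(test, ref), -region_log_ratios(ref, test), atol=1e-12
        )

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            region_log_ratios([0, 0], [1, 2])


class TestCallCna:
    def test_identical_ratios_yield_no_calls(self):
        regions = region_frame(30)
        calls = call_cna(np.zeros(30), regions, "S1", "S0")
        assert all(c.direction == "neutral" for c in calls)

    def test_alpha_zero_yields_no_calls(self):
        rng = np.random.default_rng(3)
        ratios = rng.normal(0, 0.05, size=100)
        ratios[:5] += 1.0
        calls = call_cna(ratios, region_frame(100), "S1", "S0", alpha=0.0)
        assert all(c.direction == "neutral" for c in calls)

    def test_planted_outliers_called_at_q_005(self):
        rng = np.random.default_rng(4)
        ratios = rng.normal(0, 0.05, size=205)
        ratios[200:] = 1.0
        calls = call_cna(ratios, region_frame(205), "S1", "S0", alpha=0.05)
        assert all(c.direction == "gain" for c in calls[200:])
        false = [c for c in calls[:200] if c.direction != "neutral"]
        assert len(false) <= 2

    def test_too_few_regions_rejected(self):
        with pytest.raises(EstimationError):
            call_cna(np.zeros(5), region_frame(5), "S1", "S0")

    def test_planted_cna_recovery_on_synthetic_counts(self, default_output):
        """Sensitivity >= 90% and false-call rate <= 2*alpha on the default
        synthetic series (|log2| = 1, ~100 reads/region, 200 regions)."""
        table = default_output.region_counts
        series = default_output.series
        truth = default_output.truth.regions
        final = series.labels[-1]
        calls = call_cna_from_table(table, final, series.labels[0], alpha=0.05)
        called = {i for i, c in enumerate(calls) if c.direction != "neutral"}
        planted = set(truth["region_index"])
        sensitivity = len(called & planted) / len(planted)
        false_rate = len(called - planted) / (len(calls) - len(planted))
        assert sensitivity >= 0.90
        assert false_rate <= 0.10
        for i, c in enumerate(calls):
            if i in planted and c.direction != "neutral":
                want = truth.set_index("region_index").loc[i, "direction"]
                assert c.direction == want


def seg(chrom, start, end, direction="gain", stage="S1"):
    lr = 1.0 if direction == "gain" else -1.0
    return CnaSegmentCall(
        stage_label=stage, reference_label="S0", chrom=chrom, start=start, end=end,
        log2_ratio=lr, p_value=0.001, q_value=0.01, direction=direction,
    )


class TestGeneMapping:
    def test_overlap_and_adjacency(self):
        genes = [
            GeneModel("GA", "GA", "1", 150, 400, "+"),
            GeneModel("GB", "GB", "1", 201, 400, "+"),
        ]
        assert [c.gene_id for c in map_to_genes([seg("1", 100, 200)], genes)] == ["GA"]

    def test_segment_spanning_two_genes_reports_both(self):
        genes = [
            GeneModel("GA", "GA", "1", 50, 120, "+"),
            GeneModel("GB", "GB", "1", 121, 300, "+"),
        ]
        assert [c.gene_id for c in map_to_genes([seg("1", 100, 200)], genes)] == ["GA", "GB"]

    def test_agrees_with_brute_force_on_random_intervals(self):
        rng = np.random.default_rng(9)
        genes = [
            GeneModel(f"G{i}", f"G{i}", str(rng.integers(1, 4)),
                      int(s := rng.integers(1, 100_000)), int(s + rng.integers(1, 5000)), "+")
            for i in range(1000)
        ]
        segments = [
            seg(str(rng.integers(1, 4)), int(s := rng.integers(1, 100_000)),
                int(s + rng.integers(1, 5000)))
            for _ in range(1000)
        ]
        mapped = map_to_genes(segments, genes)
        got = sorted((c.stage_label, c.gene_id) for c in mapped)
        expected = []
        for sg in segments:
            for g in genes:
                if g.chrom == sg.chrom and sg.start <= g.end and g.start <= sg.end:
                    expected.append((sg.stage_label, g.gene_id))
        assert got == sorted(expected)


class TestConcordance:
    def make_call(self, direction, stage="S2"):
        return CnaGeneCall(gene_id="ABCB1", stage_label=stage, direction=direction, log2_ratio=1.0)

    def test_gain_with_upregulation_is_persistent(self):
        (call,) = expression_concordance(
            [self.make_call("gain")],
            [ExpressionRecord("ABCB1", log2fc=2.0, significant=True)],
            final_calls=[],
        )
        assert call.concordant_expression and call.persistent

    def test_loss_with_downregulation_is_persistent(self):
        (call,) = expression_concordance(
            [CnaGeneCall("CASK", "S2", "loss", -1.0)],
            [ExpressionRecord("CASK", log2fc=-1.5, significant=True)],
            final_calls=[],
        )
        assert call.concordant_expression and call.persistent

    def test_discordant_and_not_redetected_is_not_persistent(self):
        (call,) = expression_concordance(
            [self.make_call("gain")],
            [ExpressionRecord("ABCB1", log2fc=-2.0, significant=True)],
            final_calls=[],
        )
        assert not call.concordant_expression and not call.persistent

    def test_insignificant_change_does_not_rescue(self):
        (call,) = expression_concordance(
            [self.make_call("gain")],
            [ExpressionRecord("ABCB1", log2fc=2.0, significant=False)],
            final_calls=[],
        )
        assert not call.concordant_expression

    def test_final_redetection_makes_persistent_without_concordance(self):
        final = [CnaGeneCall("ABCB1", "S5", "gain", 1.1)]
        (call,) = expression_concordance([self.make_call("gain")], [], final_calls=final)
        assert call.persistent and not call.concordant_expression

    def test_gene_missing_from_expression_is_nonconcordant(self):
        (call,) = expression_concordance([self.make_call("gain")], [], final_calls=[])
        assert not call.concordant_expression and not call.persistent


class TestSegmentInvariants:
    def test_direction_sign_consistency_enforced(self):
        with pytest.raises(ValidationError):
            CnaSegmentCall(
                stage_label="S1", reference_label="S0", chrom="1", start=1, end=10,
                log2_ratio=-1.0, p_value=0.01, q_value=0.02, direction="gain",
            )
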