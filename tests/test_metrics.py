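"""Ratio metrics and roadblock-boundary estimation."""
import numpy as np
import pytest

from txroadblock import (
    BinTestConfig,
    BinTrack,
    DataError,
    ElongationParams,
    RoadblockConfig,
    apa_ratio,
    bin_test,
    estimate_block_position,
    expression_ratio,
    interval_signal,
    make_bins,
    readthrough_ratio,
    sample_fragments,
    simulate_expression,
    simulate_occupancy,
)
from txroadblock.studies import readthrough_checkpoints
from conftest import make_fragments


class TestReadthroughRatio:
    def test_halved_readthrough(self):
        rt = readthrough_ratio(ds_treated=50, us_treated=100, ds_control=100, us_control=100)
        assert rt.normalized_ratio == pytest.approx(0.5)

    def test_identical_inputs_give_unity(self):
        rt = readthrough_ratio(30, 60, 30, 60)
        assert rt.normalized_ratio == pytest.approx(1.0)

    def test_zero_signal_names_the_checkpoint(self):
        with pytest.raises(DataError, match="us_control"):
            readthrough_ratio(10, 10, 10, 0)

    def test_simulated_post_pas_block_recovers_thinning(self, small_gene, params):
        """Checkpoints flanking a tau=0.8 block: normalised ratio ~ 0.2."""
        tau = 0.8
        block = RoadblockConfig(position=8_500, term_prob=tau)
        us, ds = readthrough_checkpoints(block, width=500, gap=160)
        n = 500_000
        tp = simulate_occupancy(small_gene, block, params, n_ec=n, seed=13)
        cp = simulate_occupancy(small_gene, None, params, n_ec=n, seed=14)
        tf = sample_fragments(tp, n, 150, seed=13)
        cf = sample_fragments(cp, n, 150, seed=14)
        rt = readthrough_ratio(
            interval_signal(tf, *ds), interval_signal(tf, *us),
            interval_signal(cf, *ds), interval_signal(cf, *us),
        )
        assert rt.normalized_ratio == pytest.approx(1 - tau, abs=0.02)


class TestApaRatio:
    def test_arithmetic(self):
        res = apa_ratio(up_treated=80, down_treated=20, up_control=40, down_control=40)
        assert res.ratio_treated == pytest.approx(4.0)
        assert res.normalized_ratio == pytest.approx(4.0)

    def test_no_shift_gives_unity(self):
        assert apa_ratio(10, 20, 10, 20).normalized_ratio == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(DataError, match="down_treated"):
            apa_ratio(10, 0, 10, 10)


class TestExpressionRatio:
    def _summary(self, small_gene, params, block, n, seed):
        prof = simulate_occupancy(small_gene, block, params, n_ec=n, seed=seed)
        return simulate_expression(prof, small_gene, params)

    def test_identical_runs_give_unity(self, small_gene, params):
        s = self._summary(small_gene, params, None, 10_000, 3)
        assert expression_ratio(s, s) == pytest.approx(1.0)

    def test_intragenic_block_thins_by_tau(self, small_gene, params):
        t = self._summary(small_gene, params, RoadblockConfig(position=3_000, term_prob=0.6), 200_000, 3)
        c = self._summary(small_gene, params, None, 200_000, 4)
        assert expression_ratio(t, c) == pytest.approx(0.4, abs=0.01)

    def test_post_pas_block_is_neutral(self, small_gene, params):
        t = self._summary(small_gene, params, RoadblockConfig(position=9_000, term_prob=0.9), 50_000, 3)
        c = self._summary(small_gene, params, None, 50_000, 4)
        assert expression_ratio(t, c) == pytest.approx(1.0)

    def test_reference_double_normalisation(self, small_gene, params):
        t = self._summary(small_gene, params, None, 10_000, 1)
        c = self._summary(small_gene, params, None, 10_000, 2)
        raw = expression_ratio(t, c)
        double = expression_ratio(t, c, treated_ref=t, control_ref=c)
        assert double == pytest.approx(raw / (t.mrna_count / c.mrna_count))

    def test_zero_control_rejected(self, small_gene, params):
        t = self._summary(small_gene, params, None, 1_000, 1)
        dead = self._summary(
            small_gene, params, RoadblockConfig(position=3_000, term_prob=1.0), 1_000, 1
        )
        with pytest.raises(DataError):
            expression_ratio(t, dead)


def result_from_pattern(log2fc, significant):
    """Build a BinTestResult-shaped object from explicit patterns."""
    grid = make_bins(("chrT", 0, 500 * len(log2fc)), 500)
    from txroadblock import BinTestResult

    log2fc = np.asarray(log2fc, float)
    sig = np.asarray(significant, bool)
    return BinTestResult(
        grid=grid,
        treated_norm=np.zeros(len(log2fc)),
        control_norm=np.zeros(len(log2fc)),
        log2fc=log2fc,
        p_value=np.where(sig, 1e-9, 0.5),
        significant=sig,
    )


class TestEstimateBlockPosition:
    def test_boundary_after_elevated_bin(self):
        res = result_from_pattern([+2, -2, -2], [True, True, True])
        assert estimate_block_position(res) == 1

    def test_not_detected_when_nothing_significant(self):
        res = result_from_pattern([1, -1, 0.5], [False, False, False])
        assert estimate_block_position(res) is None

    def test_first_bin_qualifies_vacuously(self):
        res = result_from_pattern([-2, -2, 0], [True, True, False])
        assert estimate_block_position(res) == 0

    def test_elevated_only_pattern_is_not_a_boundary(self):
        res = result_from_pattern([+2, +1, 0], [True, True, False])
        assert estimate_block_position(res) is None

    def test_recovers_simulated_block_bin(self, small_gene, params):
        """Block mid-bin 6 of a 20-bin locus: boundary within one bin."""
        block = RoadblockConfig(position=3_269, term_prob=0.8)  # stall 3250, bin 6
        n = 500_000
        tp = simulate_occupancy(small_gene, block, params, n_ec=n, seed=17)
        cp = simulate_occupancy(small_gene, None, params, n_ec=n, seed=18)
        grid = make_bins(small_gene)
        from txroadblock import count_fragments

        res = bin_test(
            count_fragments(grid, sample_fragments(tp, n, 150, seed=17)),
            count_fragments(grid, sample_fragments(cp, n, 150, seed=18)),
            BinTestConfig(method="exact"),
        )
        boundary = estimate_block_position(res)
        assert boundary is not None and abs(boundary - 6) <= 1
        assert int(np.argmax(res.log2fc)) == 6  # pause bin


class TestIntervalSignal:
    def test_overlap_convention(self):
        frags = make_fragments([100, 300], [200, 400])
        assert interval_signal(frags, 150, 320) == 2
        assert interval_signal(frags, 200, 300) == 0

    def test_bad_interval_rejected(self):
        frags = make_fragments([0], [10])
        from txroadblock import ConfigError

        with pytest.raises(ConfigError):
            interval_signal(frags, 10, 10)
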