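"""Elongation/roadblock simulator: fates, density shape, determinism."""
import numpy as np
import pytest

from txroadblock import (
    ConfigError,
    DataError,
    ElongationParams,
    GeneModel,
    Orientation,
    RoadblockConfig,
    sample_fragments,
    simulate_expression,
    simulate_occupancy,
)
from txroadblock.io import write_bed


class TestGeneModel:
    def test_invariants_enforced(self):
        with pytest.raises(ConfigError):
            GeneModel("c", 0, 1000, 500, (400,), 400)  # PAS before TSS
        with pytest.raises(ConfigError):
            GeneModel("c", 0, 1000, 0, (700, 600), 700)  # non-increasing PAS
        with pytest.raises(ConfigError):
            GeneModel("c", 0, 1000, 0, (700,), 0)  # zero length

    def test_roadblock_config_bounds(self):
        with pytest.raises(ConfigError):
            RoadblockConfig(position=100, term_prob=1.5)
        with pytest.raises(ConfigError):
            RoadblockConfig(position=100, pause_dwell=0.5)


class TestOccupancy:
    def test_absorbing_barrier_tau_one(self, small_gene, params):
        """With certain termination, no density survives past the stall and
        every EC is tallied as blocked."""
        block = RoadblockConfig(position=3_000, term_prob=1.0)
        prof = simulate_occupancy(small_gene, block, params, n_ec=5_000, seed=3)
        stall = block.stall
        assert np.all(prof.density[stall:] == 0)
        assert prof.fates["terminated_at_block"] == 5_000
        assert prof.fates["terminated_in_zone_at_pas_0"] == 0

    def test_template_strand_is_pass_through(self, small_gene, params):
        """T-orientation targeting leaves the profile identical to no block."""
        t_block = RoadblockConfig(
            position=3_000, orientation=Orientation.T, term_prob=0.0, pause_dwell=1.0
        )
        with_t = simulate_occupancy(small_gene, t_block, params, n_ec=10_000, seed=11)
        without = simulate_occupancy(small_gene, None, params, n_ec=10_000, seed=11)
        np.testing.assert_array_equal(with_t.density, without.density)
        assert with_t.fates == without.fates

    def test_template_strand_warns_when_tau_set(self, small_gene, params):
        t_block = RoadblockConfig(position=3_000, orientation="T", term_prob=0.8)
        with pytest.warns(UserWarning, match="no roadblock"):
            simulate_occupancy(small_gene, t_block, params, n_ec=100, seed=0)

    def test_mean_termination_distance_is_inverse_hazard(self):
        """Run-on past the committed PAS is geometric with mean 1/h."""
        h = 5e-4
        gene = GeneModel("chrT", 0, 30_000, 0, (7_000,), 7_000)  # ample run-on room
        params = ElongationParams(term_hazard=h)
        n = 200_000
        prof = simulate_occupancy(gene, None, params, n_ec=n, seed=5)
        dist = prof.stop - 7_000
        se = (1.0 / h) / np.sqrt(n)
        assert abs(dist.mean() - 1.0 / h) < 4 * se

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize(
        "block",
        [None, RoadblockConfig(position=3_000, term_prob=0.7), RoadblockConfig(position=8_000, term_prob=0.3)],
    )
    def test_fate_conservation(self, small_gene, params, seed, block):
        prof = simulate_occupancy(small_gene, block, params, n_ec=3_000, seed=seed)
        assert sum(prof.fates.values()) == 3_000
        assert (prof.density >= 0).all()

    def test_downstream_density_thins_by_one_minus_tau(self, small_gene, params):
        """Density past an NT block scales as (1 - tau) of control."""
        n = 400_000
        ctrl = simulate_occupancy(small_gene, None, params, n_ec=n, seed=9)
        means = []
        for tau in (0.3, 0.6):
            block = RoadblockConfig(position=3_000, term_prob=tau)
            prof = simulate_occupancy(small_gene, block, params, n_ec=n, seed=9)
            region = slice(4_000, 6_000)  # past block, before PAS
            means.append(prof.density[region].mean() / ctrl.density[region].mean())
        assert means[0] == pytest.approx(0.7, abs=0.01)
        assert means[1] == pytest.approx(0.4, abs=0.01)
        assert means[0] > means[1]

    def test_pause_peak_localised_to_window(self, small_gene, params):
        block = RoadblockConfig(position=3_000, term_prob=0.5)
        prof = simulate_occupancy(small_gene, block, params, n_ec=50_000, seed=2)
        ctrl = simulate_occupancy(small_gene, None, params, n_ec=50_000, seed=2)
        excess = prof.density - ctrl.density
        peak = int(np.argmax(excess))
        assert block.stall - block.pause_width <= peak < block.stall

    def test_post_pas_block_shifts_termination_zone_upstream(self, small_gene, params):
        """With a roadblock 2 kb past the PAS the native termination zone is
        lost: nearly all terminations move upstream of the control's tail."""
        block = RoadblockConfig(position=9_000, term_prob=0.9)
        treated = simulate_occupancy(small_gene, block, params, n_ec=100_000, seed=4)
        ctrl = simulate_occupancy(small_gene, None, params, n_ec=100_000, seed=14)
        q99 = np.quantile(ctrl.stop, 0.99)
        assert (treated.stop <= q99).mean() >= 0.99
        assert treated.stop.mean() < ctrl.stop.mean()

    def test_block_outside_locus_rejected(self, small_gene, params):
        block = RoadblockConfig(position=20_000, term_prob=0.5)
        with pytest.raises(ConfigError, match="outside locus"):
            simulate_occupancy(small_gene, block, params, n_ec=10, seed=0)


class TestFragments:
    def test_count_and_locus_containment(self, small_gene, params):
        prof = simulate_occupancy(small_gene, None, params, n_ec=2_000, seed=1)
        frags = sample_fragments(prof, n_fragments=1_000, frag_len=150, seed=1)
        assert frags.library_size == 1_000
        assert (frags.starts >= 0).all() and (frags.ends <= 10_000).all()

    def test_no_starts_in_zero_density_region(self, small_gene, params):
        block = RoadblockConfig(position=3_000, term_prob=1.0)
        prof = simulate_occupancy(small_gene, block, params, n_ec=2_000, seed=1)
        frags = sample_fragments(prof, n_fragments=2_000, frag_len=150, seed=1)
        assert (frags.starts < block.stall).all()

    def test_same_seed_gives_byte_identical_bed(self, small_gene, params, tmp_path):
        prof = simulate_occupancy(small_gene, None, params, n_ec=2_000, seed=7)
        a = sample_fragments(prof, 500, 150, seed=42)
        b = sample_fragments(prof, 500, 150, seed=42)
        pa, pb = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed(a, pa)
        write_bed(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_fragment_sampling_does_not_perturb_fates(self, small_gene, params):
        """Labeled substreams: fates are identical whatever fragment count."""
        p1 = simulate_occupancy(small_gene, None, params, n_ec=2_000, seed=7)
        sample_fragments(p1, 100, 150, seed=7)
        p2 = simulate_occupancy(small_gene, None, params, n_ec=2_000, seed=7)
        sample_fragments(p2, 9_000, 150, seed=7)
        assert p1.fates == p2.fates
        np.testing.assert_array_equal(p1.stop, p2.stop)

    def test_zero_density_rejected(self, small_gene, params):
        prof = simulate_occupancy(small_gene, None, params, n_ec=10, seed=0)
        prof.density[:] = 0.0
        with pytest.raises(DataError, match="zero"):
            sample_fragments(prof, 100, 150, seed=0)


class TestExpression:
    def test_intragenic_block_thins_mrna(self, small_gene, params):
        n = 100_000
        block = RoadblockConfig(position=3_000, term_prob=0.6)
        prof = simulate_occupancy(small_gene, block, params, n_ec=n, seed=6)
        summ = simulate_expression(prof, small_gene, params)
        se = np.sqrt(0.6 * 0.4 / n)
        assert summ.mrna_count / n == pytest.approx(0.4, abs=4 * se)

    def test_post_pas_block_leaves_expression_unchanged(self, small_gene, params):
        block = RoadblockConfig(position=9_000, term_prob=0.9)
        prof = simulate_occupancy(small_gene, block, params, n_ec=10_000, seed=6)
        summ = simulate_expression(prof, small_gene, params)
        assert summ.mrna_count == 10_000  # terminal PAS commits every EC

    def test_inter_pas_rescue_matches_fate_enumeration(self, two_pas_gene):
        """Enumerating fate branches: proximal usage = c + (1-c) * tau."""
        c, tau, n = 0.2, 0.5, 200_000
        params = ElongationParams(pas_commit=(c, 1.0), inter_pas_rescue=True)
        block = RoadblockConfig(position=8_000, term_prob=tau)
        prof = simulate_occupancy(two_pas_gene, block, params, n_ec=n, seed=8)
        summ = simulate_expression(prof, two_pas_gene, params)
        expected = c + (1 - c) * tau
        se = np.sqrt(expected * (1 - expected) / n)
        assert summ.pas_counts[0] / summ.mrna_count == pytest.approx(expected, abs=4 * se)
        assert summ.mrna_count == summ.pas_counts[0] + summ.pas_counts[1]

    def test_rescue_off_drops_blocked_transcripts(self, two_pas_gene):
        params = ElongationParams(pas_commit=(0.2, 1.0), inter_pas_rescue=False)
        block = RoadblockConfig(position=8_000, term_prob=1.0)
        prof = simulate_occupancy(two_pas_gene, block, params, n_ec=50_000, seed=8)
        summ = simulate_expression(prof, two_pas_gene, params)
        # only proximal committers make mRNA; everyone else dies at the block
        assert summ.pas_counts[1] == 0
        assert summ.mrna_count == pytest.approx(0.2 * 50_000, rel=0.05)

    def test_readthrough_count_uses_checkpoint(self, small_gene, params):
        prof = simulate_occupancy(small_gene, None, params, n_ec=5_000, seed=2)
        near = simulate_expression(prof, small_gene, params, readthrough_checkpoint=7_100)
        far = simulate_expression(prof, small_gene, params, readthrough_checkpoint=9_500)
        assert near.readthrough_count > far.readthrough_count
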