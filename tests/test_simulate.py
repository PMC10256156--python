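import numpy as np
import pytest
from scipy import stats

from replisim import (
    EffectiveIPLS,
    GenomeLattice,
    Profile,
    SimParams,
    draw_potential_origins,
    rescale_kon,
    simulate_ensemble,
    simulate_s_phase,
)
from tests.conftest import point_mass_ipls


class TestRescaleKon:
    def test_whole_genome_value(self):
        # 2 875 000 kb at kone = 8.625 kb/min gives the printed 3e-6 /min
        assert np.isclose(rescale_kon(8.625, 2_875_000.0), 3e-6)

    def test_small_system(self):
        assert np.isclose(rescale_kon(8.625, 8_625.0), 1e-3)

    def test_halving_length_doubles_rate(self):
        assert rescale_kon(8.625, 1e5) * 2 == rescale_kon(8.625, 5e4)

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            rescale_kon(8.625, 0.0)


class TestDrawPotentialOrigins:
    def test_point_mass_gets_all_origins(self, small_lattice):
        ipls = EffectiveIPLS(point_mass_ipls(small_lattice, 7), 0.0)
        counts = draw_potential_origins(ipls, 10, np.random.default_rng(0))
        assert counts[7] == 10 and counts.sum() == 10

    def test_pure_uniform_is_uniform_multinomial(self, small_lattice):
        zero = Profile(np.zeros(small_lattice.n_bins), "generic", small_lattice)
        ipls = EffectiveIPLS(zero, 1.0)
        p = ipls.effective()
        assert np.allclose(p, 1.0 / small_lattice.n_bins)

    def test_multinomial_goodness_of_fit(self):
        lat = GenomeLattice(["c"], [1000], 5.0)
        ipls = EffectiveIPLS(
            Profile(np.full(1000, 1e-3), "ipls", lat), 0.0
        )
        passes = 0
        for seed in range(50):
            counts = draw_potential_origins(
                ipls, 100_000, np.random.default_rng(seed)
            )
            p = stats.chisquare(counts).pvalue
            passes += p > 1e-3
        assert passes >= 48

    def test_all_zero_landscape_rejected(self, small_lattice):
        zero = Profile(np.zeros(small_lattice.n_bins), "generic", small_lattice)
        with pytest.raises(ValueError):
            draw_potential_origins(EffectiveIPLS(zero, 0.0), 5, np.random.default_rng(0))


class TestSingleOriginGeometry:
    def test_rt_and_fork_signs(self):
        lat = GenomeLattice(["c"], [200], 5.0)
        b0 = 80
        # exactly one potential origin (d_PO = L), immediate strong firing
        params = SimParams(
            v=1.5, kone=1e6, rho_F=1.0, d_PO=lat.length_kb, tau=0.0, n_sims=1
        )
        rec = simulate_s_phase(
            lat, EffectiveIPLS(point_mass_ipls(lat, b0), 0.0), params,
            np.random.default_rng(0),
        )
        t0 = rec.rt_min[b0]
        x = (np.arange(200) + 0.5) * 5.0
        expected = t0 + np.abs(x - x[b0]) / 1.5
        assert np.allclose(rec.rt_min, expected)
        assert rec.fork_sign[b0] == 0
        assert (rec.fork_sign[:b0] == -1).all()
        assert (rec.fork_sign[b0 + 1 :] == 1).all()
        assert rec.fired_bins.tolist() == [b0]

    def test_two_origin_symmetry_and_factor_balance(self):
        lat = GenomeLattice(["c"], [200], 5.0)
        a, b = 50, 150
        params = SimParams(
            v=1.5, kone=1e8, rho_F=4.0, d_PO=lat.length_kb / 2, tau=0.0, n_sims=1
        )
        rec = simulate_s_phase(
            lat, EffectiveIPLS(point_mass_ipls(lat, [a, b]), 0.0), params,
            np.random.default_rng(1),
        )
        # both fire (essentially simultaneously); termination at the midpoint
        assert set(rec.fired_bins) == {a, b}
        mid = (a + b) // 2
        assert rec.fork_sign[mid] == 0
        assert rec.rt_min[mid] == np.nanmax(rec.rt_min[a:b])
        # 2 initiations - 1 merge - 1 boundary pair = all factors free at end
        times, counts = rec.f_free_trace
        assert counts[0] == 0
        assert counts[-1] == params.n_factors(lat.length_kb)


class TestStrongAffinityLimits:
    def test_t100_matches_distance_transform_oracle(self):
        lat = GenomeLattice(["c"], [200], 5.0)
        rng = np.random.default_rng(7)
        bins = rng.choice(200, size=5, replace=False)
        params = SimParams(
            v=1.5, kone=1e8, rho_F=10.0, d_PO=lat.length_kb / 5, tau=0.0, n_sims=1
        )
        rec = simulate_s_phase(
            lat, EffectiveIPLS(point_mass_ipls(lat, bins), 0.0), params,
            np.random.default_rng(3),
        )
        # oracle: with instant firing every drawn origin bin fires, so
        # rt(x) = (distance to the nearest fired bin) / v.  The multinomial
        # draw can place several origins in one bin, so use the fired set.
        fired = rec.fired_bins
        assert set(fired) <= set(bins.tolist())
        x = (np.arange(200) + 0.5) * 5.0
        dist = np.min(np.abs(x[:, None] - x[fired][None, :]), axis=1)
        assert np.allclose(rec.rt_min, dist / 1.5, atol=1e-3)

    def test_ts_approximation_strong_affinity(self):
        # T_S ~ 1/(2 v rho_F) when kone is large on a uniform landscape
        lat = GenomeLattice(["c"], [4000], 5.0)  # 20 Mb
        ipls = Profile(np.full(4000, 1 / 4000), "ipls", lat)
        params = SimParams(
            v=1.5, kone=8625.0, rho_F=1.0, d_PO=10.0, tau=0.0, n_sims=10, seed=5
        )
        ens = simulate_ensemble(lat, EffectiveIPLS(ipls, 0.0), params)
        t100 = np.median([r.t100 for r in ens.records])
        expected = 1.0 / (2 * 1.5 * 1.0e-3)  # rho_F per kb
        assert abs(t100 - expected) / expected < 0.15


class TestConservationAndErrors:
    def test_every_bin_replicated_exactly_once(self, small_lattice, uniform_ipls):
        params = SimParams(rho_F=3.0, n_sims=1, seed=0)
        rec = simulate_s_phase(
            small_lattice, EffectiveIPLS(uniform_ipls, 0.0), params,
            np.random.default_rng(2),
        )
        assert np.isfinite(rec.rt_min).all()
        times, counts = rec.f_free_trace
        assert counts[-1] == params.n_factors(small_lattice.length_kb)
        assert (np.asarray(counts) >= 0).all()

    def test_unreplicable_segment_is_reported(self):
        lat = GenomeLattice(["c"], [400], 5.0)
        lat.mask[200:210] = True  # splits chromosome in two segments
        params = SimParams(n_sims=1, d_PO=lat.length_kb / 4)
        with pytest.raises(ValueError, match="segment"):
            # all origins forced into the first segment
            simulate_s_phase(
                lat, EffectiveIPLS(point_mass_ipls(lat, 50), 0.0), params,
                np.random.default_rng(0),
            )

    def test_rho_f_monotonicity_of_t95(self):
        lat = GenomeLattice(["c"], [2000], 5.0)
        ipls = Profile(np.full(2000, 1 / 2000), "ipls", lat)

        def median_t95(rho):
            params = SimParams(rho_F=rho, n_sims=8, seed=99)
            ens = simulate_ensemble(lat, EffectiveIPLS(ipls, 0.0), params)
            t95s = []
            for r in ens.records:
                rts = np.sort(r.rt_min)
                t95s.append(rts[int(np.ceil(0.95 * rts.size)) - 1])
            return np.median(t95s)

        assert median_t95(4.0) <= median_t95(1.0)

    def test_seed_determinism(self, small_lattice, uniform_ipls):
        params = SimParams(rho_F=3.0, n_sims=3, seed=77)
        a = simulate_ensemble(small_lattice, EffectiveIPLS(uniform_ipls, 0.0), params)
        b = simulate_ensemble(small_lattice, EffectiveIPLS(uniform_ipls, 0.0), params)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.rt_min, rb.rt_min)
            assert np.array_equal(ra.fork_sign, rb.fork_sign)
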