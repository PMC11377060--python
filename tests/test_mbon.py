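"""MBON plasticity: spt rule, AP probability, latency, protocol mechanics."""

import numpy as np
import pytest

from beemb.mb import KCSpikeRaster, MBConfig
from beemb.mbon import (
    ConditioningProtocol,
    MBONModel,
    PROTOCOLS,
    ablation_experiment,
    ap_probability,
    conditioning_inputs_from_maps,
    evaluate_protocols,
    learned_latency,
    min_active_time_ms,
    train,
)
from beemb.stats import bartlett_test, kruskal_test, wilcoxon_signed_rank
from beemb.synthetic import make_balanced_odorants


def raster(activity, t0=-1.0):
    act = np.asarray(activity, dtype=np.uint8)
    t = t0 + np.arange(act.shape[1]) * 0.05
    return KCSpikeRaster(activity=act, epsp=act.astype(float), time_s=t,
                         network_seed=0)


def make_window_raster(counts_in_window, protocol, T=300, t0=-2.0):
    """Raster where KC i fires exactly counts_in_window[i] times inside the
    learning window and nowhere else."""
    n = len(counts_in_window)
    act = np.zeros((n, T), dtype=np.uint8)
    t = t0 + np.arange(T) * 0.05
    lo, hi = protocol.window
    win = np.flatnonzero((t >= lo - 1e-9) & (t < hi - 1e-9))
    for i, c in enumerate(counts_in_window):
        act[i, win[:c]] = 1
    return KCSpikeRaster(activity=act, epsp=act.astype(float), time_s=t,
                         network_seed=0)


class TestSptRule:
    def test_threshold_arithmetic(self):
        """spt = 15 at 50 ms steps requires >= 750 ms of activation inside
        the 3 s window; spt = 40 requires 2 s."""
        assert min_active_time_ms(15) == pytest.approx(750.0)
        assert min_active_time_ms(40) == pytest.approx(2000.0)

    @pytest.mark.parametrize("count,expect_weight", [(20, 0.0), (15, 0.0),
                                                     (14, 1.0), (0, 1.0)])
    def test_depression_boundary(self, count, expect_weight):
        proto = PROTOCOLS["early"]
        r = make_window_raster([count], proto)
        m = train(MBONModel.untrained(1, spt=15), r, proto)
        assert m.weights[0] == expect_weight

    def test_window_outside_raster_rejected(self):
        r = raster(np.zeros((3, 20)), t0=0.0)  # covers [0, 1) s only
        with pytest.raises(ValueError, match="outside raster"):
            train(MBONModel.untrained(3), r, PROTOCOLS["delay"])

    def test_backward_window_needs_prestimulus_coverage(self):
        r = raster(np.zeros((3, 100)), t0=-1.0)
        with pytest.raises(ValueError):
            train(MBONModel.untrained(3), r, PROTOCOLS["backward"])

    def test_monotone_learning(self, rng):
        """Training never increases weights; a superset window depresses a
        superset of synapses."""
        act = (rng.random((50, 300)) < 0.3).astype(np.uint8)
        r = raster(act, t0=-2.0)
        short = ConditioningProtocol("short", 1.0, us_duration_s=2.0)
        full = ConditioningProtocol("full", 1.0, us_duration_s=3.0)
        m0 = MBONModel.untrained(50, spt=10)
        m_short = train(m0, r, short)
        m_full = train(m0, r, full)
        assert np.all(m_short.weights <= m0.weights)
        assert np.all(m_full.weights <= m_short.weights)

    def test_maximal_sensitivity_depresses_every_recruited_synapse(self, rng):
        """spt = 1 switches off every KC that fires at all inside the
        window — the non-specific learning extreme."""
        act = (rng.random((40, 300)) < 0.2).astype(np.uint8)
        r = raster(act, t0=-2.0)
        proto = PROTOCOLS["early"]
        m = train(MBONModel.untrained(40, spt=1), r, proto)
        t = r.time_s
        lo, hi = proto.window
        recruited = act[:, (t >= lo) & (t < hi)].sum(axis=1) >= 1
        np.testing.assert_array_equal(m.weights == 0, recruited)

    def test_impossible_threshold_learns_nothing(self, rng):
        """spt larger than the 60-step window leaves all weights intact."""
        act = (rng.random((30, 300)) < 0.5).astype(np.uint8)
        r = raster(act, t0=-2.0)
        m = train(MBONModel.untrained(30, spt=61), r, PROTOCOLS["early"])
        assert np.all(m.weights == 1)


class TestApProbability:
    def test_untrained_identically_one(self, rng):
        act = (rng.random((40, 60)) < 0.25).astype(np.uint8)
        act[:, 0] = 1  # avoid an empty timestep
        p = ap_probability(MBONModel.untrained(40), raster(act))
        assert np.allclose(p[np.isfinite(p)], 1.0)

    def test_depressed_fraction_arithmetic(self):
        """100 active KCs of which 40 depressed -> probability 0.6."""
        act = np.zeros((120, 1), dtype=np.uint8)
        act[:100] = 1
        w = np.ones(120)
        w[:40] = 0.0
        p = ap_probability(MBONModel(weights=w, spt=15), raster(act))
        assert p[0] == pytest.approx(0.6)

    def test_no_active_kc_flagged_nan(self):
        act = np.zeros((5, 3), dtype=np.uint8)
        act[0, 1] = 1
        p = ap_probability(MBONModel.untrained(5), raster(act))
        assert np.isnan(p[0]) and np.isnan(p[2])
        assert p[1] == 1.0

    def test_matches_bruteforce_weighted_count(self, rng):
        act = (rng.random((25, 40)) < 0.3).astype(np.uint8)
        w = (rng.random(25) < 0.6).astype(float)
        p = ap_probability(MBONModel(weights=w, spt=1), raster(act))
        for t in range(40):
            n_act = act[:, t].sum()
            if n_act == 0:
                assert np.isnan(p[t])
            else:
                expect = (w * act[:, t]).sum() / n_act
                assert p[t] == pytest.approx(expect, abs=1e-12)


class TestLearnedLatency:
    def test_step_drop(self):
        t = np.arange(0, 6, 0.05)
        p = np.where(t >= 0.4, 0.3, 1.0)
        assert learned_latency(p, t) == pytest.approx(400.0)

    def test_linear_ramp_90pct(self):
        """Ramp from 1 at onset to p_min at 5 s crosses 90% of the drop at
        4.5 s."""
        t = np.arange(0, 5.0001, 0.001)
        p = 1.0 - 0.6 * (t / 5.0)
        assert learned_latency(p, t) == pytest.approx(4500.0, abs=2)

    def test_flat_trace_undefined(self):
        t = np.arange(0, 3, 0.05)
        assert np.isnan(learned_latency(np.ones_like(t), t))


@pytest.fixture(scope="module")
def small_battery(gen_config, conditioning_protocol):
    from beemb.synthetic import make_profile_database
    db = make_profile_database(gen_config, conditioning_protocol,
                               n_per_group=6, seed=11)
    maps = make_balanced_odorants(db, 4, seed=11)
    inputs = conditioning_inputs_from_maps(maps, gen_config, seed=12)
    return evaluate_protocols(inputs, config=MBConfig(n_kc=300), seed=13)


class TestProtocolBattery:

    def test_records_cover_all_protocols_and_inputs(self, small_battery):
        rec = small_battery.records()
        assert set(rec["protocol"]) == set(PROTOCOLS)
        assert len(rec) == 4 * 4  # 4 inputs x 4 protocols

    def test_cs_scores_exceed_novel_for_forward_pairings(self, small_battery):
        for proto in ("early", "delay"):
            cs, nod = small_battery.scores(proto)
            assert cs.mean() > nod.mean()

    def test_backward_weaker_than_early(self, small_battery):
        cs_b, _ = small_battery.scores("backward")
        cs_e, _ = small_battery.scores("early")
        assert cs_b.mean() < cs_e.mean()

    def test_trace_minimum_after_offset(self, small_battery):
        t_min = [o.t_min_s for o in small_battery.outcomes
                 if o.protocol == "trace"]
        assert np.median(t_min) > 5.0

    def test_determinism(self, gen_config, conditioning_protocol):
        from beemb.synthetic import make_profile_database
        db = make_profile_database(gen_config, conditioning_protocol,
                                   n_per_group=6, seed=21)
        maps = make_balanced_odorants(db, 2, seed=21)
        kw = dict(config=MBConfig(n_kc=200), seed=5)
        a = evaluate_protocols(conditioning_inputs_from_maps(maps, gen_config,
                                                             seed=3), **kw)
        b = evaluate_protocols(conditioning_inputs_from_maps(maps, gen_config,
                                                             seed=3), **kw)
        assert a.records().equals(b.records())


class TestAblation:
    def test_same_seed_identical_pvalues(self, profile_db, gen_config):
        kw = dict(n_repeats=2, n_odorants=4, config=MBConfig(n_kc=200),
                  seed=7, variants={"none": (), "no_inh": (1, 2, 3)})
        a = ablation_experiment(profile_db, gen_config, **kw)
        b = ablation_experiment(profile_db, gen_config, **kw)
        for v in a.p_values:
            np.testing.assert_array_equal(a.p_values[v], b.p_values[v])

    def test_reports_all_variants(self, profile_db, gen_config):
        res = ablation_experiment(profile_db, gen_config, n_repeats=1,
                                  n_odorants=4, config=MBConfig(n_kc=150),
                                  seed=1)
        assert set(res.p_values) == {"none", "no_stable_excitatory",
                                     "no_inhibitory", "no_short_excitatory",
                                     "no_inhibitory_no_short"}
        assert len(res.latency_medians) == 5


class TestStatsSuite:
    def test_identical_paired_samples_no_effect(self):
        x = np.arange(10.0)
        stat, p = wilcoxon_signed_rank(x, x)
        assert p == 1.0

    def test_kruskal_textbook_example(self):
        """Three untied rank groups 1-3, 4-6, 7-9 give H = 7.2 exactly."""
        h, p = kruskal_test([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(7.2, abs=1e-12)

    def test_kruskal_all_identical_p_one(self):
        assert kruskal_test([2, 2], [2, 2])[1] == 1.0

    def test_bartlett_null_uniform(self, rng):
        """Bartlett p-values are ~uniform under equal variances."""
        ps = [bartlett_test(rng.normal(size=30), rng.normal(size=30))[1]
              for _ in range(200)]
        assert 0.35 < np.mean(np.asarray(ps) < 0.5) < 0.65
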