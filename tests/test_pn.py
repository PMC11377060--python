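"""PN processing: dF/F, averaging, stability, classification, latency."""

import numpy as np
import pytest

from beemb.pn import (
    ClassifierParams,
    average_trials,
    classify_profile,
    compute_dff,
    latency_summary,
    response_latency,
    trial_stability,
    window_vector,
)
from beemb.stats import safe_pearson
from beemb.synthetic import GeneratorConfig, draw_template, make_dataset, make_profile
from beemb.types import GlomerularTrace, OdorResponseMap, UNRESPONSIVE


def trace_from(values, protocol, **kw):
    return GlomerularTrace(values=np.asarray(values, float),
                           time_s=protocol.times(), protocol=protocol, **kw)


class TestComputeDff:
    def test_constant_fluorescence_gives_zero(self, fast_protocol):
        raw = trace_from(np.full(fast_protocol.n_samples, 100.0), fast_protocol)
        out = compute_dff(raw)
        assert np.allclose(out.values, 0)

    def test_signed_arithmetic(self, fast_protocol):
        """A fluorescence decrease maps to a positive response (-dF/F) and
        an increase to a negative one."""
        f = np.full(fast_protocol.n_samples, 100.0)
        t = fast_protocol.times()
        f[np.searchsorted(t, 1.0)] = 90.0
        f[np.searchsorted(t, 2.0)] = 120.0
        out = compute_dff(trace_from(f, fast_protocol))
        assert out.values[np.searchsorted(t, 1.0)] == pytest.approx(0.10)
        assert out.values[np.searchsorted(t, 2.0)] == pytest.approx(-0.20)
        base = t < 0
        assert abs(out.values[base].mean()) < 1e-12

    def test_nonpositive_baseline_rejected(self, fast_protocol):
        raw = trace_from(np.zeros(fast_protocol.n_samples), fast_protocol)
        with pytest.raises(ValueError, match="baseline"):
            compute_dff(raw)

    def test_not_idempotent_on_normalised_traces(self, fast_protocol):
        """An already-normalised trace has a zero baseline, so re-applying
        the dF/F transform recomputes F0 = 0 and must fail loudly rather
        than silently renormalise."""
        raw = trace_from(np.full(fast_protocol.n_samples, 50.0), fast_protocol)
        once = compute_dff(raw)
        with pytest.raises(ValueError, match="baseline"):
            compute_dff(once)

    def test_missing_baseline_window_rejected(self, fast_protocol):
        t = fast_protocol.times()
        keep = t >= -0.5
        tr = GlomerularTrace(values=np.full(keep.sum(), 10.0), time_s=t[keep],
                             protocol=fast_protocol)
        with pytest.raises(ValueError, match="baseline"):
            compute_dff(tr)


class TestAverageTrials:
    def test_identical_trials_average_to_themselves(self, fast_protocol, rng):
        tr = trace_from(rng.normal(size=fast_protocol.n_samples), fast_protocol)
        out = average_trials([tr, tr, tr])
        np.testing.assert_allclose(out.values, tr.values)
        assert out.trial == "mean"

    def test_opposite_trials_cancel(self, fast_protocol, rng):
        v = rng.normal(size=fast_protocol.n_samples)
        out = average_trials([trace_from(v, fast_protocol),
                              trace_from(-v, fast_protocol)])
        assert np.allclose(out.values, 0)

    def test_noise_reduction_scaling(self, fast_protocol, rng):
        """Averaging 20 noisy trials shrinks residual sd by ~1/sqrt(20)."""
        sigma = 0.1
        trials = [trace_from(rng.normal(0, sigma, fast_protocol.n_samples),
                             fast_protocol) for _ in range(20)]
        resid_sd = average_trials(trials).values.std()
        assert resid_sd == pytest.approx(sigma / np.sqrt(20), rel=0.25)


class TestWindows:
    def test_all_zero_map_gives_zero_vector(self, fast_protocol):
        m = OdorResponseMap(values=np.zeros((3, fast_protocol.n_samples)),
                            time_s=fast_protocol.times(), protocol=fast_protocol)
        assert np.all(window_vector(m, "ON") == 0)

    def test_constant_on_response(self, fast_protocol):
        t = fast_protocol.times()
        v = np.zeros((1, len(t)))
        v[0, (t >= 0) & (t < 5)] = 0.2
        m = OdorResponseMap(values=v, time_s=t, protocol=fast_protocol)
        assert window_vector(m, "ON")[0] == pytest.approx(0.2)
        assert window_vector(m, "PRE")[0] == pytest.approx(0.0)

    def test_unknown_window_rejected(self, fast_protocol):
        m = OdorResponseMap(values=np.zeros((1, fast_protocol.n_samples)),
                            time_s=fast_protocol.times(), protocol=fast_protocol)
        with pytest.raises(ValueError):
            window_vector(m, "BOGUS")


class TestTrialStability:
    def make_trials(self, fast_protocol, rng, noise=0.0, n=5):
        t = fast_protocol.times()
        base = np.outer(rng.uniform(0.05, 0.3, size=6), (t >= 0) & (t < 5))
        post = np.outer(rng.uniform(0.05, 0.3, size=6),
                        (t >= 6) & (t < 9))
        return [OdorResponseMap(values=base + post +
                                rng.normal(0, noise, base.shape),
                                time_s=t, protocol=fast_protocol)
                for _ in range(n)]

    def test_noiseless_trials_fully_correlated(self, fast_protocol, rng):
        rep = trial_stability(self.make_trials(fast_protocol, rng))
        assert rep.mean("ONvsON") == pytest.approx(1.0)
        assert rep.mean("POSTvsPOST") == pytest.approx(1.0)

    def test_on_equals_post_pattern(self, fast_protocol, rng):
        t = fast_protocol.times()
        pat = rng.uniform(0.1, 0.3, size=6)
        v = np.outer(pat, ((t >= 0) & (t < 5)) | ((t >= 6) & (t < 9)))
        trials = [OdorResponseMap(values=v, time_s=t, protocol=fast_protocol)
                  for _ in range(3)]
        rep = trial_stability(trials)
        assert rep.mean("ONvsPOST") == pytest.approx(1.0)

    def test_pure_noise_uncorrelated(self, fast_protocol, rng):
        t = fast_protocol.times()
        trials = [OdorResponseMap(values=rng.normal(0, 1, (10, len(t))),
                                  time_s=t, protocol=fast_protocol)
                  for _ in range(8)]
        rep = trial_stability(trials)
        assert abs(rep.mean("ONvsON")) < 0.2

    def test_zero_variance_reported_missing(self, fast_protocol):
        t = fast_protocol.times()
        trials = [OdorResponseMap(values=np.zeros((4, len(t))), time_s=t,
                                  protocol=fast_protocol) for _ in range(3)]
        rep = trial_stability(trials)
        assert rep.n_missing["ONvsON"] == 3  # all pairs undefined, not zero
        assert np.isnan(rep.correlations["ONvsON"]).all()


class TestClassification:
    def test_flat_trace_unresponsive(self, protocol):
        tr = trace_from(np.zeros(protocol.n_samples), protocol)
        assert classify_profile(tr).group_id == UNRESPONSIVE

    def test_sustained_positive_is_group4(self, protocol):
        t = protocol.times()
        v = np.where((t >= 0.3) & (t < 5), 0.2, 0.0)
        c = classify_profile(trace_from(v, protocol))
        assert c.group_id == 4
        assert c.polarity == "excitatory"
        assert not c.has_inhibitory_component

    def test_short_excitation_then_inhibition_is_group8(self, protocol, gen_config,
                                                        rng):
        tpl = draw_template(8, gen_config, rng)
        c = classify_profile(make_profile(tpl, protocol))
        assert c.group_id == 8
        assert c.has_inhibitory_component

    def test_nonuniform_grid_rejected_at_construction(self, protocol):
        t = protocol.times().copy()
        t[10] += 0.003
        with pytest.raises(ValueError, match="uniform"):
            GlomerularTrace(values=np.zeros_like(t), time_s=t, protocol=protocol)

    def test_inhibitory_component_flag_matches_group_set(self, protocol,
                                                         gen_config, rng):
        for g in range(10):
            c = classify_profile(
                make_profile(draw_template(g, gen_config, rng), protocol))
            assert c.has_inhibitory_component == (g in {1, 2, 3, 5, 7, 8})


class TestLatency:
    def test_step_latency_exact(self, protocol):
        t = protocol.times()
        v = np.where(t >= 0.3, 1.0, 0.0)
        r = response_latency(trace_from(v, protocol), "onset_excitatory")
        assert r.latency_ms == pytest.approx(1000 * t[np.searchsorted(t, 0.3)])
        assert r.latency_ms >= 300
        assert r.latency_ms - 300 < 1000 * protocol.dt

    def test_pure_noise_flagged_undefined(self, protocol, rng):
        v = rng.normal(0, 0.01, protocol.n_samples)
        r = response_latency(trace_from(v, protocol), "onset_excitatory")
        assert not r.defined
        assert "not_crossed" in r.flags

    def test_noiseless_onset_recovery(self, protocol, gen_config, rng):
        """1-SD estimator recovers the configured onset to one sample for
        excitatory profiles; deepening inhibition may cross the threshold a
        few samples later (shallow initial depth), bounded at 40 ms."""
        for g, direction, bound_ms in ((4, "onset_excitatory",
                                        1000 * protocol.dt),
                                       (1, "onset_inhibitory", 40.0)):
            for _ in range(20):
                tpl = draw_template(g, gen_config, rng)
                r = response_latency(make_profile(tpl, protocol), direction)
                err = r.latency_ms - tpl.onset_latency_ms
                assert 0 <= err <= bound_ms + 1e-9

    def test_population_latency_recovery(self, protocol):
        """Mean recovered onset of a noisy group-4 population stays within a
        sampling interval plus the standard error of the 313 ms target."""
        cfg = GeneratorConfig(seed=77)
        p = np.zeros(10)
        p[3] = 1.0  # group 4 only
        d = cfg.to_dict()
        d.update(group_proportions=p, noise_sd=0.02)
        ds = make_dataset(GeneratorConfig(**d), protocol, n_glomeruli=40,
                          n_odorants=1)
        lats = []
        avg = ds.trial_average_map(0)
        for i in range(40):
            r = response_latency(avg.row(i), "onset_excitatory")
            if r.defined:
                lats.append(r.latency_ms)
        mean = np.mean(lats)
        sem = 22.0 / np.sqrt(len(lats))
        assert abs(mean - 313.0) <= 1000 * protocol.dt + 3 * sem + 10

    def test_unknown_direction_rejected(self, protocol):
        tr = trace_from(np.zeros(protocol.n_samples), protocol)
        with pytest.raises(ValueError):
            response_latency(tr, "sideways")


class TestLatencySummary:
    def test_single_group_no_test(self, protocol, gen_config, rng):
        cls = [classify_profile(make_profile(draw_template(4, gen_config, rng),
                                             protocol)) for _ in range(5)]
        s = latency_summary(cls)
        assert s.kruskal is None
        assert s.table.set_index("category").loc["excitatory_onset", "n"] == 5

    def test_printed_latency_distributions_separate(self, rng):
        """At the recorded sample sizes (263/201/60) the excitatory-vs-
        inhibitory onset difference is detected by Kruskal-Wallis."""
        from beemb.pn import ResponseClassification

        def fake(n, mu, sd, group, attr):
            out = []
            for v in rng.normal(mu, sd, n):
                c = ResponseClassification(group_id=group, polarity="",
                                           has_inhibitory_component=False)
                setattr(c, attr, v)
                out.append(c)
            return out

        cls = (fake(263, 313, 22, 4, "onset_latency_ms")
               + fake(201, 351, 47, 1, "onset_latency_ms")
               + fake(60, 346, 47, 7, "termination_latency_ms"))
        s = latency_summary(cls)
        assert s.kruskal[1] < 0.05
        tbl = s.table.set_index("category")
        assert tbl.loc["excitatory_onset", "mean_ms"] < \
            tbl.loc["inhibitory_onset", "mean_ms"]


def test_pearson_matches_bruteforce_oracle(rng):
    """All Pearson computations agree with the covariance formula to 1e-12."""
    for _ in range(50):
        x, y = rng.normal(size=(2, 10))
        expect = (np.cov(x, y, bias=True)[0, 1]
                  / (x.std() * y.std()))
        assert safe_pearson(x, y) == pytest.approx(expect, abs=1e-12)
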