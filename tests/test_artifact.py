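"""Template subtraction, residual detection and blackout bookkeeping."""
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import optoclean as oc
from optoclean.artifact import BlackoutMask, _window_bounds
from optoclean.synth import spike_shape


def _identical_snippets(n, C=2, T=600, value=None, rng=None):
    base = (np.outer(np.ones(C), np.sin(np.linspace(0, 6, T))) * 100
            if value is None else value)
    return [base.copy() for _ in range(n)]


class TestPVRConfig:
    def test_defaults_carry_the_procedure_constants(self):
        cfg = oc.PVRConfig()
        assert cfg.k_neighbors == 20
        assert cfg.overlap_samples == 100
        assert cfg.residual_window_trials == 7
        assert cfg.residual_threshold_sd == 4.0
        assert (cfg.blackout_expand_back, cfg.blackout_expand_fwd) == (40, 20)

    @pytest.mark.parametrize("kw", [dict(k_neighbors=1),
                                    dict(residual_window_trials=4),
                                    dict(residual_threshold_sd=0.0)])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            oc.PVRConfig(**kw)


class TestBuildTemplate:
    def test_identical_snippets_give_exact_template(self):
        snips = _identical_snippets(20)
        tpl = oc.build_pulse_template(snips, 0, oc.PVRConfig())
        np.testing.assert_allclose(tpl.onset, snips[0])
        np.testing.assert_allclose(tpl.offset, snips[0])

    def test_two_trace_mean_by_hand(self):
        cfg = oc.PVRConfig(k_neighbors=2)
        x = np.ones((1, 100))
        d = np.zeros((1, 100))
        d[0, 50] = 8.0
        tpl = oc.build_pulse_template([x, x + d], 0, cfg)
        np.testing.assert_allclose(tpl.onset, x + d / 2)
        # residual of the pulse of interest is -d/2
        np.testing.assert_allclose(oc.subtract_template(x, tpl.onset), -d / 2)

    def test_too_few_snippets_instructs_smaller_k(self):
        with pytest.raises(ValueError, match="smaller k"):
            oc.build_pulse_template(_identical_snippets(5), 0, oc.PVRConfig())

    @pytest.mark.parametrize("k", [5, 10, 20])
    def test_spike_attenuated_by_one_over_k(self, k):
        """A spike in one of k averaged snippets shrinks by 1/k (5% at k=20)."""
        cfg = oc.PVRConfig(k_neighbors=k)
        T = 600
        artifact = np.outer([1.0, 0.7], np.hanning(T)) * 2000.0
        snips = [artifact.copy() for _ in range(k)]
        spike = spike_shape(30000.0, 150.0)
        snips[0][0, 300:360] += spike
        tpl = oc.build_pulse_template(snips, 0, cfg)
        merged = oc.merge_onset_offset(
            tpl, T, pulse_duration=T, pre=0, cfg=replace(cfg, overlap_samples=25,
                                                         supersample_factor=4),
        )
        residual = oc.subtract_template(snips[0], merged)
        trough_before = spike.min()
        trough_after = residual[0, 300:360].min()
        attenuation = 1 - trough_after / trough_before
        assert attenuation == pytest.approx(1.0 / k, abs=1e-9)


class TestMergeOnsetOffset:
    def test_overlap_duration_is_3_3_ms(self):
        assert oc.overlap_ms(oc.PVRConfig(), 30000.0) == pytest.approx(3.3, abs=0.05)

    def test_identical_templates_merge_to_either(self):
        x = np.outer([1.0, 2.0], np.linspace(-1, 1, 800))
        tpl = oc.PulseTemplate(x, x, 0)
        merged = oc.merge_onset_offset(tpl, 800, pulse_duration=600, pre=100,
                                       cfg=oc.PVRConfig(overlap_samples=100,
                                                        supersample_factor=1))
        np.testing.assert_allclose(merged, x)

    def test_linear_ramp_across_overlap(self):
        cfg = oc.PVRConfig(overlap_samples=100, supersample_factor=1)
        on = np.zeros((1, 800))
        off = np.ones((1, 800))
        tpl = oc.PulseTemplate(on, off, 0)
        merged = oc.merge_onset_offset(tpl, 800, pulse_duration=600, pre=100, cfg=cfg)
        a = (100 + 300) - 50  # overlap centred on the pulse midpoint
        ramp = merged[0, a:a + 100]
        np.testing.assert_allclose(ramp, np.linspace(0.0, 1.0, 100))
        assert np.all(merged[0, :a] == 0) and np.all(merged[0, a + 100:] == 1)

    def test_pulse_shorter_than_overlap_is_an_error(self):
        x = np.zeros((1, 800))
        tpl = oc.PulseTemplate(x, x, 0)
        with pytest.raises(ValueError, match="overlap"):
            oc.merge_onset_offset(tpl, 800, pulse_duration=50, pre=100,
                                  cfg=oc.PVRConfig(overlap_samples=100,
                                                   supersample_factor=1))


class TestSubtract:
    def test_snippet_equals_template_gives_zero(self):
        x = np.random.default_rng(0).normal(size=(3, 50))
        np.testing.assert_array_equal(oc.subtract_template(x, x), np.zeros_like(x))

    def test_zero_template_is_identity(self):
        x = np.random.default_rng(1).normal(size=(3, 50))
        np.testing.assert_array_equal(oc.subtract_template(x, np.zeros_like(x)), x)

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            oc.subtract_template(np.zeros((2, 10)), np.zeros((2, 11)))

    def test_artifact_energy_reduced_tenfold_in_first_ms(self, desk_session,
                                                         desk_groups, desk_cleaned):
        _, block, _, truth = desk_session
        from optoclean.events import decimate, preprocess
        ms1 = int(0.001 * block.rate)
        pre_rms, post_rms = [], []
        g, res = desk_groups[0], desk_cleaned[0]
        for i, s in enumerate(g.snippets):
            a = s.start_sample
            art = truth.artifact[s.channel_indices, a:a + s.n_samples]
            other = decimate(preprocess(s.data - art, s.rate, 1.0, 4), 4)
            resid_art = res.cleaned[i] - other
            w = slice(s.pre, s.pre + ms1)
            pre_rms.append(np.sqrt((art[:, w] ** 2).mean()))
            post_rms.append(np.sqrt((resid_art[:, w] ** 2).mean()))
        assert np.mean(post_rms) < np.mean(pre_rms) / 10


class TestResidualDetector:
    def _noise_residuals(self, seed=0, n=21, C=2, T=1200):
        rng = np.random.default_rng(seed)
        return [rng.normal(0, 1, (C, T)) for _ in range(n)], np.arange(n, dtype=float)

    def test_noise_false_positive_rate_matches_permutation_oracle(self):
        residuals, inten = self._noise_residuals()
        cfg = oc.PVRConfig()
        observed = oc.detect_residual_pvr(residuals, inten, cfg, 400, 1).total_masked()
        rng = np.random.default_rng(9)
        perm_counts = []
        for _ in range(10):
            order = rng.permutation(len(inten))
            m = oc.detect_residual_pvr([residuals[i] for i in order],
                                       inten, cfg, 400, 1)
            perm_counts.append(m.total_masked())
        assert observed <= max(max(perm_counts), 2)

    def test_shared_transient_flagged_in_adjacent_trials(self):
        residuals, inten = self._noise_residuals(seed=1)
        for j in range(7, 14):  # 7 intensity-adjacent trials
            residuals[j][0, 600:603] += 10.0
        mask = oc.detect_residual_pvr(residuals, inten, oc.PVRConfig(), 400, 1)
        hits = sum(mask.overlaps(j, 0, 595, 610) for j in range(7, 14))
        assert hits >= 6

    def test_single_outlier_trial_excluded_from_window(self):
        residuals, inten = self._noise_residuals(seed=2)
        residuals[10][0, 600] += 50.0
        mask = oc.detect_residual_pvr(residuals, inten, oc.PVRConfig(), 400, 1)
        neighbours = [j for j in range(len(residuals)) if j != 10]
        assert not any(mask.overlaps(j, 0, 595, 610) for j in neighbours)

    def test_mask_monotone_in_threshold(self):
        residuals, inten = self._noise_residuals(seed=3)
        for j in range(5, 14):
            residuals[j][1, 700:704] += 6.0
        cfg4 = oc.PVRConfig()
        cfg5 = replace(cfg4, residual_threshold_sd=5.0)
        m4 = oc.detect_residual_pvr(residuals, inten, cfg4, 400, 1)
        m5 = oc.detect_residual_pvr(residuals, inten, cfg5, 400, 1)
        assert m5.issubset(m4)

    def test_too_few_trials_is_an_error(self):
        residuals, inten = self._noise_residuals(n=5)
        with pytest.raises(ValueError, match="fewer"):
            oc.detect_residual_pvr(residuals, inten, oc.PVRConfig(), 400, 1)

    def test_window_shrinks_symmetrically_never_below_three(self):
        n = 21
        for j in range(n):
            lo, hi = _window_bounds(j, n, 3)
            assert 3 <= hi - lo <= 7
            assert 0 <= lo and hi <= n
            if 3 <= j <= n - 4:
                assert (lo, hi) == (j - 3, j + 4)


class TestBlackoutMask:
    def test_single_sample_expansion(self):
        mask = BlackoutMask(1, 1, 3000)
        mask.add(0, 0, 1000, 1001)
        out = oc.expand_blackout(mask, oc.PVRConfig())
        assert out.intervals(0, 0) == [(960, 1021)]

    def test_empty_mask_stays_empty(self):
        mask = BlackoutMask(2, 3, 500)
        assert oc.expand_blackout(mask, oc.PVRConfig()).is_empty()

    def test_nearby_intervals_merge_after_expansion(self):
        mask = BlackoutMask(1, 1, 3000)
        mask.add(0, 0, 1000, 1010)
        mask.add(0, 0, 1040, 1050)  # 30 samples apart
        out = oc.expand_blackout(mask, oc.PVRConfig())
        assert out.intervals(0, 0) == [(960, 1070)]

    def test_expansion_clipped_to_snippet(self):
        mask = BlackoutMask(1, 1, 100)
        mask.add(0, 0, 5, 95)
        out = mask.expanded(40, 20)
        assert out.intervals(0, 0) == [(0, 100)]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 900), st.integers(1, 80)),
                    min_size=1, max_size=10))
    def test_expansion_is_superset_and_normalized(self, raw):
        mask = BlackoutMask(1, 1, 1000)
        for a, w in raw:
            mask.add(0, 0, a, min(a + w, 1000))
        out = mask.expanded(40, 20)
        assert mask.issubset(out)
        iv = out.intervals(0, 0)
        assert all(b > a for a, b in iv)
        assert all(iv[i + 1][0] > iv[i][1] for i in range(len(iv) - 1))
        assert all(0 <= a and b <= 1000 for a, b in iv)

    def test_masking_does_not_alter_unmasked_values(self, desk_cleaned):
        res = desk_cleaned[0]
        arr = res.cleaned[0]
        m = res.expanded_mask.masked_array(0)
        assert np.all(np.isfinite(arr[~m[:, :arr.shape[1]]]))
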