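"""Built-in sorting, template-matching spike recovery and weighted PSTHs."""
from dataclasses import replace

import numpy as np
import pytest

import optoclean as oc
from optoclean.artifact import BlackoutMask
from optoclean.spikes import WIN_PRE, WIN_POST, detect_threshold_events, _curate
from optoclean.synth import spike_shape

from conftest import desk_config, shank_restricted_units, truth_primary_channels


def _unit(waveform, uid=0):
    w = np.atleast_2d(waveform)
    return oc.UnitTemplate(waveform=w, unit_id=uid,
                           primary_channel=int(np.unravel_index(
                               np.argmin(w), w.shape)[0]))


def _empty_mask(n, C, T):
    return BlackoutMask(n, C, T)


class TestSorter:
    def test_cluster_budget_is_twice_the_channel_count(self):
        assert oc.SorterConfig().clusters_per_channel * 32 == 64

    def test_oversized_trough_removed_by_curation(self):
        w = np.zeros((4, 60))
        w[1] = spike_shape(30000.0, 450.0)
        assert not _curate(w, oc.SorterConfig())
        w2 = np.zeros((4, 60))
        w2[1] = spike_shape(30000.0, 150.0)
        assert _curate(w2, oc.SorterConfig())

    def test_artifact_signature_removed_by_curation(self):
        # large positive deflections on >= 3 channels at the trough sample
        w = np.zeros((4, 60))
        w[1] = spike_shape(30000.0, 100.0)
        w[[0, 2, 3], 20] = 50.0
        assert not _curate(w, oc.SorterConfig())

    def test_two_separated_units_sorted_with_high_accuracy(self):
        cfg = desk_config(seed=5, scenario_name="artifact-free", n_units=2,
                          trough_range_uv=(120.0, 180.0), fibers=1,
                          n_pulses=100)
        block, light, truth = oc.generate_session(cfg)
        pulses = oc.detect_pulses(light, rate=block.rate)
        units, events = oc.sort_interpulse(block, pulses, return_events=True)
        all_t = np.concatenate(truth.spike_times)
        all_u = np.concatenate([[u] * len(t)
                                for u, t in enumerate(truth.spike_times)])
        order = np.argsort(all_t)
        all_t, all_u = all_t[order], all_u[order]
        confusion = {}
        for t, uid in events:
            i = int(np.argmin(np.abs(all_t - t)))
            if abs(all_t[i] - t) <= 3:
                confusion[(uid, all_u[i])] = confusion.get((uid, all_u[i]), 0) + 1
        total = sum(confusion.values())
        # majority mapping of sorted -> true units
        best = {}
        for (uid, tu), n in confusion.items():
            if n > best.get(uid, (None, 0))[1]:
                best[uid] = (tu, n)
        correct = sum(n for uid, (tu, _) in best.items()
                      for (u2, t2), n in confusion.items()
                      if u2 == uid and t2 == tu)
        assert total > 20
        assert correct / total >= 0.95

    def test_no_interpulse_data_is_an_error(self):
        block = oc.RecordingBlock(np.zeros((2, 3000)), rate=30000.0)
        pulses = [oc.PulseEvent(1000, 2000, 0, 1.0)]
        with pytest.raises(ValueError, match="inter-pulse"):
            oc.sort_interpulse(block, pulses)


class TestMatchSpikes:
    def test_pure_waveform_self_match(self):
        # snippet that is exactly one unit's waveform plus zeros
        C, T = 3, 1200
        w = np.zeros((C, 60))
        w[1] = spike_shape(30000.0, 150.0)
        w[0] = w[2] = 0.5 * w[1]
        data = np.zeros((C, T))
        data[:, 600 - WIN_PRE:600 + WIN_POST] += w
        events = oc.match_spikes([data], _empty_mask(1, C, T),
                                 _empty_mask(1, C, T), [_unit(w)])
        assert len(events) == 1
        e = events[0]
        assert e.time_sample == 600
        assert e.unit_id == 0 and e.valid
        assert e.error == pytest.approx(0.0, abs=1e-12)

    def test_noisy_self_match_error_below_threshold(self):
        rng = np.random.default_rng(0)
        C, T = 3, 1200
        w = np.zeros((C, 60))
        w[1] = spike_shape(30000.0, 150.0)
        w[0] = w[2] = 0.5 * w[1]
        data = rng.normal(0, 5.0, (C, T))
        data[:, 600 - WIN_PRE:600 + WIN_POST] += w
        events = oc.match_spikes([data], _empty_mask(1, C, T),
                                 _empty_mask(1, C, T), [_unit(w)])
        assert len(events) == 1
        e = events[0]
        assert abs(e.time_sample - 600) <= 2
        assert e.error < 1.0

    def test_event_window_on_blackout_is_invalid(self):
        rng = np.random.default_rng(1)
        C, T = 3, 1200
        w = np.zeros((C, 60))
        w[1] = spike_shape(30000.0, 150.0)
        data = rng.normal(0, 5.0, (C, T))
        data[:, 600 - WIN_PRE:600 + WIN_POST] += w
        raw = _empty_mask(1, C, T)
        expanded = BlackoutMask(1, C, T)
        expanded.add(0, 1, 630, 660)  # inside the spike window
        events = oc.match_spikes([data], raw, expanded, [_unit(w)])
        assert len(events) == 1
        assert not events[0].valid

    def test_fully_masked_snippet_yields_no_events(self, caplog):
        C, T = 2, 600
        full = BlackoutMask(1, C, T)
        full.add(0, 0, 0, T)
        full.add(0, 1, 0, T)
        with caplog.at_level("WARNING"):
            events = oc.match_spikes([np.zeros((C, T))], full, full,
                                     [_unit(np.tile(spike_shape(30000., 100.), (2, 1)))])
        assert events == []
        assert any("entirely masked" in r.message for r in caplog.records)

    def test_recovery_f1_against_ground_truth(self, desk_session, desk_groups,
                                              desk_cleaned, desk_matches):
        from conftest import score_recovery
        _, block, _, truth = desk_session
        precision, recall, f1 = score_recovery(block, truth, desk_groups,
                                               desk_cleaned, desk_matches)
        assert f1 >= 0.9

    def test_no_valid_spike_window_intersects_expanded_mask(self, desk_cleaned,
                                                            desk_matches):
        """Hard invariant over every recovered spike: valid is True exactly
        when the -20/+40 window on the matched channels avoids the mask."""
        checked = 0
        for res, (snips, events) in zip(desk_cleaned, desk_matches):
            for e in events:
                C = snips[e.snippet_index].n_channels
                chans = range(max(0, e.channel - 1), min(C, e.channel + 2))
                hit = res.expanded_mask.overlaps(
                    e.snippet_index, chans,
                    e.time_sample - WIN_PRE, e.time_sample + WIN_POST,
                )
                assert e.valid == (not hit)
                checked += 1
        assert checked > 100

    def test_matching_is_deterministic(self, desk_groups, desk_cleaned, desk_units):
        g, res = desk_groups[0], desk_cleaned[0]
        snips = [replace(s, data=arr) for s, arr in zip(g.snippets, res.cleaned)]
        gunits = shank_restricted_units(desk_units, g)
        e1 = oc.match_spikes(snips, res.mask, res.expanded_mask, gunits)
        e2 = oc.match_spikes(snips, res.mask, res.expanded_mask, gunits)
        assert e1 == e2

    def test_scaling_recording_and_units_together_is_invariant(
            self, desk_groups, desk_cleaned, desk_units):
        g, res = desk_groups[0], desk_cleaned[0]
        snips = [replace(s, data=arr) for s, arr in zip(g.snippets, res.cleaned)]
        gunits = shank_restricted_units(desk_units, g)
        ref = oc.match_spikes(snips, res.mask, res.expanded_mask, gunits)
        for c in (0.5, 3.0):
            snips_c = [replace(s, data=s.data * c) for s in snips]
            units_c = [replace(u, waveform=u.waveform * c,
                               channel_scale=u.channel_scale * c) for u in gunits]
            got = oc.match_spikes(snips_c, res.mask, res.expanded_mask, units_c)
            assert [(e.time_sample, e.unit_id, e.valid) for e in got] == \
                   [(e.time_sample, e.unit_id, e.valid) for e in ref]

    def test_agreement_with_threshold_detection_on_artifact_free_data(self):
        """Inside pulse windows of artifact-free data, template matching finds
        what plain -30 µV threshold detection finds on the same traces."""
        cfg = desk_config(seed=2, scenario_name="artifact-free", n_pulses=100)
        block, light, truth = oc.generate_session(cfg)
        pulses = oc.detect_pulses(light, rate=block.rate)
        units = oc.sort_interpulse(block, pulses)
        g = oc.extract_snippets(block, pulses)[0]
        res = oc.clean_group(g)
        snips = [replace(s, data=arr) for s, arr in zip(g.snippets, res.cleaned)]
        gunits = shank_restricted_units(units, g)
        events = oc.match_spikes(snips, res.mask, res.expanded_mask, gunits)
        tp = fp = fn = 0
        for si, s in enumerate(snips):
            det, _, _ = detect_threshold_events(s.data, -30.0, 20)
            det = np.array(sorted(t for t in det
                                  if WIN_PRE <= t < s.n_samples - WIN_POST))
            used = np.zeros(len(det), dtype=bool)
            for t in sorted(e.time_sample for e in events
                            if e.snippet_index == si):
                d = np.abs(det - t) if len(det) else np.array([np.inf])
                i = int(np.argmin(d))
                if len(det) and d[i] <= 5 and not used[i]:
                    used[i] = True
                    tp += 1
                else:
                    fp += 1
            fn += int((~used).sum())
        p = tp / max(tp + fp, 1)
        r = tp / max(tp + fn, 1)
        f1 = 2 * p * r / max(p + r, 1e-12)
        assert f1 >= 0.95

    def test_no_units_is_an_error(self):
        with pytest.raises(ValueError, match="unit"):
            oc.match_spikes([np.zeros((2, 100))], _empty_mask(1, 2, 100),
                            _empty_mask(1, 2, 100), [])


class TestWeightedPSTH:
    def _snippets(self, n_trials=8, C=2, dur=300, pre=900, post=900):
        T = dur + pre + post
        snips = []
        for i in range(n_trials):
            pulse = oc.PulseEvent(10000 + i * 3000, 10000 + i * 3000 + dur, 0, 1.0, 0)
            snips.append(oc.Snippet(pulse, np.zeros((C, T)), pre, post, 30000.0,
                                    pulse.onset_sample - pre, np.arange(C)))
        return snips

    def _event(self, si, t, valid=True):
        return oc.SpikeEvent(si, t, 0, 0, 0.1, valid)

    def test_no_blackout_equals_plain_psth(self):
        snips = self._snippets()
        T = snips[0].n_samples
        # one spike per trial, 5 ms after onset
        events = [self._event(i, snips[i].pre + 150) for i in range(len(snips))]
        mask = BlackoutMask(len(snips), 2, T)
        psth = oc.weighted_psth(events, mask, snips, bin_ms=1.0)
        b = int(np.argmin(np.abs(psth.bin_edges_ms[:-1] - 5.0)))
        assert psth.rate_hz[b] == pytest.approx(1000.0)  # 1 spike / 1 ms / trial
        assert np.all(psth.pct_masked_trials == 0)

    def test_half_masked_bin(self):
        snips = self._snippets(n_trials=8)
        T = snips[0].n_samples
        mask = BlackoutMask(len(snips), 2, T)
        # mask the bin at +5 ms in half the trials
        for i in range(4):
            mask.add(i, 0, snips[i].pre + 150, snips[i].pre + 180)
        events = [self._event(i, snips[i].pre + 150) for i in range(4, 8)]
        psth = oc.weighted_psth(events, mask, snips, bin_ms=1.0)
        b = int(np.argmin(np.abs(psth.bin_edges_ms[:-1] - 5.0)))
        assert psth.pct_masked_trials[b] == pytest.approx(50.0)
        assert psth.rate_hz[b] == pytest.approx(1000.0)  # mean over unmasked half

    def test_fully_masked_bin_is_undefined_and_isolated(self):
        snips = self._snippets(n_trials=4)
        T = snips[0].n_samples
        mask = BlackoutMask(len(snips), 2, T)
        for i in range(4):
            mask.add(i, 1, snips[i].pre + 150, snips[i].pre + 151)
        psth = oc.weighted_psth([], mask, snips, bin_ms=1.0)
        b = int(np.argmin(np.abs(psth.bin_edges_ms[:-1] - 5.0)))
        assert np.isnan(psth.rate_hz[b])
        assert psth.undefined_bins[b]
        assert not psth.undefined_bins[b - 2] and not psth.undefined_bins[b + 2]

    def test_invalid_spikes_are_not_counted(self):
        snips = self._snippets(n_trials=4)
        mask = BlackoutMask(len(snips), 2, snips[0].n_samples)
        events = [self._event(i, snips[i].pre + 150, valid=False) for i in range(4)]
        psth = oc.weighted_psth(events, mask, snips, bin_ms=1.0)
        assert np.nansum(psth.rate_hz) == 0

    def test_no_trials_is_an_error(self):
        with pytest.raises(ValueError, match="trials"):
            oc.weighted_psth([], BlackoutMask(0, 1, []), [], 1.0)
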