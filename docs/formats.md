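# File formats

All binary payloads are little-endian and carry a JSON sidecar with the same
stem (`name.bin` + `name.json`). Tables are plain CSV with a header row.

## Trace (`optoclean-trace`)

Used for recordings and light logs. The `.bin` file is sample-major: frame 0
(all channels at t=0), frame 1, …

Sidecar fields:

| field | meaning |
|---|---|
| `format` | `"optoclean-trace"` |
| `version` | format version (1) |
| `kind` | `"recording"` or `"light"` |
| `dtype` | `"float32"` or `"int16"` |
| `layout` | `"sample_major"` |
| `uv_per_unit` | µV per stored unit (int16 scaling; 1.0 for float32) |
| `rate_hz` | sampling rate (`null` for a light log on the recording timebase) |
| `n_channels`, `n_samples` | matrix shape |
| `channel_positions_um` | per-channel depth along the shank (recordings) |
| `shank_ids` | per-channel shank id (recordings) |
| `fiber_ids` | per-trace fiber id (light logs) |

## Pulse events (CSV)

`fiber_id, shank_id, onset_sample, offset_sample, intensity_summary` —
0-based half-open sample intervals at the recording rate; `shank_id` is −1
when the pulse is not bound to a shank; `intensity_summary` is the peak
photodiode value during the pulse.

## Blackout mask (CSV)

`snippet_id, channel, start_sample, end_sample` — half-open base-rate
intervals, snippet-relative, merged and sorted.

## Spike events (CSV)

`snippet_id, time_sample, block_sample, unit_id, channel, error, valid` —
`time_sample` snippet-relative, `block_sample` absolute; `error` is the
matching mean squared error in normalized units; `valid` is 0/1.

## PSTH (CSV)

`bin_start_ms, bin_end_ms, rate_hz, pct_masked_trials` — bin edges relative
to light onset; `rate_hz` empty (NaN) where all trials are masked;
`pct_masked_trials` is the per-bin percentage of blacked-out trials.

## Unit templates (`optoclean-units`)

`.bin`: float32 array of shape `(n_units, n_channels, 60)` (waveforms in µV,
trough at sample 20). Sidecar: `unit_ids`, `primary_channels`,
`channel_scale` (per-unit, per-channel SD of the source data), `n_spikes`.

## Snippet stacks (`optoclean-snippets`)

`.bin`: float32 array of shape `(n_snippets, n_channels, n_samples)`;
sidecar carries `shape` plus free-form metadata (e.g. `fiber_id`,
`shank_id`).

## Run manifest (`manifest.json`)

`seed`, the full configuration snapshot, and per-stage entries
`{"key": <config+input digest>, "outputs": {filename: sha256}}` — enough to
re-execute any stage bit-reproducibly and to resume unchanged stages.
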