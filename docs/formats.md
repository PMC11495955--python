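# File formats

All tables are comma-separated text with a header row, UTF-8, `.` decimal.
Results and generating truths are JSON.  Readers are strict: missing
columns or non-numeric cells fail with row/column context; unknown extra
columns warn.

## Track (`track.csv`)

| column  | type  | meaning                                   |
|---------|-------|-------------------------------------------|
| time_s  | float | seconds from CEE start, strictly increasing |
| x_m     | float | local planar easting, metres               |
| y_m     | float | local planar northing, metres              |

## Block table (`blocks.csv`)

| column      | type  | meaning                                             |
|-------------|-------|-----------------------------------------------------|
| block_index | int   | index on the 5 s block grid                         |
| phase       | str   | `pre`, `exp` or `post`                              |
| metric      | str   | response name (`whistles`, `subgroups`); optional in single-metric files |
| value       | float | response value; empty iff unobserved                |
| observed    | 0/1   | whether the block was scored                        |

## Ping log (`pings.csv`)

| column      | type  | meaning                                        |
|-------------|-------|------------------------------------------------|
| time_s      | float | ping start, seconds from CEE start             |
| range_m     | float | source to focal-group centre, metres           |
| spl_db      | float | received level, dB re 1 uPa (RMS)              |
| sel_db      | float | per-ping sound exposure level, dB re 1 uPa^2 s |
| transmitted | 0/1   | 0 for mock pings of control CEEs               |

Per-ping duration is implied by `sel_db - spl_db = 10 log10(duration)`.

## Manifest (`manifest.json`)

```json
{
  "cee_id": "sim_01",
  "subspecies": "short_beaked",        // or long_beaked
  "cee_type": "mfas_sim",              // mfas_sim | mfas_navy | control
  "schedule": {"pre_dur": 600, "exp_dur": 600, "post_dur": 600,
               "block_dur": 5},
  "track": "track.csv",
  "blocks": "blocks.csv",
  "pings": "pings.csv",
  "flags": {"uas": true, "pam": true, "subgroup": true}
}
```

`flags` mark data availability per stream (drone track, passive acoustics,
visual subgroup scans); a CEE with a flag off is excluded from that
metric's detection denominators.

## Covariate table for the exposure-response regression

| column          | type  | meaning                                   |
|-----------------|-------|-------------------------------------------|
| cee_id          | str   | CEE identifier                            |
| p_response_move | float | movement response probability, in [0, 1]  |
| rl_max          | float | maximum per-ping received level, dB RMS   |
| v1              | float | pre-exposure mean group speed, km/h       |

## Results (`results.json`)

A list of per-CEE, per-metric summaries: phase means with posterior sds,
response/persistence probabilities with directions, detection flags,
per-parameter potential scale reduction factors, and the MCMC
configuration (including all seeds).  `truth.json` stores the generating
parameters and latent states of simulated CEEs for recovery testing.
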