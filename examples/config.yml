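# Example pipeline configuration for `avi-forage all --config examples/config.yml`
out_dir: out
seed: 1
bin_width: 1.0

conditions: [Wall, Mirror, Stranger]
comparisons:
  - [Wall, Mirror]
  - [Wall, Stranger]
  - [Mirror, Stranger]

arena:
  width: 60.0
  depth: 50.0
  feeder_center: [54.0, 46.0]
  entrance: [6.0, 5.0]
  px_per_cm: 10.0
  feeder_zone_radius: 8.0

preprocessing:
  trim_seconds: 2.0
  likelihood_threshold: 0.6
  max_gap_seconds: 0.5
  loess_window_seconds: 0.3
  min_bout_seconds: 0.3

mcmc:
  draws: 1000
  warmup: 1000
  chains: 4

# synthetic study design used by the `simulate` / `all` subcommands;
# omit this section when analyzing real tracking data via `manifest:`
sim:
  n_birds: 4
  conditions: [Wall, Mirror, Stranger]
  n_sessions: 3
  session_length: 120.0
  fps: 10.0
  latency_mean:
    Wall: [20, 14, 10]
    Mirror: [40, 25, 16]
    Stranger: [26, 16, 11]
  seed: 1
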