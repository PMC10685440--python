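# Demo campaign for `ensuq run --config examples/demo_config.yaml --out-dir out`
# Nine synthetic 100-replica systems spanning skew, heavy tails and
# bimodality; runs the full pipeline on one CPU in well under five minutes.
seed: 2024
n_boot: 10000
confidence: 0.95
out_dir: out

stages: [stats, convergence, protocols, adapt]

inputs:
  - label: a
    synthetic: {family: skew_normal, location: -10.0, scale: 1.0, shape: -5.0,
                n_replicas: 100, frames_per_replica: 20, frame_interval_ns: 0.5,
                seed: 2025}
  - label: b
    synthetic: {family: mixture,
                components: [[0.5, -11.5, 0.6], [0.5, -8.5, 0.6]],
                n_replicas: 100, frames_per_replica: 20, frame_interval_ns: 0.5,
                seed: 2026}
  - label: c
    synthetic: {family: student_t, location: -10.0, scale: 0.8, dof: 4.5,
                n_replicas: 100, frames_per_replica: 20, frame_interval_ns: 0.5,
                seed: 2027}
  - label: d
    synthetic: {family: skew_normal, location: -10.0, scale: 1.2, shape: 10.0,
                n_replicas: 100, frames_per_replica: 20, frame_interval_ns: 0.5,
                seed: 2028}
  - label: e
    synthetic: {family: gaussian, location: -10.0, scale: 0.3,
                between_replica_sd: 1.0,
                n_replicas: 100, frames_per_replica: 20, frame_interval_ns: 0.5,
                seed: 2029}
  - label: f
    synthetic: {family: skew_normal, location: -10.0, scale: 1.0, shape: 2.0,
                n_replicas: 100, frames_per_replica: 20, frame_interval_ns: 0.5,
                seed: 2030}
  - label: g
    synthetic: {family: mixture, per_replica_modes: true,
                components: [[0.5, -12.0, 0.4], [0.5, -8.0, 0.4]],
                n_replicas: 100, frames_per_replica: 20, frame_interval_ns: 0.5,
                seed: 2031}
  - label: h
    synthetic: {family: gaussian, location: -10.0, scale: 1.0, ar1_rho: 0.5,
                n_replicas: 100, frames_per_replica: 20, frame_interval_ns: 0.5,
                seed: 2032}
  - label: i
    synthetic: {family: mixture,
                components: [[0.5, -10.8, 0.7], [0.5, -9.2, 0.7]],
                n_replicas: 100, frames_per_replica: 20, frame_interval_ns: 0.5,
                seed: 2033}

protocols:
  budget_ns: 60.0
  candidates: [1, 6, 12, 20, 30, 60]
  min_replicas: 2
  min_duration_ns: 2.0
  confidence: 0.67
  n_subset_draws: 1

adapt:
  style: esmacs
  threshold: 0.5
  batch_size: 5
  max_n: 100
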