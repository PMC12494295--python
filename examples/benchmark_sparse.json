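{
  "experiment": "benchmark_sparse",
  "master_seed": 1,
  "benchmark_scale": 0.1,
  "output_dir": "runs/benchmark_sparse",
  "simulation": {"duration_ms": 2000.0, "warmup_ms": 500.0}
}
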