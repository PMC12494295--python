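{
  "experiment": "block_async",
  "master_seed": 1,
  "output_dir": "runs/block_async",
  "simulation": {"duration_ms": 60000.0, "warmup_ms": 5000.0}
}
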