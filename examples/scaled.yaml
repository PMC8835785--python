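# Scaled-down replication protocol: ~1 minute on one CPU.
population_size: 200
generations: 20000
record_every: 100
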