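# pipeline config for the packaged fixture; input paths are filled in by
# the test/CLI relative to this directory
alpha: 0.05
top_k: 3
min_ancestries: 4
prior_sd: 0.2
pp_threshold: 0.80
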