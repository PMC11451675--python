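# run the packaged synthetic fixture study from the repository root
inputs:
  EUR: tests/data/fixture/EUR.tsv
  AFR: tests/data/fixture/AFR.tsv
  EAS: tests/data/fixture/EAS.tsv
  AMR: tests/data/fixture/AMR.tsv
out_dir: fixture_results
alpha: 0.05
top_k: 3
min_ancestries: 4
prior_sd: 0.2
pp_threshold: 0.80
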