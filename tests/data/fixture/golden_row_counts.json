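{"input": 32, "harmonized": 32, "filtered": 28, "selected": 9, "par": 9, "finemap": 28, "ranks": 9, "classification": 3}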