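{"micro_seq_snp_count": 185}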