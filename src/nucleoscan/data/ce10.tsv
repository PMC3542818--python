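chrI	15072423
chrII	15279345
chrIII	13783700
chrIV	17493793
chrV	20924149
chrX	17718866
chrM	13794
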