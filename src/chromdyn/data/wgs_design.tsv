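population	status	n_samples
Asian	wild	58
Asian	domestic	129
European	wild	35
European	domestic	184
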