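# catchment sampling counts not derivable from person-level rows
n_sampled_not_meeting: 113
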