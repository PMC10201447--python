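cosolute	wt_pct	delta_aw
PEG200	40	0.0489
ethylene glycol	20	0.047
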