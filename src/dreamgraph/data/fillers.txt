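# filled-pause tokens removed by the TRC word-count proxy
um
uh
ah
er
erm
uhm
mm
hmm
mhm
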