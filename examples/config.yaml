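# reduced-scale demonstration run (see docs/methods.md for defaults)
fixture: three_well
n_steps: 8000
n_frames: 600
pore_measure_frames: 60
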