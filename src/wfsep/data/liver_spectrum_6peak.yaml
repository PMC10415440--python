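# Six-peak liver fat spectrum (triglyceride model).
# Chemical-shift offsets are relative to the water resonance (4.7 ppm);
# negative offsets resonate below water.  Relative amplitudes sum to 1.
name: liver_6peak
ppm_offsets: [-3.80, -3.40, -2.60, -1.94, -0.39, 0.60]
relative_amplitudes: [0.087, 0.693, 0.128, 0.004, 0.039, 0.048]
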