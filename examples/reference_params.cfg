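# Reference homobivalent rate parameters (PICK1-like dimer).
# k2 is derived as k1*[L](r)/f = 0.136 /min unless overridden here.
k1_per_M_min: 1.85e5
k_off_per_min: 0.0085
r_angstrom: 180
f: 185
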