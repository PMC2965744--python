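# Bead radii (nm) for SASA.  CG beads default to 0.235 nm, half the standard
# 0.47 nm bead diameter; individual bead names may override (glob patterns).
default 0.235
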