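# Per-generation vessel counts for the cine-angiogram phantoms.
#
# Counts are visible vessels per branching generation (1st-3rd) in one
# projection.  The hyperoxia profile encodes the reported losses
# (about -18 % in generation 2, -21 % in generation 3); IL-1Ra largely
# rescues generations 2-3.  Absolute counts are free parameters.
# Every parent spawns 0, 2 or 3 children so that branch points remain
# topologically unambiguous in a projected skeleton.
conditions:
  air_vehicle:
    counts: [6, 17, 34]
  hyperoxia_vehicle:
    counts: [5, 14, 27]
  hyperoxia_il1ra:
    counts: [6, 16, 33]
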