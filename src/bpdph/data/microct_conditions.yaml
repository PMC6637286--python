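# Condition profiles for the micro-CT vascular phantoms.
#
# Bin edges follow the analysis convention: small vessels 4-7 um in 1-um
# bins, medium vessels 7-30 um in coarser bins; vessels under 4 um are
# below the resolution cutoff and never generated or counted.
#
# Absolute expected counts per 128^3 volume are free parameters (the
# source data report normalized, not absolute, counts); the hyperoxia
# profile is expressed as per-bin multiplicative depletion relative to
# the air reference.  Small-bin depletions encode the reported -84/-83/
# -76 % losses; medium-bin depletions follow the reported monotone
# relaxation of the loss with increasing diameter.
bin_edges_um: [4, 5, 6, 7, 10, 15, 20, 30]
reference: air_vehicle
conditions:
  air_vehicle:
    expected_counts: [40, 32, 26, 30, 18, 8, 4]
  hyperoxia_vehicle:
    depletion: [0.16, 0.17, 0.24, 0.50, 0.60, 0.70, 0.80]
  hyperoxia_il1ra:
    depletion: [0.80, 0.85, 0.90, 0.92, 0.95, 0.97, 1.00]
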