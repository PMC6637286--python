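# Sirius-Red-style cardiac histology phantom profiles.
#
# Only the 2.2-fold hyperoxia/air ratio of collagen fractions is
# reported; absolute fractions (of non-vessel myocardium) are free
# parameters set to plausible interstitial-collagen levels.  The IL-1Ra
# fraction reflects the partial, non-significant reduction.
# specimen_cv is the between-animal coefficient of variation applied by
# the analysis drivers when simulating a group of sections.
conditions:
  air_vehicle:
    collagen_fraction: 0.040
  hyperoxia_vehicle:
    collagen_fraction: 0.088   # 2.2-fold vs air
  hyperoxia_il1ra:
    collagen_fraction: 0.058
vessel_fraction: 0.05
specimen_cv: 0.06
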