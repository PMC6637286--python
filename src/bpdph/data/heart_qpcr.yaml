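# Group-mean CT fixture for the whole-heart qPCR phantoms.
#
# Actb is flat across groups (the stably expressed housekeeping gene).
# Target CT offsets encode the reported group fold changes relative to
# air vehicle (Lgals3 2.9x and Ccl2 1.8x in hyperoxia vehicle; the
# IL-1Ra group carries the reported partial reversals: Lgals3 increase
# halved, Ccl2 -59 % and Nppb -39 % versus hyperoxia vehicle).
# Absolute CT levels are free parameters.
housekeeping: Actb
housekeeping_candidates: [Actb, Gapdh]
group_means_ct:
  air_vehicle:
    Actb: 18.0
    Gapdh: 19.0
    Lgals3: 26.0
    Ccl2: 27.0
    Nppb: 24.0
  hyperoxia_vehicle:
    Actb: 18.0
    Gapdh: 19.1
    Lgals3: 24.463947    # 2.9-fold up vs air
    Ccl2: 26.152003      # 1.8-fold up vs air
    Nppb: 24.0
  hyperoxia_il1ra:
    Actb: 18.0
    Gapdh: 18.9
    Lgals3: 25.463947    # increase halved (1.45-fold vs air)
    Ccl2: 27.438          # 0.738-fold vs air (-59 % vs hyperoxia)
    Nppb: 24.713          # 0.61-fold vs air (-39 % vs hyperoxia)
default_noise_sd: 0.25
default_n_per_group: 8
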