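# Concentration-response profiles for the PCLS intrapulmonary-artery
# phantoms.  Areas are % of initial lumen area (bottom = no drug = 100).
#
# Maxima reproduce the reported 43 % (ET-1) and 38 % (U46619) reductions;
# log EC50 values are one log unit apart per the ~10-fold potency
# difference, with ET-1 at 10 nM (inside its 1-100 nM perfusion range,
# consistent with 100 nM being maximally effective).  Hill slope 1
# (single-receptor agonism; not reported).
profiles:
  et1:
    bottom_pct: 100.0
    top_pct: 57.0          # 43 % maximal reduction
    log_ec50: -8.0         # 10 nM
    hill: 1.0
    concentrations_nm: [1.0, 2.5, 6.3, 16.0, 40.0, 100.0]
  u46619:
    bottom_pct: 100.0
    top_pct: 62.0          # 38 % maximal reduction
    log_ec50: -7.0         # 100 nM
    hill: 1.0
    concentrations_nm: [3.0, 10.0, 30.0, 100.0, 300.0, 1000.0]
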