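# Diisocyanate species registry.
# Molecular weights are computed from the molecular formulas with standard
# atomic masses (C 12.011, H 1.008, N 14.007, O 15.999); one NCO group
# weighs 42.017 g/mol.
nco_group_mass: 42.017
species:
  MDI:
    formula: C15H10N2O2
    molecular_weight: 250.25
    n_nco_groups: 2
    metabolite: MDA
  TDI:
    formula: C9H6N2O2
    molecular_weight: 174.16
    n_nco_groups: 2
    metabolite: TDA
  HDI:
    formula: C8H12N2O2
    molecular_weight: 168.20
    n_nco_groups: 2
    metabolite: HDA
  IPDI:
    formula: C12H18N2O2
    molecular_weight: 222.28
    n_nco_groups: 2
    metabolite: IPDA
# Occupational exposure limits, ug NCO/m3.
oel:
  short_term_fi: 35.0
  proposed_boel: 10.0
  proposed_boel_2029: 6.0
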