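{
  "_comment": "Bound coherent neutron scattering lengths (fm) and standard atomic masses (g/mol). Values from the Sears neutron-scattering-length compilation (Neutron News 3, 26 (1992)); D is 2H. Bundled so that solvent/surfactant SLD arithmetic is reproducible without an external database.",
  "elements": {
    "H":  {"b_coh_fm": -3.7390, "mass": 1.00794},
    "D":  {"b_coh_fm": 6.671,   "mass": 2.014102},
    "C":  {"b_coh_fm": 6.6460,  "mass": 12.0107},
    "N":  {"b_coh_fm": 9.36,    "mass": 14.0067},
    "O":  {"b_coh_fm": 5.803,   "mass": 15.9994},
    "Na": {"b_coh_fm": 3.63,    "mass": 22.98977},
    "Mg": {"b_coh_fm": 5.375,   "mass": 24.305},
    "P":  {"b_coh_fm": 5.13,    "mass": 30.97376},
    "S":  {"b_coh_fm": 2.847,   "mass": 32.065},
    "Si": {"b_coh_fm": 4.1491,  "mass": 28.0855},
    "K":  {"b_coh_fm": 3.67,    "mass": 39.0983},
    "Ca": {"b_coh_fm": 4.70,    "mass": 40.078},
    "Cl": {"b_coh_fm": 9.5770,  "mass": 35.453}
  }
}
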