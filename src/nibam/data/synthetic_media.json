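{
  "version": "1.0",
  "note": "Minor-ion defaults for synthetic test waters and for target waters specified only by pH/DOC/hardness. Loosely follows standard reconstituted-freshwater recipes (e.g. US EPA moderately hard water, OECD 202 medium), where alkalinity and sulfate co-vary with hardness while Na, K and Cl sit at fixed background levels.",
  "minor_ions": {
    "na_mol_l": 5.0e-04,
    "k_mol_l": 5.0e-05,
    "cl_mol_l": 5.0e-04,
    "so4_fraction_of_ca_plus_mg": 0.3,
    "alkalinity_mg_caco3_per_mg_hardness": 0.8
  }
}
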