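{
  "version": "1.0",
  "reference_temperature_c": 25.0,
  "note": "Infinite-dilution formation constants (log10 K) for the reference inorganic speciation engine, 25 degC. Values are rounded critical-compilation constants (NIST SRD 46 / Smith & Martell style). Activity corrections via the Davies equation are applied at run time, so constants here are thermodynamic (I=0).",
  "carbonate_system": {
    "pk1_h2co3": 6.352,
    "pk2_hco3": 10.329,
    "pkw": 13.997,
    "log_kh_co2_mol_per_l_atm": -1.47,
    "pco2_atm": 0.000415,
    "source": "Plummer & Busenberg (1982) carbonate constants; Kw CODATA; present-day atmospheric pCO2"
  },
  "reactions": {
    "NiOH+":    {"components": ["Ni2+", "OH-"],    "log_k": 4.14, "source": "NIST SRD 46"},
    "Ni(OH)2":  {"components": ["Ni2+", "2 OH-"],  "log_k": 9.00, "source": "NIST SRD 46 (cumulative beta2)"},
    "NiCO3":    {"components": ["Ni2+", "CO3-2"],  "log_k": 4.57, "source": "NIST SRD 46"},
    "NiHCO3+":  {"components": ["Ni2+", "HCO3-"],  "log_k": 2.14, "source": "NIST SRD 46"},
    "NiSO4":    {"components": ["Ni2+", "SO4-2"],  "log_k": 2.29, "source": "NIST SRD 46"},
    "NiCl+":    {"components": ["Ni2+", "Cl-"],    "log_k": 0.40, "source": "NIST SRD 46"},
    "CaHCO3+":  {"components": ["Ca2+", "HCO3-"],  "log_k": 1.11, "source": "Plummer & Busenberg (1982)"},
    "CaCO3":    {"components": ["Ca2+", "CO3-2"],  "log_k": 3.22, "source": "Plummer & Busenberg (1982)"},
    "CaSO4":    {"components": ["Ca2+", "SO4-2"],  "log_k": 2.30, "source": "NIST SRD 46"},
    "MgHCO3+":  {"components": ["Mg2+", "HCO3-"],  "log_k": 1.07, "source": "NIST SRD 46"},
    "MgCO3":    {"components": ["Mg2+", "CO3-2"],  "log_k": 2.98, "source": "NIST SRD 46"},
    "MgSO4":    {"components": ["Mg2+", "SO4-2"],  "log_k": 2.37, "source": "NIST SRD 46"}
  },
  "doc_binding": {
    "log_k_conditional": 4.5,
    "site_density_mol_per_mg_active": 6.0e-06,
    "active_fraction": 0.65,
    "note": "Transparent single-site stand-in for humic/fulvic Ni binding (NOT a WHAM/NICA replication): binding sites = DOC (mg/L) x active_fraction x site_density; 1:1 complexation against free Ni2+ activity with a conditional constant. Defaults give roughly 70% organically bound Ni at DOC 20 mg/L in a typical moderately hard water, in line with the qualitative role of DOC as a Ni-complexing phase."
  }
}
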