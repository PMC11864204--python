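{
  "version": "1.0",
  "note": "The seven European 'ecoregion' freshwater scenarios used for site-specific acute threshold derivation: pH, DOC (mg/L) and hardness (mg CaCO3/L) as tabulated in the source regulatory set. Remaining ions are filled from the minor-ion recipe in synthetic_media.json (hardness split 3:1 Ca:Mg on a molar basis).",
  "waters": [
    {"water_id": "lake_monate",  "name": "Lake Monate (Italy)",       "ph": 7.7, "doc": 2.5,  "hardness": 48.0},
    {"water_id": "rhine",        "name": "Rhine (Netherlands)",        "ph": 7.8, "doc": 2.8,  "hardness": 217.0},
    {"water_id": "otter",        "name": "Otter (United Kingdom)",     "ph": 8.1, "doc": 3.2,  "hardness": 165.0},
    {"water_id": "teme",         "name": "Teme (United Kingdom)",      "ph": 7.6, "doc": 8.0,  "hardness": 160.0},
    {"water_id": "swedish_lake", "name": "Swedish Lake (Sweden)",      "ph": 6.7, "doc": 3.8,  "hardness": 28.0},
    {"water_id": "ebro",         "name": "Ebro (Spain)",               "ph": 8.2, "doc": 3.7,  "hardness": 273.0},
    {"water_id": "ditches",      "name": "Ditches (Netherlands)",      "ph": 6.9, "doc": 12.0, "hardness": 260.0}
  ]
}
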