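{
  "_provenance": "Approximate published manufacturer geometries (mm). Directional leads are modelled as rings at the ring centre; segmented levels count as one contact. Edit freely: values are data, not code.",
  "3389": {
    "n_contacts": 4,
    "contact_length": 1.5,
    "contact_pitch": 2.0,
    "tip_to_first_contact_centre": 2.25,
    "directional": false,
    "manufacturer": "Medtronic (Activa PC)"
  },
  "6147": {
    "n_contacts": 4,
    "contact_length": 1.5,
    "contact_pitch": 3.0,
    "tip_to_first_contact_centre": 2.25,
    "directional": false,
    "manufacturer": "Abbott/St Jude (Libra PC)"
  },
  "6170": {
    "n_contacts": 4,
    "contact_length": 1.5,
    "contact_pitch": 2.0,
    "tip_to_first_contact_centre": 2.25,
    "directional": true,
    "manufacturer": "Abbott/St Jude (Infinity)"
  },
  "Cartesia": {
    "n_contacts": 4,
    "contact_length": 1.5,
    "contact_pitch": 2.0,
    "tip_to_first_contact_centre": 1.75,
    "directional": true,
    "manufacturer": "Boston Scientific (Vercise PC/Gevia)"
  }
}
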