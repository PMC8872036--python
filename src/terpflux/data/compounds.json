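{
  "isoprene":        {"formula": "C5H8",   "category": "isoprene"},
  "alpha-pinene":    {"formula": "C10H16", "category": "monoterpene"},
  "beta-pinene":     {"formula": "C10H16", "category": "monoterpene"},
  "camphene":        {"formula": "C10H16", "category": "monoterpene"},
  "sabinene":        {"formula": "C10H16", "category": "monoterpene"},
  "limonene":        {"formula": "C10H16", "category": "monoterpene"},
  "3-carene":        {"formula": "C10H16", "category": "monoterpene"},
  "p-cymene":        {"formula": "C10H14", "category": "aromatic_monoterpenoid"},
  "1,8-cineole":     {"formula": "C10H18O", "category": "oxygenated_monoterpenoid"},
  "isocaryophyllene":{"formula": "C15H24", "category": "sesquiterpene"},
  "methacrolein":    {"formula": "C4H6O",  "category": "oxidation_product"},
  "mvk":             {"formula": "C4H6O",  "category": "oxidation_product"},
  "acetonitrile":    {"formula": "C2H3N",  "category": "biomass_burning_tracer"},
  "toluene":         {"formula": "C7H8",   "category": "internal_standard"},
  "cfc-11":          {"formula": "CCl3F",  "category": "reference"},
  "cfc-113":         {"formula": "C2Cl3F3","category": "reference"}
}
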