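# Ribonucleoside registry: formulas and hydrazine reaction rules.
#
# Formulas are for the free nucleoside; the residue (internal chain unit,
# i.e. nucleoside 5'-monophosphate minus water) is derived in code.
# Reaction deltas are signed formulas applied to the *nucleoside/residue*
# composition (e.g. the uridine -> urea-ribose rule removes C3O, nominal
# -52 Da).  Dose-response parameters parameterise the converted fraction
# p(c) = ceiling / (1 + (ec50 / c)^hill) at the reference condition
# (0 degrees C, 1 h), with c the hydrazine concentration in % v/v.
version: "1.0"
reference_condition: {temperature_c: 0.0, time_h: 1.0}

nucleosides:
  A:    {name: adenosine,                                formula: C10H13N5O4}
  C:    {name: cytidine,                                 formula: C9H13N3O5}
  G:    {name: guanosine,                                formula: C10H13N5O5}
  U:    {name: uridine,                                  formula: C9H12N2O6}
  Psi:  {name: pseudouridine,                            formula: C9H12N2O6, aliases: ["Ψ", "Y55"]}
  m5C:  {name: 5-methylcytidine,                         formula: C10H15N3O5}
  m3C:  {name: 3-methylcytidine,                         formula: C10H15N3O5}
  m7G:  {name: 7-methylguanosine,                        formula: C11H15N5O5}
  s4U:  {name: 4-thiouridine,                            formula: C9H12N2O5S}
  s2U:  {name: 2-thiouridine,                            formula: C9H12N2O5S}
  s2C:  {name: 2-thiocytidine,                           formula: C9H13N3O4S}
  ac4C: {name: N4-acetylcytidine,                        formula: C11H15N3O6}
  D:    {name: dihydrouridine,                           formula: C9H14N2O6}
  acp3U: {name: 3-(3-amino-3-carboxypropyl)uridine,      formula: C13H19N3O8}
  m5U:  {name: 5-methyluridine,                          formula: C10H14N2O6}
  Um:   {name: 2'-O-methyluridine,                       formula: C10H14N2O6}
  Cm:   {name: 2'-O-methylcytidine,                      formula: C10H15N3O5}
  Gm:   {name: 2'-O-methylguanosine,                     formula: C11H15N5O5}
  Am:   {name: 2'-O-methyladenosine,                     formula: C11H15N5O4}
  m1A:  {name: 1-methyladenosine,                        formula: C11H15N5O4}
  m1G:  {name: 1-methylguanosine,                        formula: C11H15N5O5}
  m2G:  {name: 2-methylguanosine,                        formula: C11H15N5O5}
  m22G: {name: 2,2-dimethylguanosine,                    formula: C12H17N5O5}
  m1I:  {name: 1-methylinosine,                          formula: C11H14N4O5}
  I:    {name: inosine,                                  formula: C10H12N4O5}
  Y:    {name: wybutosine,                               formula: C21H28N6O9}
  t6A:  {name: N6-threonylcarbamoyladenosine,            formula: C15H20N6O8}
  i6A:  {name: N6-isopentenyladenosine,                  formula: C15H21N5O4}
  Q:    {name: queuosine,                                formula: C17H23N5O7}
  mcm5s2U: {name: 5-methoxycarbonylmethyl-2-thiouridine, formula: C12H16N2O7S}
  ncm5U: {name: 5-carbamoylmethyluridine,                formula: C11H15N3O7}

# Hydrazine reaction rules.  "delta: null" marks a product whose composition
# is unknown (the residue is lost from quantification but contributes no mass
# state to conversion ladders).  "organisms" restricts a rule to a registry
# profile; rules without the key apply to every profile.
rules:
  - reactant: U
    product: urea-ribose
    delta: "C-3O-1"
    leaving_group: pyrazolone
    mechanism: C6-pyrazolone-loss
    dose_response: {ec50: 50.0, hill: 1.83, ceiling: 1.0}
  - reactant: acp3U
    product: urea-ribose-acp
    delta: "C-3O-1"
    leaving_group: pyrazolone
    mechanism: C6-pyrazolone-loss
    dose_response: {ec50: 36.7, hill: 2.0, ceiling: 1.0}
  - reactant: Um
    product: urea-2'-O-methylribose
    delta: "C-3O-1"
    leaving_group: pyrazolone
    mechanism: C6-pyrazolone-loss
    dose_response: {ec50: 50.0, hill: 1.83, ceiling: 0.5}
  - reactant: m3C
    product: urea-ribose-N-methyl
    delta: "C-3H-1N-1"
    leaving_group: 3-aminopyrazole
    mechanism: C6-aminopyrazole-loss
    dose_response: {ec50: 3.0, hill: 3.0, ceiling: 1.0}
  - reactant: s2C
    product: thiourea-ribose
    delta: "C-3H-1N-1"
    leaving_group: 3-aminopyrazole
    mechanism: C6-aminopyrazole-loss
    dose_response: {ec50: 70.0, hill: 6.0, ceiling: 1.0}
  - reactant: ac4C
    product: cytidine
    delta: "C-2H-2O-1"
    leaving_group: acetohydrazide
    mechanism: deacetylation
    dose_response: {ec50: 8.0, hill: 3.0, ceiling: 1.0}
  - reactant: s4U
    product: 4-hydrazone-uridine
    delta: "N2H2S-1"
    leaving_group: hydrogen sulfide
    mechanism: C4-hydrazide-S-elimination
    dose_response: {ec50: 3.0, hill: 3.0, ceiling: 1.0}
  - reactant: D
    product: dihydrouridine-C4-hydrazide
    delta: "N2H4"
    delta_alternatives: {hydrate-hydrazide: "N2H6O"}
    leaving_group: null
    mechanism: ring-open-hydrazide
    dose_response: {ec50: 9.0, hill: 3.0, ceiling: 1.0}
  - reactant: m7G
    product: N7-methyl-FAPy-G
    delta: "H2O"
    leaving_group: null
    mechanism: hydroxide-FAPy
    dose_response: {ec50: 20.8, hill: 3.0, ceiling: 1.0}
  - reactant: mcm5s2U
    product: unknown
    delta: null
    leaving_group: null
    mechanism: unknown-loss
    dose_response: {ec50: 3.0, hill: 3.0, ceiling: 1.0}
  - reactant: t6A
    product: unknown
    delta: null
    leaving_group: null
    mechanism: unknown-loss
    organisms: [ecoli]
    dose_response: {ec50: 5.0, hill: 2.0, ceiling: 1.0}
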