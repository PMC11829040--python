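# Methods

## Mass model

All species are integer element-count vectors over C, H, N, O, P, S, F.
Monoisotopic masses use most-abundant-isotope masses to ≥8 decimals
(C 12 exactly, H 1.00782503, N 14.00307400, O 15.99491462, P 30.97376163,
S 31.97207100, F 18.99840322); average masses use IUPAC conventional atomic
weights; nominal masses are integer mass numbers.  Masses are linear in the
counts, so composition deltas (reaction rules, terminus corrections) commute
with mass computation.

Positive-ion m/z uses the simplified convention
m/z = (M + Σ cation masses)/z with charged-cation constants
(H⁺ 1.007276, Na⁺ 22.989218, K⁺ 38.963158, NH₄⁺ 18.033823); the electron
mass is folded into these constants rather than subtracted per charge.  At
+4 on a 6.5 kDa oligonucleotide the difference from the exact
electron-corrected form is < 0.001 m/z, far below the 0.02 m/z agreement the
worked examples are held to.

## Oligonucleotide terminus bookkeeping

One formula everywhere: an internal residue is a nucleoside
5′-monophosphate − H₂O, so a chain is Σ residues + H₂O (a 5′-phosphate/3′-OH
molecule), then 5′-OH ⇒ −HPO₃, 3′-phosphate ⇒ +HPO₃, 2′,3′-cyclic phosphate
⇒ +HPO₃ − H₂O.  This gives the mass-conservation identity used as a property
test: the fragments of a complete RNase T1 digest sum to the parent mass
plus one water per cut.

RNase T1 cleaves 3′ of unmodified G only; Gm, m¹G, m²G, m²²G and m⁷G are
treated as resistant (2′-O- or base methylation blocks the chemistry).
Products carry 5′-OH and, by default, a ring-opened linear 3′-phosphate —
a 30-min digestion is long enough for cyclic-phosphate hydrolysis — but the
matcher offers both the linear and cyclic (−18.0106 Da) variants of every
fragment and records which one an assignment used, since printed fingerprint
annotations rarely state the phosphate form.

## Hydrazine reaction rules

Each reactive nucleoside carries a composition delta, a mechanism tag and a
leaving group:

| reactant | product | delta | mono Δ (Da) |
|---|---|---|---|
| U, acp³U, Um (partial) | urea–ribose | −C₃O | −51.9949 |
| m³C, s²C | N-methyl/thio urea–ribose | −C₃HN | −51.0109 |
| ac⁴C | cytidine (deacetylation) | −C₂H₂O | −42.0106 |
| s⁴U | C4-hydrazone, S eliminated | +N₂H₂ −S | −1.9502 |
| D | ring-opened C4-hydrazide | +N₂H₄ | +32.0375 |
| m⁷G | N7-methyl-FAPy-G (hydroxide) | +H₂O | +18.0106 |
| mcm⁵s²U; t⁶A (E. coli profile) | unknown | — | — |

Ψ, m⁵U, m⁵C, Cm, Gm, Am, m¹A, m¹G, m²G, m²²G, I, Q, i⁶A, ncm⁵U and Y
(wybutosine) carry no rule.  The dihydrouridine product is ambiguous between
+N₂H₄ and +N₂H₄+H₂O depending on whether the ring-opening water is
retained; +N₂H₄ is the default and the alternative is selectable when
loading the registry (`d_product="hydrate-hydrazide"`).  m³C's product is
assumed to retain the N3-methyl.  The differential t⁶A loss between E. coli
and human tRNA is not chemistry (the nucleoside is identical) but plausibly
a co-purified catalyst, so it is modelled as a registry *profile* switch
rather than a rule difference.  Unknown-loss rules contribute to
quantification (the residue disappears) but are excluded from ladder mass
prediction and flagged per position.

## Dose–response model

Converted fraction p(c) = p_max / (1 + (EC50/c)^h) with p(0) = 0; c is
hydrazine % v/v at the reference condition 0 °C, 1 h.  The experimental data
behind this give a reactivity ordering and a handful of anchor points, not a
functional form, so the two-parameter log-logistic was chosen as the
standard pharmacological minimal model and the registry defaults were set to
the anchors: p_U(10%) ≈ 0.05, p_U(50%) ≈ 0.5 (EC50 50, h 1.83);
s⁴U/m³C/mcm⁵s²U nearly fully converted at 10% (EC50 3, h 3); ac⁴C (EC50 8)
and D (EC50 9) ≥ 0.9 converted at 30%; p_m7G(30%) ≈ 0.75 (EC50 20.8);
p_acp3U(30%) ≈ 0.4 (EC50 36.7, h 2); s²C essentially inert at 30%
(EC50 70, h 6).  Um shares the uridine parameters with ceiling 0.5
(partial reactivity).  Parameters live in the registry YAML so they can be
refitted without touching code.

Incubation time scales the effective concentration linearly up to a 6 h
plateau (longer incubations add little conversion); temperature is not
modelled kinetically — too few data points for an Arrhenius fit — and any
temperature off the 0 °C reference is flagged as extrapolation.
Temperatures above 10 °C degrade RNA (severely at 50 °C); the simulator
refuses quantitative runs under degrading conditions unless overridden.

## Ladder enumeration and matching

A fragment's conversion states are enumerated over all subsets of reactive
positions; states with identical total composition delta are collapsed with
summed Bernoulli probability (independent per-position conversion, at most
one reaction per residue), so a fragment with r equivalent reactive sites
yields r+1 mass states and the probabilities sum to 1.  Matching assigns
each observed peak to the nearest theoretical peak within tolerance —
defaults 0.5 Da for MALDI-TOF on 2–7 kDa fragments, 10 ppm precursor /
20 ppm fragment for Orbitrap-class data — breaking ties by |ppm|, then
lower conversion count, then lower charge; exact ties are reported for both
candidates with an ambiguity flag.

Ψ inference is deliberately a *count*, not a localisation: with u positions
written U or Ψ and a maximum assigned conversion count k_max, u − k_max
sites did not react.  Sites are localised only in the all-or-nothing cases,
and when the per-residue conversion probability under the stated condition
is below 0.9 the confidence is reported low (an unconverted U explains the
data as well as a Ψ).  Cytidine is treated as non-reactive by default; its
slow Maxam–Gilbert-type reactivity can be enabled by registering a C rule.

## Quantification

Calibration is unweighted ordinary least squares of response ratio vs amount
with intercept (the weighting/origin conventions of the source workflow are
unstated; 1/x weighting and through-origin fits are options).  The standard
design is a 12-point 1:1 serial dilution from 100 pmol (canonicals),
20 pmol (Ψ, D) or 5 pmol (other modifications).  Per-molecule counts anchor
on guanosine: molecules = amount(G)/count(G) with count(G) known from the
sequence.  Conversion yield is 1 − treated/control, clipped to [0, 1] with
the raw value retained (noise can put treated above control).  Dose–response
fitting is trust-region least squares (scipy `curve_fit`) on the
remaining-fraction scale with bounds EC50 ∈ [10⁻³, 10⁴], h ∈ [0.05, 50],
ceiling ∈ [0, 1]; below-LOQ points enter as 0 with a censoring flag; flat
data flag the EC50 unidentifiable, step data flag the slope at its bound.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
Bernoulli per-residue conversion (so per-molecule conversion counts are
binomial — checked by chi-square at n = 10⁴), Gaussian m/z jitter (additive
in ppm for ESI at σ = 5 ppm default, in Da for MALDI at σ = 0.15 Da),
multiplicative log-normal intensity noise (MS intensities are scale-noisy),
Poisson noise peaks over the scan range, and multiplicative Gaussian noise
on calibration responses (5%) and remaining fractions (3%).  One master
seed per run; every stage derives a named sub-stream, so stages are
independently reproducible and identical configurations are byte-identical.

What it does **not** emulate: chromatography and retention, ion suppression,
isotope envelopes, detector saturation, sequence-dependent digestion
kinetics or structural protection of residues.  Passing tests therefore
demonstrate correctness of the mass arithmetic, enumeration, matching and
statistical machinery under the stated noise model — not instrument-level
realism.

## Problem sizes

The test suite and acceptance checks run on desk-scale inputs: 20-mer
oligonucleotides and 8–14-mer T1 fragments; exhaustive ladder enumeration is
verified against a 2^r brute force up to r = 10 reactive sites; digestion
invariants on 1000 random sequences up to 35 nt; binomial goodness-of-fit on
10⁴ simulated molecules; dose–response recovery over 20 seeded simulations
of an 8-concentration series; end-to-end fingerprint recovery over 40 seeded
runs of 500 molecules.

## Known limitations

- No isotope-pattern simulation or negative-ion mode.
- Temperature enters only as a degradation/extrapolation flag.
- Ladder probabilities assume positional independence; cooperative or
  structure-protected conversion is not modelled.
- The Ψ caller counts non-reactive sites per fragment; site-level
  localisation requires MS² coverage and is out of scope.
- Database-wide search with decoys/FDR is out of scope (the fingerprint
  matcher works against the supplied sequences only).
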