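# hydramass

Hydrazine reacts with uridine at C6, cleaving out a pyrazolone molecule and
leaving a urea–ribose moiety that is 52 Da lighter — while pseudouridine (Ψ),
a mass-identical C-glycosidic isomer, does not react.  In an aniline-free
environment the RNA backbone stays intact, so the reaction turns an invisible
isomer difference into a clean mass signature: an RNase T1 fragment with
*r* reactive uridines shows a *conversion ladder* of peaks at Δm = 0, −52,
−104, … and the number of missing rungs counts the Ψ sites.  Several other
modified nucleosides (s⁴U, m³C, ac⁴C, D, acp³U, m⁷G, mcm⁵s²U) react at lower
hydrazine concentrations than U, each with its own product mass and
log-logistic dose–response.

`hydramass` models this chemistry end to end for mass-spectrometrists and
epitranscriptomics researchers:

- **`chem`** — elemental-composition arithmetic, monoisotopic/average/nominal
  masses, m/z ↔ neutral mass for multiply protonated and Na⁺/K⁺/NH₄⁺-adducted
  ions, ppm errors.
- **`registry`** — ~30 canonical and modified ribonucleosides with formulas,
  hydrazine reaction rules (composition deltas, leaving groups, mechanisms)
  and dose–response parameters, shipped as an overridable YAML file.
- **`digest`** — bracket-notation sequence parsing
  (`A[Cm]U[Gm]AA[Y]A[Psi][m5C]UG`) and in-silico RNase T1 digestion with
  exact 5′/3′-terminus mass bookkeeping.
- **`ladder`** — conversion-ladder enumeration, theoretical MALDI/ESI peaks,
  tolerance-based peak matching, Ψ-site counting, MS²/MS³ neutral-loss labels.
- **`quant`** — SILIS response-ratio calibration (12-point 1:1 dilutions),
  guanosine-normalised per-molecule counts, conversion yields and
  log-logistic dose–response fitting.
- **`simulate`** — seeded generators for treated molecule populations, noisy
  peak lists, calibration and concentration series.

## Worked example

The dose–response model: a residue converts with probability
p(c) = p_max / (1 + (EC50/c)^h) at hydrazine concentration c (% v/v, 0 °C,
1 h).  For the T1 fragment `[m1A]UCCACAG` (one uridine) at 30% hydrazine:

```
$ hydramass ladder "[m1A]UCCACAG" --concentration 30 -z 4
k       neutral_mass    mz_z4           probability
0       2505.4140       627.3608        0.7181
1       2453.4191       614.3621        0.2819
```

One rung below the precursor, 51.9949 Da (13.00 m/z at +4) lighter: the
single U converts with p ≈ 0.28 at this concentration, m¹A and the cytidines
are inert.  In the library, the same numbers for the 20-mer
`GUAGUCGUGGCCGAGUGGUU`:

```python
>>> from hydramass import *
>>> reg = load_registry()
>>> frag = Fragment((o := tokenize("GUAGUCGUGGCCGAGUGGUU", reg)), o.name, 1, 20)
>>> [round(p.mz, 4) for p in theoretical_peaks(conversion_ladder(frag, reg)[:3], charges=[4])]
[1614.2202, 1601.2215, 1588.2228]
```

— the [M+4H]⁴⁺ ladder of the unreacted, singly and doubly converted 20-mer,
spaced by 52/4 ≈ 13.00 m/z.  Mass-calibration arithmetic:

```
$ hydramass masses C15H12N2O C33H40N2O9 -z 1
C15H12N2O   mono=236.09496  avg=236.2740  [M+1H]1+=237.10224
C33H40N2O9  mono=608.27338  avg=608.6880  [M+1H]1+=609.28066
```

Other subcommands: `digest`, `match`, `fingerprint` (digest → ladder →
match → Ψ inference), `quant` (calibration → amounts → per-molecule counts →
yields), `fit` (dose–response), `simulate`.

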