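# cimion

Automatic recognition of molecular-ion species in methane chemical-ionization
(CI) GC accurate-mass spectra of trimethylsilylated (TMS) metabolites, and
assignment of elemental formulas to the recognized masses.

Methane CI spectra of derivatized metabolites show a predictable set of ions
around the intact molecule M — [M−CH₃]⁺, [M−H]⁺, [M]⁺, [M+H]⁺ and the
reagent adducts [M+C₂H₅]⁺ / [M+C₃H₅]⁺, occasionally a rearrangement
[M+TMS]⁺. `cimion` finds that pattern in centroided spectra, reports the
neutral monoisotopic mass with supporting evidence, and decomposes the
anchoring ion masses into candidate elemental formulas over C/H/N/O/P/S/Si.

## What is in the package

| module | role |
|---|---|
| `cimion.chem_core` | exact-mass arithmetic: formulas, TMS/MEOX derivatization, ion-species m/z, isotope patterns |
| `cimion.spectra_io` | MSP reader; MSP/CSV/MGF/SIRIUS-MS writers |
| `cimion.adduct_pattern` | the CI molecular-ion pattern detector |
| `cimion.formula_assign` | bounded accurate-mass formula decomposition + ranking (self-contained stand-in for external formula-search software; SIRIUS export is provided for cross-checking) |
| `cimion.synthetic` | seeded synthetic CI spectrum generator with ground truth |
| `cimion.evaluate` | recognition / top-k formula-rank scoring |

## CLI

```bash
# generate a synthetic library with ground truth
cimion simulate --n 100 --seed 42 --out lib.msp --truth truth.csv

# detect molecular-ion patterns
cimion detect --msp lib.msp --out assignments.csv --tolerance 0.005 --strict

# tolerate the [M+TMS]+ rearrangement above [M+C3H5]+
cimion detect --msp lib.msp --out assignments.csv --whitelist tms

# score against ground truth
cimion evaluate --assignments assignments.csv --truth truth.csv --out report.json

# assign elemental formulas (anchored on the [M-CH3]+ ion)
cimion assign --msp lib.msp --strategy m_minus_ch3 --ppm 10 --top 10 --out candidates.csv

# format conversions and SIRIUS input export
cimion convert --from msp --to csv --msp lib.msp --out peaks.csv
cimion convert --from msp --to mgf --msp lib.msp --out lib.mgf
cimion export-sirius --msp lib.msp --out sirius_inputs/
```

## Python API sketch

```python
from cimion import (
    ElementalFormula, derivatize, ion_mz, ION_SPECIES,
    detect_molecular_ion, assign_with_strategy, DecompositionBounds,
)

neutral = derivatize(ElementalFormula.parse("H3PO4"), n_tms=3)  # C9H27O4PSi3
ion_mz(neutral, ION_SPECIES["[M+H]+"])                          # 315.1033

assignment = detect_molecular_ion(spectrum)      # Spectrum -> neutral mass
candidates = assign_with_strategy(
    spectrum, assignment, "m_minus_ch3",
    DecompositionBounds(tolerance_ppm=10, require_si=True),
)
```

Conventions: cation m/z equals the neutral-arithmetic monoisotopic mass plus
the species delta (no electron-mass correction; an `electron_correction`
flag is available). TMS adds +72.0395 Da net per active hydrogen,
methoximation +29.0266 Da per carbonyl.

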