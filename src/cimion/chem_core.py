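"""Exact-mass chemistry for TMS/MEOX-derivatized metabolites.

Element masses, elemental-formula arithmetic, derivatization shifts,
ion-species m/z and nominal-shift isotope patterns for the element set
C/H/N/O/P/S/Si encountered in trimethylsilylated metabolites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Tuple

__all__ = [
    "SUPPORTED_ELEMENTS",
    "MONOISOTOPIC_MASS",
    "ISOTOPES",
    "ELECTRON_MASS",
    "ElementalFormula",
    "IonSpecies",
    "ION_SPECIES",
    "MOLECULAR_CLUSTER",
    "REAGENT_ADDUCTS",
    "IsotopePattern",
    "DerivatizedCompound",
    "TMS_NET",
    "MEOX_NET",
    "monoisotopic_mass",
    "derivatize",
    "ion_mz",
    "isotope_pattern",
]

# Isotope masses (Da) and abundances: CODATA/AME2020 values as tabulated in
# the NIST "Atomic Weights and Isotopic Compositions" compilation.
ISOTOPES: Dict[str, Tuple[Tuple[float, float], ...]] = {
    "H": ((1.00782503207, 0.999885), (2.01410177812, 0.000115)),
    "C": ((12.0, 0.9893), (13.00335483507, 0.0107)),
    "N": ((14.00307400443, 0.99636), (15.00010889888, 0.00364)),
    "O": ((15.99491461957, 0.99757), (16.99913175650, 0.00038), (17.99915961286, 0.00205)),
    "P": ((30.97376199842, 1.0),),
    "S": ((31.97207117440, 0.9499), (32.97145890980, 0.0075), (33.96786700400, 0.0425), (35.96708071000, 0.0001)),
    "Si": ((27.97692653465, 0.92223), (28.97649466490, 0.04685), (29.97377013600, 0.03092)),
}

SUPPORTED_ELEMENTS: Tuple[str, ...] = ("C", "H", "N", "O", "P", "S", "Si")

#: mass of the most abundant (here also lightest) isotope of each element
MONOISOTOPIC_MASS: Dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}

ELECTRON_MASS = 0.000548579909  # Da

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnsupportedElementError(ValueError):
    """Raised when a formula contains an element outside C/H/N/O/P/S/Si."""


def _validate_counts(counts: Mapping[str, int]) -> Dict[str, int]:
    clean: Dict[str, int] = {}
    for el, n in counts.items():
        if el not in ISOTOPES:
            raise UnsupportedElementError(f"unsupported element symbol: {el!r}")
        n = int(n)
        if n < 0:
            raise ValueError(f"negative count for element {el}: {n}")
        if n > 0:
            clean[el] = n
    return clean


@dataclass(frozen=True)
class ElementalFormula:
    """Immutable element->count map with exact monoisotopic-mass semantics."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", _validate_counts(self.counts))

    # -- construction ------------------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-order formula string such as ``C17H32O4Si3``."""
        text = text.strip()
        counts: Dict[str, int] = {}
        pos = 0
        while pos < len(text):
            m = _FORMULA_TOKEN.match(text, pos)
            if m is None or m.group(1) == "":
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            el, num = m.group(1), m.group(2)
            if el not in ISOTOPES:
                raise UnsupportedElementError(f"unsupported element symbol: {el!r}")
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = m.end()
        return cls(counts)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + n
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            new = counts.get(el, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction would give negative {el} count "
                    f"({self} - {other})"
                )
            counts[el] = new
        return ElementalFormula(counts)

    def __mul__(self, k: int) -> "ElementalFormula":
        if k < 0:
            raise ValueError("multiplier must be non-negative")
        return ElementalFormula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        return iter(self.counts.items())

    def contains(self, other: "ElementalFormula") -> bool:
        return all(self[el] >= n for el, n in other.counts.items())

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def hill(self) -> str:
        """Hill-order string: C, then H, then other elements alphabetically."""
        parts: List[str] = []
        order = ["C", "H"] + sorted(el for el in self.counts if el not in ("C", "H"))
        for el in order:
            n = self.counts.get(el, 0)
            if n == 0:
                continue
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill()!r})"


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass in Da (most-abundant-isotope masses)."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.counts.items())


# -- derivatization --------------------------------------------------------

#: net formula change per trimethylsilylation: -H +Si(CH3)3
TMS_NET = ElementalFormula({"C": 3, "H": 8, "Si": 1})
#: net formula change per methoximation of a carbonyl: +CH3N
MEOX_NET = ElementalFormula({"C": 1, "H": 3, "N": 1})

_H = ElementalFormula({"H": 1})


def derivatize(base: ElementalFormula, n_tms: int = 0, n_meox: int = 0) -> ElementalFormula:
    """Formula of the TMS/MEOX derivative of ``base``.

    Each TMS group replaces one active hydrogen (net +C3H8Si, +72.0395 Da);
    each methoximation converts a carbonyl (net +CH3N, +29.0266 Da).
    """
    if n_tms < 0 or n_meox < 0:
        raise ValueError("derivatization group counts must be non-negative")
    if base["H"] < n_tms:
        raise ValueError(
            f"{base} has {base['H']} hydrogens; cannot attach {n_tms} TMS groups"
        )
    return base + n_tms * TMS_NET + n_meox * MEOX_NET


# -- ion species -----------------------------------------------------------


@dataclass(frozen=True)
class IonSpecies:
    """A named singly-charged cation rule relative to the neutral molecule M."""

    label: str
    gain: ElementalFormula
    loss: ElementalFormula
    charge: int = 1

    @property
    def delta_mass(self) -> float:
        return monoisotopic_mass(self.gain) - monoisotopic_mass(self.loss)

    def apply(self, neutral: ElementalFormula) -> ElementalFormula:
        """Elemental composition of the ion formed from ``neutral``."""
        if not neutral.contains(self.loss):
            raise ValueError(f"{self.label} not applicable to {neutral}")
        return neutral + self.gain - self.loss

    def __str__(self) -> str:
        return self.label


def _species(label: str, gain: str = "", loss: str = "") -> IonSpecies:
    return IonSpecies(
        label,
        ElementalFormula.parse(gain) if gain else ElementalFormula(),
        ElementalFormula.parse(loss) if loss else ElementalFormula(),
    )


#: the fixed, immutable label -> species registry
ION_SPECIES: Dict[str, IonSpecies] = {
    s.label: s
    for s in (
        _species("[M-CH3]+", loss="CH3"),
        _species("[M-H]+", loss="H"),
        _species("[M]+"),
        _species("[M+H]+", gain="H"),
        _species("[M+C2H5]+", gain="C2H5"),
        _species("[M+C3H5]+", gain="C3H5"),
        _species("[M+TMS]+", gain="C3H9Si"),
        _species("[M-H2O+H]+", gain="H", loss="H2O"),
    )
}

#: the intact-molecule cluster species
MOLECULAR_CLUSTER = (ION_SPECIES["[M-H]+"], ION_SPECIES["[M]+"], ION_SPECIES["[M+H]+"])
#: methane reagent-gas adducts
REAGENT_ADDUCTS = (ION_SPECIES["[M+C2H5]+"], ION_SPECIES["[M+C3H5]+"])


def ion_mz(neutral: ElementalFormula, species: IonSpecies, *, electron_correction: bool = False) -> float:
    """m/z of ``species`` formed from ``neutral``.

    By default no electron-mass correction is applied: the cation m/z equals
    the neutral-arithmetic monoisotopic mass plus the species delta, which is
    the convention the reference theoretical values follow.
    """
    mz = monoisotopic_mass(species.apply(neutral))
    if electron_correction:
        mz -= species.charge * ELECTRON_MASS
    return mz


# -- isotope patterns ------------------------------------------------------


@dataclass(frozen=True)
class IsotopePattern:
    """Isotopologue abundances aggregated on nominal-mass shift (A, A+1, ...)."""

    peaks: Tuple[Tuple[float, float], ...]  # (mass_Da, relative_abundance)

    def __post_init__(self) -> None:
        masses = [m for m, _ in self.peaks]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError("isotope pattern masses must be strictly increasing")
        total = sum(a for _, a in self.peaks)
        if self.peaks and abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {total})")

    @property
    def masses(self) -> Tuple[float, ...]:
        return tuple(m for m, _ in self.peaks)

    @property
    def abundances(self) -> Tuple[float, ...]:
        return tuple(a for _, a in self.peaks)

    def ratio(self, shift: int) -> float:
        """Abundance of the A+shift peak relative to the A peak."""
        return self.abundances[shift] / self.abundances[0]


def _element_pattern(el: str) -> List[Tuple[int, float, float]]:
    """(nominal shift, mass, abundance) per isotope of a single atom."""
    base_nominal = round(ISOTOPES[el][0][0])
    return [(round(m) - base_nominal, m, a) for m, a in ISOTOPES[el]]


def isotope_pattern(f: ElementalFormula, max_shift: int = 3) -> IsotopePattern:
    """Nominal-shift isotope pattern of ``f`` truncated at ``max_shift``.

    Element-wise convolution of the natural isotope distributions, with
    isobaric contributions (e.g. 13C and 29Si within A+1) merged per shift
    bin; per-bin masses are abundance-weighted means; abundances are
    renormalized to sum to 1 after truncation.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    # state[shift] = (abundance, abundance-weighted mass sum)
    ab = [0.0] * (max_shift + 1)
    wm = [0.0] * (max_shift + 1)
    ab[0] = 1.0
    for el, n in f.counts.items():
        iso = _element_pattern(el)
        for _ in range(n):
            new_ab = [0.0] * (max_shift + 1)
            new_wm = [0.0] * (max_shift + 1)
            for shift in range(max_shift + 1):
                if ab[shift] == 0.0:
                    continue
                for dshift, dmass, dab in iso:
                    t = shift + dshift
                    if t > max_shift:
                        continue
                    new_ab[t] += ab[shift] * dab
                    new_wm[t] += (wm[shift] + ab[shift] * dmass) * dab
            ab, wm = new_ab, new_wm
    total = sum(ab)
    peaks = tuple(
        (wm[s] / ab[s], ab[s] / total) for s in range(max_shift + 1) if ab[s] > 0.0
    )
    return IsotopePattern(peaks)


# -- derivatized compounds -------------------------------------------------


@dataclass(frozen=True)
class DerivatizedCompound:
    """A metabolite with its TMS/MEOX derivatization counts."""

    name: str
    base_formula: ElementalFormula
    n_tms: int = 0
    n_meox: int = 0

    def __post_init__(self) -> None:
        if self.n_tms < 0 or self.n_meox < 0:
            raise ValueError("derivatization counts must be non-negative")

    @property
    def derivatized_formula(self) -> ElementalFormula:
        return derivatize(self.base_formula, self.n_tms, self.n_meox)

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.derivatized_formula)
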