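"""Elemental-formula assignment by bounded accurate-mass decomposition.

A self-contained stand-in for external formula-search software: complete
enumeration of C/H/N/O/P/S/Si formulas within per-element bounds and a ppm
window, filtered by RDBE and H/C plausibility, ranked by mass error and by
how many spectrum peaks are explainable as subformula cations. Exports via
:mod:`cimion.spectra_io` allow cross-checking with external tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .adduct_pattern import MolecularIonAssignment
from .chem_core import (
    ION_SPECIES,
    MONOISOTOPIC_MASS,
    ElementalFormula,
    IonSpecies,
    isotope_pattern,
    monoisotopic_mass,
)
from .spectra_io import Spectrum

__all__ = [
    "DecompositionBounds",
    "FormulaCandidate",
    "rdbe",
    "decompose_mass",
    "rank_candidates",
    "assign_with_strategy",
    "STRATEGIES",
]

_M_CH3 = ION_SPECIES["[M-CH3]+"]

STRATEGIES = ("molecular_ion", "m_minus_ch3", "with_isotopes")


@dataclass(frozen=True)
class DecompositionBounds:
    """Per-element count bounds and the mass tolerance of the search."""

    min_counts: Dict[str, int] = field(
        default_factory=lambda: {el: 0 for el in ("C", "H", "N", "O", "P", "S", "Si")}
    )
    max_counts: Dict[str, int] = field(
        default_factory=lambda: {"C": 60, "H": 120, "N": 10, "O": 25, "P": 4, "S": 4, "Si": 12}
    )
    tolerance_ppm: float = 10.0
    require_si: bool = False

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be > 0")
        for el in self.max_counts:
            lo = self.min_counts.get(el, 0)
            if lo > self.max_counts[el]:
                raise ValueError(f"min > max for element {el}")

    def with_mandatory_si(self) -> "DecompositionBounds":
        return replace(self, require_si=True)


@dataclass(frozen=True)
class FormulaCandidate:
    """One decomposed neutral formula for an observed ion."""

    formula: ElementalFormula
    species: IonSpecies
    mass_error_ppm: float
    rdbe: float
    explained_fragments: int = 0
    rank_score: float = 0.0


def rdbe(f: ElementalFormula) -> float:
    """Ring-plus-double-bond equivalents; Si counted tetravalent like C."""
    return 1.0 + f["C"] + f["Si"] + 0.5 * (f["N"] + f["P"]) - 0.5 * f["H"]


# decomposition search order: heaviest first so mass pruning bites early;
# C and H last because their counts are constrained tightest by the residue
_SEARCH_ORDER = ("S", "Si", "P", "O", "N", "C", "H")


def _decompose(target: float, tol: float, bounds: DecompositionBounds) -> List[Dict[str, int]]:
    """All count maps with |mass - target| <= tol. Complete within bounds."""
    results: List[Dict[str, int]] = []
    counts: Dict[str, int] = {}
    masses = {el: MONOISOTOPIC_MASS[el] for el in _SEARCH_ORDER}
    mins = {el: bounds.min_counts.get(el, 0) for el in _SEARCH_ORDER}
    maxs = {el: bounds.max_counts.get(el, 0) for el in _SEARCH_ORDER}
    if bounds.require_si:
        mins = dict(mins)
        mins["Si"] = max(1, mins["Si"])
    # minimum mass still to come at each search depth (from element minima)
    min_tail = [0.0] * (len(_SEARCH_ORDER) + 1)
    for i in range(len(_SEARCH_ORDER) - 1, -1, -1):
        el = _SEARCH_ORDER[i]
        min_tail[i] = min_tail[i + 1] + mins[el] * masses[el]

    last = len(_SEARCH_ORDER) - 1

    def recurse(depth: int, remaining: float) -> None:
        el = _SEARCH_ORDER[depth]
        m = masses[el]
        lo, hi = mins[el], maxs[el]
        if depth == last:
            # the residue fixes the count of the final element (tol << m/2)
            n = round(remaining / m)
            for cand in (n - 1, n, n + 1):
                if lo <= cand <= hi and abs(remaining - cand * m) <= tol:
                    counts[el] = cand
                    results.append(dict(counts))
            counts.pop(el, None)
            return
        hi = min(hi, int((remaining - min_tail[depth + 1] + tol) // m))
        for n in range(lo, hi + 1):
            rem = remaining - n * m
            if rem + tol < min_tail[depth + 1]:
                break
            counts[el] = n
            recurse(depth + 1, rem)
        counts.pop(el, None)

    recurse(0, target)
    return results


def _plausible(f: ElementalFormula) -> bool:
    if rdbe(f) < -0.5:
        return False
    c = f["C"]
    if c > 0:
        hc = f["H"] / c
        if not (0.1 <= hc <= 4.0):
            return False
    return True


def decompose_mass(
    target_mz: float,
    species: IonSpecies,
    bounds: DecompositionBounds = DecompositionBounds(),
) -> List[FormulaCandidate]:
    """Enumerate neutral formulas M with ion_mz(M, species) within tolerance.

    Complete relative to the bounds; candidates are filtered by
    RDBE >= -0.5 and 0.1 <= H/C <= 4 (when C > 0), and by Si >= 1 when the
    mandatory-Si flag is set. Sorted by |mass error| then Hill string.
    """
    if target_mz <= 0:
        raise ValueError("target_mz must be > 0")
    neutral_target = target_mz - species.delta_mass
    tol = target_mz * bounds.tolerance_ppm * 1e-6
    out: List[FormulaCandidate] = []
    for counts in _decompose(neutral_target, tol, bounds):
        f = ElementalFormula(counts)
        if not f.contains(species.loss):
            continue
        if not _plausible(f):
            continue
        err_ppm = (monoisotopic_mass(f) + species.delta_mass - target_mz) / target_mz * 1e6
        out.append(FormulaCandidate(f, species, err_ppm, rdbe(f)))
    out.sort(key=lambda c: (abs(c.mass_error_ppm), c.formula.hill()))
    return out


def _count_explained(candidate: ElementalFormula, peaks: Sequence[Tuple[float, float]], tolerance_ppm: float) -> int:
    """Peaks explainable as a subformula cation of ``candidate``."""
    sub_bounds = DecompositionBounds(
        min_counts={el: 0 for el in candidate.counts},
        max_counts=dict(candidate.counts),
        tolerance_ppm=tolerance_ppm,
    )
    n = 0
    for mz, _ in peaks:
        tol = mz * tolerance_ppm * 1e-6
        if _decompose(mz, tol, sub_bounds):
            n += 1
    return n


def _minmax(values: Sequence[float]) -> List[float]:
    lo, hi = min(values), max(values)
    if hi - lo < 1e-12:
        return [0.5] * len(values)
    return [(v - lo) / (hi - lo) for v in values]


def rank_candidates(
    candidates: Sequence[FormulaCandidate],
    spectrum: Optional[Spectrum] = None,
    assignment: Optional[MolecularIonAssignment] = None,
    *,
    w_error: float = 1.0,
    w_fragments: float = 1.0,
    tolerance_ppm: float = 10.0,
    isotope_scores: Optional[Sequence[float]] = None,
    w_isotope: float = 1.0,
) -> List[FormulaCandidate]:
    """Rank candidates by mass error and explained spectrum fragments.

    rank_score = w_error * (1 - scaled |error|) + w_fragments * scaled
    explained-fragment count (+ optional isotope-agreement term); both
    terms min-max scaled per spectrum. Stable; ties broken by lower
    |error| then Hill string.
    """
    if not candidates:
        return []
    if spectrum is not None:
        explained = [
            _count_explained(c.formula, spectrum.peaks, tolerance_ppm) for c in candidates
        ]
    else:
        explained = [0] * len(candidates)
    err_scaled = _minmax([abs(c.mass_error_ppm) for c in candidates])
    frag_scaled = _minmax([float(e) for e in explained])
    scores = [
        w_error * (1.0 - e) + w_fragments * fr
        for e, fr in zip(err_scaled, frag_scaled)
    ]
    if isotope_scores is not None:
        iso_scaled = _minmax(list(isotope_scores))
        scores = [s + w_isotope * i for s, i in zip(scores, iso_scaled)]
    ranked = [
        replace(c, explained_fragments=e, rank_score=s)
        for c, e, s in zip(candidates, explained, scores)
    ]
    ranked.sort(key=lambda c: (-c.rank_score, abs(c.mass_error_ppm), c.formula.hill()))
    return ranked


def _isotope_agreement(
    candidate: ElementalFormula,
    observed_ratios: Sequence[float],
    species: IonSpecies,
) -> float:
    """Negative L1 distance between observed and theoretical A+k ratios."""
    ion = species.apply(candidate)
    theo = isotope_pattern(ion, max_shift=max(1, len(observed_ratios)))
    dist = 0.0
    for k, obs in enumerate(observed_ratios, start=1):
        t = theo.ratio(k) if k < len(theo.abundances) else 0.0
        dist += abs(obs - t)
    if not observed_ratios:  # no members observed: compare against A+1 alone
        dist = theo.ratio(1) if len(theo.abundances) > 1 else 0.0
    return -dist


def assign_with_strategy(
    spectrum: Spectrum,
    assignment: MolecularIonAssignment,
    strategy: str,
    bounds: DecompositionBounds = DecompositionBounds(),
    **rank_kw,
) -> List[FormulaCandidate]:
    """Decompose and rank using one of the three anchoring strategies.

    ``m_minus_ch3`` anchors on the observed [M-CH3]+ peak; ``molecular_ion``
    anchors on the detector's base species; ``with_isotopes`` additionally
    scores agreement between the observed isotope-group ratios at the anchor
    and each candidate's theoretical pattern.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if assignment.rejected:
        raise ValueError("cannot assign formulas to a rejected detection")

    if strategy == "m_minus_ch3":
        match = assignment.find(_M_CH3.label)
        if match is None:
            raise ValueError("strategy m_minus_ch3 requires an [M-CH3]+ species match")
    else:
        if assignment.base_species is None:
            raise ValueError("assignment has no base species")
        match = assignment.find(assignment.base_species.label)
        if match is None:
            raise ValueError(f"base species {assignment.base_species.label} not in species_found")

    candidates = decompose_mass(match.mz, match.species, bounds)

    isotope_scores = None
    if strategy == "with_isotopes":
        from .adduct_pattern import DetectionConfig, group_isotopes

        groups = group_isotopes(
            spectrum.normalized(), DetectionConfig(mz_tolerance=bounds.tolerance_ppm * match.mz * 1e-6)
        )
        anchor_group = min(groups, key=lambda g: abs(g.mz - match.mz))
        ratios = anchor_group.shift_ratios()
        isotope_scores = [
            _isotope_agreement(c.formula, ratios, match.species) for c in candidates
        ]

    return rank_candidates(
        candidates,
        spectrum,
        assignment,
        tolerance_ppm=bounds.tolerance_ppm,
        isotope_scores=isotope_scores,
        **rank_kw,
    )
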