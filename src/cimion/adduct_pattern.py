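"""Recognition of methane-CI molecular-ion species patterns.

A methane-CI spectrum of a derivatized metabolite shows a characteristic
set of ions around the intact molecule M: [M-CH3]+, [M-H]+, [M]+, [M+H]+
plus the reagent adducts [M+C2H5]+ and [M+C3H5]+. The detector groups
peaks into isotopologue clusters, anchors hypotheses on [M-CH3]+ (with a
fallback on the molecular cluster itself), scores each hypothesis by the
species it explains and returns the neutral monoisotopic mass with the
supporting evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import pandas as pd

from .chem_core import ION_SPECIES, MOLECULAR_CLUSTER, REAGENT_ADDUCTS, IonSpecies
from .spectra_io import Spectrum

__all__ = [
    "DetectionConfig",
    "IsotopeGroup",
    "SpeciesMatch",
    "MolecularIonAssignment",
    "group_isotopes",
    "detect_molecular_ion",
    "batch_detect",
]

_M_CH3 = ION_SPECIES["[M-CH3]+"]
_M_H_LOSS = ION_SPECIES["[M-H]+"]
_M = ION_SPECIES["[M]+"]
_M_H = ION_SPECIES["[M+H]+"]
_C3H5 = ION_SPECIES["[M+C3H5]+"]
_WATER_LOSS = ION_SPECIES["[M-H2O+H]+"]
_TMS_ADDUCT = ION_SPECIES["[M+TMS]+"]

# isotopologue successive-gap window: covers 13C (+1.00336), 29Si (+0.99957)
# and the 30Si A+1 -> A+2 step (+0.9935) plus ppm-scale jitter
_ISO_GAP_MIN = 0.990
_ISO_GAP_MAX = 1.007


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable thresholds of the pattern detector.

    The intensity floors encode the observed behaviour of CI spectra:
    molecular-cluster species usually appear above 5% of the base peak
    while reagent adducts mostly sit below 5%.
    """

    mz_tolerance: float = 0.005
    molecular_intensity_floor: float = 0.05
    adduct_intensity_floor: float = 0.001
    noise_floor: float = 0.001
    higher_mz_whitelist: FrozenSet[str] = frozenset()
    require_adducts: bool = False
    strict: bool = True

    def __post_init__(self) -> None:
        if self.mz_tolerance <= 0:
            raise ValueError("mz_tolerance must be > 0")
        for name in ("molecular_intensity_floor", "adduct_intensity_floor", "noise_floor"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        object.__setattr__(self, "higher_mz_whitelist", frozenset(self.higher_mz_whitelist))
        for label in self.higher_mz_whitelist:
            if label not in ION_SPECIES:
                raise ValueError(f"unknown ion species in whitelist: {label!r}")


@dataclass(frozen=True)
class IsotopeGroup:
    """One isotopologue cluster: a monoisotopic peak plus its A+k members."""

    monoisotopic: Tuple[float, float]
    members: Tuple[Tuple[float, float], ...]

    @property
    def mz(self) -> float:
        return self.monoisotopic[0]

    @property
    def intensity(self) -> float:
        return self.monoisotopic[1]

    def shift_ratios(self) -> Tuple[float, ...]:
        """Member intensities relative to the monoisotopic peak (A+1, A+2, ...)."""
        return tuple(i / self.monoisotopic[1] for _, i in self.members)


@dataclass(frozen=True)
class SpeciesMatch:
    species: IonSpecies
    mz: float
    intensity: float  # relative to base peak


@dataclass(frozen=True)
class MolecularIonAssignment:
    """Detector output for one spectrum."""

    neutral_mass: Optional[float]
    species_found: Tuple[SpeciesMatch, ...] = ()
    base_species: Optional[IonSpecies] = None
    precursor_mz: Optional[float] = None
    rejected: bool = False
    reason: str = ""

    def find(self, label: str) -> Optional[SpeciesMatch]:
        for m in self.species_found:
            if m.species.label == label:
                return m
        return None

    @property
    def species_labels(self) -> Tuple[str, ...]:
        return tuple(m.species.label for m in self.species_found)


def group_isotopes(spectrum: Spectrum, config: DetectionConfig = DetectionConfig()) -> List[IsotopeGroup]:
    """Greedy ascending-m/z grouping of peaks into isotopologue clusters.

    A peak joins the open group if its gap to the group's last member lies
    in [0.996, 1.007] Da and its intensity does not exceed the monoisotopic
    member's; every peak belongs to exactly one group.
    """
    if not spectrum.peaks:
        raise ValueError("cannot group an empty spectrum")
    groups: List[IsotopeGroup] = []
    current: List[Tuple[float, float]] = [spectrum.peaks[0]]
    for peak in spectrum.peaks[1:]:
        gap = peak[0] - current[-1][0]
        if _ISO_GAP_MIN <= gap <= _ISO_GAP_MAX and peak[1] <= current[0][1] and len(current) <= 3:
            current.append(peak)
        else:
            groups.append(IsotopeGroup(current[0], tuple(current[1:])))
            current = [peak]
    groups.append(IsotopeGroup(current[0], tuple(current[1:])))
    return groups


def _nearest_group(groups: Sequence[IsotopeGroup], mz: float, tol: float) -> Optional[IsotopeGroup]:
    best = None
    best_d = tol
    for g in groups:
        d = abs(g.mz - mz)
        if d <= best_d:
            best, best_d = g, d
    return best


@dataclass
class _Hypothesis:
    neutral_mass: float
    matches: List[SpeciesMatch]

    @property
    def score(self) -> Tuple[int, float, float]:
        return (
            len(self.matches),
            sum(m.intensity for m in self.matches),
            self.neutral_mass,
        )


def _evaluate_hypothesis(
    neutral_mass: float,
    groups: Sequence[IsotopeGroup],
    config: DetectionConfig,
) -> Optional[_Hypothesis]:
    """Collect species evidence for a hypothetical neutral mass."""
    matches: List[SpeciesMatch] = []

    g = _nearest_group(groups, neutral_mass + _M_CH3.delta_mass, config.mz_tolerance)
    if g is not None and g.intensity >= config.noise_floor:
        matches.append(SpeciesMatch(_M_CH3, g.mz, g.intensity))

    molecular_ok = False
    for sp in MOLECULAR_CLUSTER:
        g = _nearest_group(groups, neutral_mass + sp.delta_mass, config.mz_tolerance)
        if g is not None and g.intensity >= config.noise_floor:
            matches.append(SpeciesMatch(sp, g.mz, g.intensity))
            if g.intensity >= config.molecular_intensity_floor:
                molecular_ok = True
    if not molecular_ok:
        return None

    n_adducts = 0
    for sp in REAGENT_ADDUCTS:
        g = _nearest_group(groups, neutral_mass + sp.delta_mass, config.mz_tolerance)
        if g is not None and g.intensity >= config.adduct_intensity_floor:
            matches.append(SpeciesMatch(sp, g.mz, g.intensity))
            n_adducts += 1
    if config.require_adducts and n_adducts == 0:
        return None

    # annotated but never used as anchors or counted for acceptance
    g = _nearest_group(groups, neutral_mass + _WATER_LOSS.delta_mass, config.mz_tolerance)
    if g is not None and g.intensity >= config.adduct_intensity_floor:
        matches.append(SpeciesMatch(_WATER_LOSS, g.mz, g.intensity))

    for label in config.higher_mz_whitelist:
        sp = ION_SPECIES[label]
        g = _nearest_group(groups, neutral_mass + sp.delta_mass, config.mz_tolerance)
        if g is not None and g.intensity >= config.adduct_intensity_floor:
            matches.append(SpeciesMatch(sp, g.mz, g.intensity))

    return _Hypothesis(neutral_mass, matches)


def _accept(hyp: _Hypothesis) -> bool:
    labels = {m.species.label for m in hyp.matches}
    core = labels & {_M_CH3.label, _M_H_LOSS.label, _M.label, _M_H.label}
    if _M_CH3.label in labels and len(core) >= 2:
        return True
    # fallback: at least two members of the molecular cluster itself
    return len(core - {_M_CH3.label}) >= 2


def detect_molecular_ion(
    spectrum: Spectrum, config: DetectionConfig = DetectionConfig()
) -> MolecularIonAssignment:
    """Recognize the molecular-ion species pattern of one CI spectrum.

    Every isotope-group monoisotopic peak above the noise floor is tried
    both as an [M-CH3]+ anchor and as an [M]+ anchor; the hypothesis
    explaining the most species wins (ties: summed relative intensity,
    then larger neutral mass). In strict mode any unexplained monoisotopic
    peak above m/z([M+C3H5]+) rejects the assignment.
    """
    if not spectrum.peaks:
        raise ValueError("cannot detect on an empty spectrum")
    if len(spectrum.peaks) < 2:
        return MolecularIonAssignment(None, rejected=True, reason="no pattern")

    norm = spectrum.normalized()
    groups = group_isotopes(norm, config)
    candidates = [g for g in groups if g.intensity >= config.noise_floor]

    hypotheses: Dict[float, _Hypothesis] = {}
    for g in candidates:
        for anchor_delta in (_M_CH3.delta_mass, 0.0, _M_H.delta_mass):
            neutral = g.mz - anchor_delta
            key = round(neutral, 4)
            if key in hypotheses:
                continue
            hyp = _evaluate_hypothesis(neutral, groups, config)
            if hyp is not None and _accept(hyp):
                hypotheses[key] = hyp

    if not hypotheses:
        return MolecularIonAssignment(None, rejected=True, reason="no pattern")

    best = max(hypotheses.values(), key=lambda h: h.score)

    # refined neutral mass: intensity-weighted mean over supporting species
    core = [m for m in best.matches if m.species.label != _WATER_LOSS.label]
    weight = sum(m.intensity for m in core)
    neutral_mass = sum((m.mz - m.species.delta_mass) * m.intensity for m in core) / weight

    cluster = [m for m in best.matches if m.species in MOLECULAR_CLUSTER]
    if cluster:
        base = max(cluster, key=lambda m: m.intensity)
    else:
        base = max(best.matches, key=lambda m: m.intensity)

    if config.strict:
        limit = neutral_mass + _C3H5.delta_mass + config.mz_tolerance
        explained = {round(m.mz, 4) for m in best.matches}
        for g in candidates:
            if g.mz > limit and round(g.mz, 4) not in explained:
                return MolecularIonAssignment(
                    neutral_mass,
                    species_found=tuple(best.matches),
                    rejected=True,
                    reason="unexplained high-mass ions",
                )

    return MolecularIonAssignment(
        neutral_mass,
        species_found=tuple(best.matches),
        base_species=base.species,
        precursor_mz=base.mz,
    )


def batch_detect(
    spectra: Sequence[Spectrum], config: DetectionConfig = DetectionConfig()
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Run the detector over a batch; never aborts on per-record errors.

    Returns a per-spectrum table and aggregate counts of base-species
    categories and rejection reasons.
    """
    if len(spectra) == 0:
        raise ValueError("empty batch")
    rows = []
    summary: Dict[str, int] = {}
    for spec in spectra:
        try:
            a = detect_molecular_ion(spec, config)
            rows.append(
                {
                    "name": spec.name,
                    "neutral_mass": a.neutral_mass,
                    "precursor_mz": a.precursor_mz,
                    "base_species": a.base_species.label if a.base_species else "",
                    "species_found": ";".join(a.species_labels),
                    "rejected": a.rejected,
                    "reason": a.reason,
                }
            )
            key = a.reason if a.rejected else (a.base_species.label if a.base_species else "")
        except ValueError as exc:
            rows.append(
                {
                    "name": spec.name,
                    "neutral_mass": None,
                    "precursor_mz": None,
                    "base_species": "",
                    "species_found": "",
                    "rejected": True,
                    "reason": f"error: {exc}",
                }
            )
            key = "error"
        summary[key] = summary.get(key, 0) + 1
    return pd.DataFrame(rows), summary


def lenient(config: DetectionConfig) -> DetectionConfig:
    """Copy of ``config`` with the high-mass rejection rule disabled."""
    return replace(config, strict=False)
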