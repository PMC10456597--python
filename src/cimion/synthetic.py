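"""Synthetic methane-CI spectrum generator with known ground truth.

Every spectrum is built from a derivatized compound's exact chemistry
(:mod:`cimion.chem_core`) plus sampled ion species, intensities, isotope
expansion, ppm-scale mass jitter and optional contaminants, so detection
and formula assignment can be benchmarked without any acquired data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem_core import (
    ION_SPECIES,
    DerivatizedCompound,
    ElementalFormula,
    IonSpecies,
    ion_mz,
    isotope_pattern,
)
from .spectra_io import Spectrum, write_msp

__all__ = [
    "SimulationConfig",
    "DEFAULT_COMPOUNDS",
    "simulate_spectrum",
    "simulate_library",
]

_M_CH3 = ION_SPECIES["[M-CH3]+"]
_CLUSTER = (ION_SPECIES["[M-H]+"], ION_SPECIES["[M]+"], ION_SPECIES["[M+H]+"])


def _compound(name: str, formula: str, n_tms: int, n_meox: int = 0) -> DerivatizedCompound:
    return DerivatizedCompound(name, ElementalFormula.parse(formula), n_tms, n_meox)


#: literature base formulas of common GC-MS metabolites with typical
#: TMS/MEOX derivatization counts; includes the worked-example compounds
DEFAULT_COMPOUNDS: Tuple[DerivatizedCompound, ...] = (
    _compound("3,4-dihydroxyphenylacetic acid", "C8H8O4", 3),
    _compound("2,5-dihydroxyphenylacetic acid", "C8H8O4", 3),
    _compound("phosphoric acid", "H3PO4", 3),
    _compound("glycine", "C2H5NO2", 3),
    _compound("alanine", "C3H7NO2", 2),
    _compound("serine", "C3H7NO3", 3),
    _compound("glutamic acid", "C5H9NO4", 3),
    _compound("tyrosine", "C9H11NO3", 3),
    _compound("tryptophan", "C11H12N2O2", 3),
    _compound("lactic acid", "C3H6O3", 2),
    _compound("succinic acid", "C4H6O4", 2),
    _compound("citric acid", "C6H8O7", 4),
    _compound("malic acid", "C4H6O5", 3),
    _compound("glucose", "C6H12O6", 5, 1),
    _compound("fructose", "C6H12O6", 5, 1),
    _compound("myo-inositol", "C6H12O6", 6),
    _compound("urea", "CH4N2O", 2),
    _compound("uracil", "C4H4N2O2", 2),
    _compound("pyruvic acid", "C3H4O3", 1, 1),
    _compound("2-hydroxycinnamic acid", "C9H8O3", 2),
    _compound("palmitic acid", "C16H32O2", 1),
    _compound("nicotinic acid", "C6H5NO2", 1),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; the defaults follow observed CI statistics.

    ``species_abundance_priors`` gives the probability that each molecular
    cluster member carries the highest cluster intensity; the residual
    probability mass produces "hard" spectra (high-mass contaminants or
    near-noise intensities) that a strict detector cannot assign.
    """

    seed: int = 0
    species_abundance_priors: Dict[str, float] = field(
        default_factory=lambda: {"[M+H]+": 0.74, "[M-H]+": 0.07, "[M]+": 0.04}
    )
    p_c2h5: float = 0.90
    p_c3h5: float = 0.84
    p_water_loss: float = 0.06
    p_tms_adduct: float = 0.0
    mass_error_sd_ppm: float = 2.8
    n_noise_peaks: int = 5
    max_isotope_shift: int = 2
    merge_isotope_clusters: bool = False
    clean: bool = False

    def __post_init__(self) -> None:
        probs = list(self.species_abundance_priors.values()) + [
            self.p_c2h5, self.p_c3h5, self.p_water_loss, self.p_tms_adduct
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if sum(self.species_abundance_priors.values()) > 1.0 + 1e-9:
            raise ValueError("species priors must sum to <= 1")

    @property
    def p_hard(self) -> float:
        return 1.0 - sum(self.species_abundance_priors.values())


@dataclass(frozen=True)
class GroundTruth:
    name: str
    formula: str
    neutral_mass: float
    base_species: str
    n_tms: int
    n_meox: int
    contaminated: bool = False
    low_intensity: bool = False

    @property
    def hard(self) -> bool:
        return self.contaminated or self.low_intensity


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _expand(
    ion_formula: ElementalFormula,
    mz0: float,
    intensity: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> List[Tuple[float, float]]:
    """Isotopologue peaks of one ion, with ppm mass jitter unless clean."""
    if config.clean:
        return [(mz0, intensity)]
    pat = isotope_pattern(ion_formula, config.max_isotope_shift)
    mono_mass = pat.peaks[0][0]
    peaks = []
    for mass, ab in pat.peaks:
        mz = mz0 + (mass - mono_mass)
        mz *= 1.0 + rng.normal(0.0, config.mass_error_sd_ppm) * 1e-6
        peaks.append((mz, intensity * ab / pat.abundances[0]))
    return peaks


def simulate_spectrum(
    compound: DerivatizedCompound,
    config: SimulationConfig = SimulationConfig(),
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Spectrum, GroundTruth]:
    """One synthetic CI spectrum plus its ground-truth record.

    Intensities follow the qualitative CI bands: molecular-cluster species
    at >= 5% of the base peak, reagent adducts below 5%; [M-CH3]+ is the
    base peak. In ``clean`` mode the spectrum holds exactly the four
    pattern species at their theoretical m/z with no isotopes or noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    neutral = compound.derivatized_formula

    labels = list(config.species_abundance_priors)
    probs = [config.species_abundance_priors[k] for k in labels]
    draws = labels + ["hard"]
    base_label = str(rng.choice(draws, p=probs + [config.p_hard]))

    contaminated = low_intensity = False
    if base_label == "hard":
        contaminated = bool(rng.random() < 0.725)  # else: near-noise intensities
        low_intensity = not contaminated
        total = sum(probs)
        base_label = str(rng.choice(labels, p=[p / total for p in probs]))

    if config.clean:
        intensities = {
            "[M-CH3]+": 1.0,
            base_label: 0.8,
            "[M+C2H5]+": 0.04,
            "[M+C3H5]+": 0.03,
        }
    else:
        cluster_scale = _loguniform(rng, 0.008, 0.03) if low_intensity else 1.0
        base_int = _loguniform(rng, 0.15, 0.95)
        intensities = {"[M-CH3]+": 1.0, base_label: base_int * cluster_scale}
        # under unit-resolution merging the overlap effect needs the whole
        # cluster present at comparable abundance, as seen in wide CI spectra
        p_member = 1.0 if config.merge_isotope_clusters else 0.8
        lo, hi = (0.5, 0.95) if config.merge_isotope_clusters else (0.15, 0.9)
        for sp in _CLUSTER:
            if sp.label != base_label and rng.random() < p_member:
                intensities[sp.label] = (
                    base_int * rng.uniform(lo, hi) * cluster_scale
                )
        if rng.random() < config.p_c2h5:
            intensities["[M+C2H5]+"] = _loguniform(rng, 0.004, 0.045)
        if rng.random() < config.p_c3h5:
            intensities["[M+C3H5]+"] = _loguniform(rng, 0.004, 0.045)
        if rng.random() < config.p_water_loss:
            intensities["[M-H2O+H]+"] = _loguniform(rng, 0.004, 0.045)
        if contaminated or rng.random() < config.p_tms_adduct:
            intensities["[M+TMS]+"] = _loguniform(rng, 0.05, 0.3)

    peaks: List[Tuple[float, float]] = []
    cluster_peaks: List[Tuple[float, float]] = []
    for label, intensity in intensities.items():
        sp = ION_SPECIES[label]
        expanded = _expand(sp.apply(neutral), ion_mz(neutral, sp), intensity, config, rng)
        if config.merge_isotope_clusters and label in ("[M-H]+", "[M]+", "[M+H]+"):
            cluster_peaks.extend(expanded)
        else:
            peaks.extend(expanded)

    if cluster_peaks:
        bins: Dict[int, List[Tuple[float, float]]] = {}
        for mz, inten in cluster_peaks:
            bins.setdefault(round(mz), []).append((mz, inten))
        for members in bins.values():
            total = sum(i for _, i in members)
            mz = sum(m * i for m, i in members) / total
            peaks.append((mz, total))

    if not config.clean:
        for _ in range(config.n_noise_peaks):
            mz = rng.uniform(50.0, compound.neutral_mass)
            peaks.append((mz, _loguniform(rng, 0.0001, 0.0009)))

    truth = GroundTruth(
        name=compound.name,
        formula=neutral.hill(),
        neutral_mass=compound.neutral_mass,
        base_species=base_label,
        n_tms=compound.n_tms,
        n_meox=compound.n_meox,
        contaminated=contaminated,
        low_intensity=low_intensity,
    )
    spectrum = Spectrum(
        peaks,
        {
            "Name": compound.name,
            "Formula": neutral.hill(),
            "Comment": f"synthetic CI spectrum, {compound.n_tms} TMS {compound.n_meox} MEOX",
        },
    )
    return spectrum, truth


def simulate_library(
    compound_table: Sequence[DerivatizedCompound] = DEFAULT_COMPOUNDS,
    n: int = 100,
    config: SimulationConfig = SimulationConfig(),
) -> Tuple[List[Spectrum], List[GroundTruth]]:
    """Draw ``n`` spectra from the compound table under one seeded stream.

    Names are suffixed with a running index so records join uniquely to
    their ground truth.
    """
    if len(compound_table) == 0:
        raise ValueError("empty compound table")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed)
    spectra: List[Spectrum] = []
    truths: List[GroundTruth] = []
    for i in range(n):
        compound = compound_table[int(rng.integers(len(compound_table)))]
        unique = DerivatizedCompound(
            f"{compound.name} #{i}", compound.base_formula, compound.n_tms, compound.n_meox
        )
        spec, truth = simulate_spectrum(unique, config, rng)
        spectra.append(spec)
        truths.append(truth)
    return spectra, truths


def write_truth_csv(truths: Sequence[GroundTruth], stream: IO[str]) -> None:
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(
        ["name", "formula", "neutral_mass", "base_species", "n_tms", "n_meox",
         "contaminated", "low_intensity"]
    )
    for t in truths:
        writer.writerow(
            [t.name, t.formula, f"{t.neutral_mass:.4f}", t.base_species,
             t.n_tms, t.n_meox, int(t.contaminated), int(t.low_intensity)]
        )


def write_library(
    spectra: Sequence[Spectrum],
    truths: Sequence[GroundTruth],
    msp_stream: IO[str],
    truth_stream: IO[str],
) -> None:
    """Paired MSP + ground-truth CSV output."""
    write_msp(spectra, msp_stream)
    write_truth_csv(truths, truth_stream)
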