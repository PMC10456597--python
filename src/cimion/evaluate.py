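"""Scoring of detection and formula-ranking results against ground truth."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .chem_core import ElementalFormula
from .formula_assign import FormulaCandidate

__all__ = ["EvaluationReport", "score_detection", "score_formula_ranks"]

_TOP_KS = (1, 3, 5, 10)


@dataclass
class EvaluationReport:
    """Aggregate recognition / ranking metrics plus per-compound detail."""

    n_total: int
    n_recognized: int
    recognition_rate: float
    base_species_counts: Dict[str, int] = field(default_factory=dict)
    top_k_rates: Dict[int, float] = field(default_factory=dict)
    no_hit_rate: Optional[float] = None
    mass_tolerance: Optional[float] = None
    per_compound: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_recognized <= self.n_total:
            raise ValueError("n_recognized out of range")
        ks = sorted(self.top_k_rates)
        rates = [self.top_k_rates[k] for k in ks]
        if any(b < a - 1e-12 for a, b in zip(rates, rates[1:])):
            raise ValueError("top-k rates must be monotone non-decreasing in k")
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("rates must lie in [0, 1]")

    def to_dict(self) -> Dict:
        d = {
            "n_total": self.n_total,
            "n_recognized": self.n_recognized,
            "recognition_rate": self.recognition_rate,
            "base_species_counts": self.base_species_counts,
            "top_k_rates": {str(k): v for k, v in self.top_k_rates.items()},
            "no_hit_rate": self.no_hit_rate,
            "mass_tolerance": self.mass_tolerance,
        }
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def table(self) -> str:
        lines = [
            f"n_total              {self.n_total}",
            f"n_recognized         {self.n_recognized}",
            f"recognition_rate     {self.recognition_rate:.3f}",
        ]
        if self.mass_tolerance is not None:
            lines.append(f"mass_tolerance       {self.mass_tolerance}")
        for sp, n in sorted(self.base_species_counts.items()):
            lines.append(f"base {sp:<15} {n}")
        for k in sorted(self.top_k_rates):
            lines.append(f"top-{k:<2} rate          {self.top_k_rates[k]:.3f}")
        if self.no_hit_rate is not None:
            lines.append(f"no-hit rate          {self.no_hit_rate:.3f}")
        return "\n".join(lines)


def score_detection(
    assignments: pd.DataFrame,
    truth: pd.DataFrame,
    mass_tolerance: float = 0.005,
) -> EvaluationReport:
    """Join detector output to ground truth on name and score recognition.

    A compound counts as recognized when its assignment is not rejected and
    the assigned neutral mass lies within ``mass_tolerance`` of the true
    one. Unmatched names are kept as flagged rows, never dropped silently.
    """
    merged = assignments.merge(
        truth, on="name", how="outer", suffixes=("", "_true"), indicator=True
    )
    rows = []
    n_recognized = 0
    species_counts: Dict[str, int] = {}
    for _, row in merged.iterrows():
        matched = row["_merge"] == "both"
        recognized = False
        if matched and not row["rejected"] and pd.notna(row["neutral_mass"]):
            true_mass = float(row["neutral_mass_true"])
            recognized = abs(float(row["neutral_mass"]) - true_mass) <= mass_tolerance
        if recognized:
            n_recognized += 1
            sp = row.get("base_species", "")
            species_counts[sp] = species_counts.get(sp, 0) + 1
        rows.append(
            {
                "name": row["name"],
                "matched": matched,
                "recognized": recognized,
                "base_species": row.get("base_species", ""),
                "true_base_species": row.get("base_species_true", ""),
                "rejected": row.get("rejected", True),
                "reason": row.get("reason", "" if matched else "unmatched name"),
            }
        )
    n_total = len(merged)
    return EvaluationReport(
        n_total=n_total,
        n_recognized=n_recognized,
        recognition_rate=n_recognized / n_total if n_total else 0.0,
        base_species_counts=species_counts,
        mass_tolerance=mass_tolerance,
        per_compound=pd.DataFrame(rows),
    )


def score_formula_ranks(
    candidate_lists: Mapping[str, Sequence[FormulaCandidate]],
    truth_formulas: Mapping[str, str],
) -> EvaluationReport:
    """Rank of the true derivatized formula per compound; top-k summary.

    Correctness is strict element-count equality of the neutral formula —
    isobaric formulas never count.
    """
    rows: List[Dict] = []
    hits_at: Dict[int, int] = {k: 0 for k in _TOP_KS}
    n_no_hit = 0
    for name, candidates in candidate_lists.items():
        true_formula = ElementalFormula.parse(truth_formulas[name])
        rank = None
        for i, cand in enumerate(candidates, start=1):
            if cand.formula.counts == true_formula.counts:
                rank = i
                break
        if rank is None:
            n_no_hit += 1
        else:
            for k in _TOP_KS:
                if rank <= k:
                    hits_at[k] += 1
        rows.append({"name": name, "rank": rank, "n_candidates": len(candidates)})
    n = len(rows)
    return EvaluationReport(
        n_total=n,
        n_recognized=n - n_no_hit,
        recognition_rate=(n - n_no_hit) / n if n else 0.0,
        top_k_rates={k: hits_at[k] / n for k in _TOP_KS} if n else {},
        no_hit_rate=n_no_hit / n if n else None,
        per_compound=pd.DataFrame(rows),
    )
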