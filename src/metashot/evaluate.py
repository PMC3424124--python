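"""Score a classification run against simulation truth.

Detection is scored as set arithmetic over species keys, with
reference-awareness: false negatives whose species is absent from the
reference are reported separately, since no alignment-based method can
recover them. Read-level accuracy is the per-species fraction of inserted
reads attributed to the correct species, averaged unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["DetectionReport", "evaluate_detection", "assignment_accuracy", "AccuracyReport"]


@dataclass
class DetectionReport:
    truth_species: set[str]
    detected_species: set[str]
    reference_species: set[str]
    true_positives: set[str] = field(init=False)
    false_positives: set[str] = field(init=False)
    false_negatives: set[str] = field(init=False)
    fn_absent_from_reference: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.true_positives = self.truth_species & self.detected_species
        self.false_positives = self.detected_species - self.truth_species
        self.false_negatives = self.truth_species - self.detected_species
        self.fn_absent_from_reference = self.false_negatives - self.reference_species

    @property
    def recall(self) -> float:
        if not self.truth_species:
            return 1.0
        return len(self.true_positives) / len(self.truth_species)

    @property
    def precision(self) -> float:
        # vacuous truth when nothing was called: no wrong calls were made
        if not self.detected_species:
            return 1.0
        return len(self.true_positives) / len(self.detected_species)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for sp in sorted(self.truth_species | self.detected_species):
            if sp in self.true_positives:
                status = "TP"
            elif sp in self.false_positives:
                status = "FP"
            else:
                status = "FN_absent_from_reference" if sp in self.fn_absent_from_reference else "FN"
            rows.append({"species_key": sp, "status": status,
                         "in_reference": sp in self.reference_species})
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# recall={self.recall:.6f}\tprecision={self.precision:.6f}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)


def evaluate_detection(
    truth: Iterable[str],
    detected: Iterable[str],
    reference_species: Iterable[str],
) -> DetectionReport:
    """Exact set arithmetic over species keys; see :class:`DetectionReport`."""
    return DetectionReport(
        truth_species=set(truth),
        detected_species=set(detected),
        reference_species=set(reference_species),
    )


@dataclass
class AccuracyReport:
    per_species: dict[str, float]
    inserted: dict[str, int]
    correct: dict[str, int]

    @property
    def mean(self) -> float:
        """Unweighted mean over truth species."""
        if not self.per_species:
            return float("nan")
        return sum(self.per_species.values()) / len(self.per_species)

    def to_dataframe(self) -> pd.DataFrame:
        rows = sorted(self.per_species.items(), key=lambda kv: (-self.inserted[kv[0]], kv[0]))
        return pd.DataFrame(
            {
                "species_key": [k for k, _ in rows],
                "inserted": [self.inserted[k] for k, _ in rows],
                "correct": [self.correct[k] for k, _ in rows],
                "fraction_correct": [f for _, f in rows],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# unweighted_mean={self.mean:.6f}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)


def assignment_accuracy(
    truth: Mapping[str, str],
    attribution: Mapping[str, str | None],
) -> AccuracyReport:
    """Per-species fraction of inserted reads attributed correctly.

    ``truth`` maps every read id to its source species; ``attribution`` maps
    read ids to the attributed species (missing or ``None`` counts as
    incorrect). An attributed read that the truth does not know is an error.
    """
    stray = set(attribution) - set(truth)
    if stray:
        raise KeyError(f"attributed reads absent from truth: {sorted(stray)[:5]} ...")
    inserted: dict[str, int] = {}
    correct: dict[str, int] = {}
    for read_id, species in truth.items():
        inserted[species] = inserted.get(species, 0) + 1
        correct.setdefault(species, 0)
        if attribution.get(read_id) == species:
            correct[species] += 1
    per_species = {sp: correct[sp] / inserted[sp] for sp in inserted}
    return AccuracyReport(per_species=per_species, inserted=inserted, correct=correct)
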