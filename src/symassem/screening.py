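"""Clone-library screening: the sequence inclusion/exclusion rules applied before statistics.

A variant observed in the dataset is retained iff it is either previously
published, or was recovered at least three times across at least three
independent samples (an adult and an egg of the same colony count as two
samples), and it is not pseudogene-flagged. The pseudogene flag overrides
everything, including published status.

Screening is dataset-wide and happens exactly once, before any distance or
assemblage statistic (including the percent similarity index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io import CloneLibrary, SequenceVariant

__all__ = ["ScreenReport", "screen_variants", "apply_screen", "clade_count"]

MIN_RECOVERIES = 3
MIN_SAMPLES = 3


@dataclass
class ScreenReport:
    """Outcome of dataset-wide variant screening.

    ``excluded`` maps each removed label to its reason: ``"rare"`` (fails the
    three-recoveries-in-three-samples rule and unpublished) or ``"pseudogene"``.
    """

    retained: set[str] = field(default_factory=set)
    excluded: dict[str, str] = field(default_factory=dict)

    def status(self, label: str) -> str:
        if label in self.retained:
            return "retained"
        if label in self.excluded:
            return "excluded"
        return "unobserved"

    def to_frame(self) -> pd.DataFrame:
        rows = [{"label": l, "status": "retained", "reason": ""} for l in sorted(self.retained)]
        rows += [
            {"label": l, "status": "excluded", "reason": r}
            for l, r in sorted(self.excluded.items())
        ]
        return pd.DataFrame(rows, columns=["label", "status", "reason"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def screen_variants(
    libraries: Sequence[CloneLibrary],
    variants: Mapping[str, SequenceVariant],
) -> ScreenReport:
    """Classify every label observed in at least one library as retained or excluded."""
    if not libraries:
        raise ValueError("cannot screen an empty library list")
    totals: dict[str, int] = {}
    samples: dict[str, set[str]] = {}
    for lib in libraries:
        for label, c in lib.counts.items():
            totals[label] = totals.get(label, 0) + c
            samples.setdefault(label, set()).add(lib.sample_id)

    report = ScreenReport()
    for label in totals:
        v = variants.get(label)
        pseudogene = v.pseudogene_flagged if v is not None else False
        published = v.published if v is not None else False
        if pseudogene:
            report.excluded[label] = "pseudogene"
        elif published or (totals[label] >= MIN_RECOVERIES and len(samples[label]) >= MIN_SAMPLES):
            report.retained.add(label)
        else:
            report.excluded[label] = "rare"
    return report


def apply_screen(library: CloneLibrary, report: ScreenReport) -> CloneLibrary:
    """Restrict a library to retained labels.

    A library whose every clone is excluded comes back explicitly empty;
    downstream statistics must reject empty libraries.
    """
    kept = {l: c for l, c in library.counts.items() if l in report.retained}
    return CloneLibrary(
        sample_id=library.sample_id,
        colony_id=library.colony_id,
        site=library.site,
        year=library.year,
        life_stage=library.life_stage,
        morphology=library.morphology,
        counts=kept,
    )


def clade_count(library: CloneLibrary, variants: Mapping[str, SequenceVariant]) -> int:
    """Number of distinct symbiont clades present in a (screened, non-empty) library."""
    if library.is_empty():
        raise ValueError(f"cannot count clades of empty library {library.sample_id!r}")
    clades = set()
    for label in library.counts:
        v = variants.get(label)
        clades.add(v.clade if v is not None else label[0].upper())
    return len(clades)
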