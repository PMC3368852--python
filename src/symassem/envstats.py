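"""Site-level environmental summaries and Kruskal-Wallis comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import EnvSeries

__all__ = ["EnvSummary", "summarize", "kruskal_wallis"]


@dataclass
class EnvSummary:
    site: str
    variable: str
    mean: float
    sd: float
    min: float
    max: float
    n: int

    def __post_init__(self) -> None:
        if not self.min <= self.mean <= self.max:
            raise ValueError("mean outside [min, max]")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def summarize(series: EnvSeries) -> EnvSummary:
    """Arithmetic mean, sample SD (n-1 denominator), min, max and n for one series."""
    v = np.asarray(series.values, dtype=float)
    if v.size == 0:
        raise ValueError(f"empty series {series.site}/{series.variable}")
    return EnvSummary(
        site=series.site,
        variable=series.variable,
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        min=float(v.min()),
        max=float(v.max()),
        n=int(v.size),
    )


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with df = k-1 and chi-square p.

    Logger data is heavily tied (0.2 degC resolution), so the tie correction
    matters. If every observation across all groups is identical the statistic
    is defined as H = 0 with p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for g in arrays:
        if g.size == 0:
            raise ValueError("groups must be non-empty")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), df, float(p)
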