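"""Per-sample cas-gene percentages and paired habitat comparisons.

The cas-gene percentage of a sample is 100 times the number of annotated
cas genes over the total gene count of that subject x body-habitat sample.
Habitat contrasts use a two-tailed paired t-test across subjects (subjects
missing either habitat are dropped listwise); stool-vs-oral association is
summarized with the Pearson correlation coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_model import SampleInventory

__all__ = [
    "HabitatComparison",
    "cas_percentage",
    "paired_ttest",
    "pearson_r",
    "percentages_by_habitat",
    "compare_habitats",
]


@dataclass(frozen=True)
class HabitatComparison:
    habitat_a: str
    habitat_b: str
    n_pairs: int
    t_statistic: float
    p_value: float
    mean_diff: float  # percentage points, a - b
    degenerate: bool = False  # zero variance of differences with nonzero mean


def cas_percentage(sample: SampleInventory) -> float:
    """100 * n_cas_genes / n_total_genes."""
    if sample.n_total_genes <= 0:
        raise ValueError(
            f"sample {sample.subject_id}/{sample.habitat}: zero total genes"
        )
    return 100.0 * sample.n_cas_genes / sample.n_total_genes


def paired_ttest(x: list[float], y: list[float]) -> tuple[float, float]:
    """Two-tailed paired t-test.

    t = mean(d) / (SD_sample(d) / sqrt(n)) with d = x - y; the p-value comes
    from the Student t distribution with n - 1 degrees of freedom.  All
    pairs identical gives t = 0, p = 1; zero variance with nonzero mean is
    reported as (inf-signed t, p = 0).
    """
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, mean), 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def pearson_r(x: list[float], y: list[float]) -> float:
    """Product-moment correlation; requires n >= 3 and nonzero variance."""
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(xa, ya).statistic)


def percentages_by_habitat(
    samples: list[SampleInventory],
) -> dict[str, dict[str, float]]:
    """{habitat: {subject_id: cas percentage}}."""
    out: dict[str, dict[str, float]] = {}
    for s in samples:
        out.setdefault(s.habitat, {})[s.subject_id] = cas_percentage(s)
    return out


def compare_habitats(
    samples: list[SampleInventory],
    pairs: list[tuple[str, str]],
) -> list[HabitatComparison]:
    """Paired t-tests between habitat pairs over shared subjects.

    Subjects missing either habitat of a pair are dropped from that
    comparison (listwise deletion), mirroring a cohort restricted to
    subjects sampled at every site.
    """
    table = percentages_by_habitat(samples)
    out = []
    for a, b in pairs:
        if a not in table or b not in table:
            raise ValueError(f"habitat missing from cohort: {a!r} or {b!r}")
        shared = sorted(set(table[a]) & set(table[b]))
        x = [table[a][s] for s in shared]
        y = [table[b][s] for s in shared]
        t, p = paired_ttest(x, y)
        out.append(
            HabitatComparison(
                habitat_a=a, habitat_b=b, n_pairs=len(shared),
                t_statistic=t, p_value=p,
                mean_diff=float(np.mean(np.asarray(x) - np.asarray(y))),
                degenerate=math.isinf(t),
            )
        )
    return out
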