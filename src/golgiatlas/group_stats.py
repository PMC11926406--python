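"""Group statistics for per-cell colocalization values.

Per-group mean ± SEM summaries, Dunnett's many-to-one comparisons against a
control group (classic equal-variance form, family-wise adjusted p-values
from the multivariate t distribution of the contrasts), and two-sided
pooled-variance unpaired t-tests.  Significance stars follow the usual
convention: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summarize",
    "dunnett_vs_control",
    "unpaired_t",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < threshold:
            return stars
    return "ns"


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SEM of one group's per-cell values (SEM undefined for n = 1)."""

    label: str
    n_cells: int
    mean: float
    sem: float  # NaN when n == 1
    values: tuple[float, ...]


@dataclass(frozen=True)
class ComparisonResult:
    label: str
    statistic: float
    p_adjusted: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_adjusted <= 1.0:
            raise ValueError("p must be in [0, 1]")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted)


def summarize(groups: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """Mean, sample SD (n−1 denominator) and SEM = SD/√n per group."""
    out = []
    for label, values in groups.items():
        v = np.asarray(values, dtype=np.float64)
        if v.size == 0:
            raise ValueError(f"empty group {label!r}")
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
        out.append(
            GroupSummary(
                label=label,
                n_cells=int(v.size),
                mean=float(v.mean()),
                sem=sem,
                values=tuple(float(x) for x in v),
            )
        )
    return out


def dunnett_vs_control(
    groups: Mapping[str, Sequence[float]],
    control_label: str,
    seed: int = 0,
) -> list[ComparisonResult]:
    """Two-sided Dunnett many-to-one comparisons against the control group.

    Uses pooled within-group variance across all groups; the family-wise
    adjusted p for each contrast comes from the joint multivariate t
    distribution of the k standardized contrasts (numerically integrated;
    accuracy ~±0.002, so k = 1 reduces to the pooled two-sample t-test).
    """
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing")
    labels = [lab for lab in groups if lab != control_label]
    if not labels:
        raise ValueError("need at least one non-control group")
    samples = []
    for lab in list(groups):
        v = np.asarray(groups[lab], dtype=np.float64)
        if v.size < 2:
            raise ValueError(f"group {lab!r} needs n >= 2")
        samples.append(v)
    control = np.asarray(groups[control_label], dtype=np.float64)
    treatments = [np.asarray(groups[lab], dtype=np.float64) for lab in labels]
    res = stats.dunnett(
        *treatments,
        control=control,
        alternative="two-sided",
        random_state=np.random.default_rng(seed),
    )
    return [
        ComparisonResult(
            label=f"{lab} vs {control_label}",
            statistic=float(res.statistic[i]),
            p_adjusted=float(min(max(res.pvalue[i], 0.0), 1.0)),
            method="dunnett",
        )
        for i, lab in enumerate(labels)
    ]


def unpaired_t(groups: Mapping[str, Sequence[float]]) -> ComparisonResult:
    """Two-sided pooled-variance (equal-variance) unpaired t-test of two groups."""
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    (la, va), (lb, vb) = groups.items()
    a = np.asarray(va, dtype=np.float64)
    b = np.asarray(vb, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return ComparisonResult(
        label=f"{la} vs {lb}",
        statistic=float(t),
        p_adjusted=float(p),
        method="t_test",
    )
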