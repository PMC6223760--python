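"""Target-registration-error evaluation and group statistics.

TRE is the Euclidean distance between a target's registered (predicted)
position and its measured position — here, the tumour centre localized via
the tracked ultrasound click.  Trials are grouped by method, displacement
axis and displacement magnitude; each group is summarized by mean, sample
standard deviation, min, max, and repeatability (standard deviation of the
mean, sd/sqrt(n)).

Two comparisons are provided: a classical balanced one-way ANOVA (are the
displacement-group means equal?) and a Welch unequal-variance test of two
group means with the Welch–Satterthwaite fractional degrees of freedom.
Both are implemented from their textbook decompositions; the test suite
cross-checks them against scipy's independent implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateError, EmptyGroupError
from .phantom import TrialRecord

__all__ = [
    "GroupSummary",
    "TestResult",
    "tre",
    "summarize_groups",
    "summaries_to_frame",
    "one_way_anova",
    "welch_test",
    "plot_tre_by_group",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group TRE statistics (all in mm)."""

    method: str
    axis: str
    displacement_mm: float
    n: int
    mean: float
    sd: float
    min: float
    max: float
    repeatability: float


@dataclass(frozen=True)
class TestResult:
    """Statistic, degrees of freedom (tuple for F, scalar for t), p-value."""

    statistic: float
    df: Union[float, tuple[float, float]]
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def tre(p_estimated: Sequence[float], p_true: Sequence[float]) -> float:
    """Euclidean distance (mm) between predicted and measured target."""
    d = np.asarray(p_estimated, dtype=float) - np.asarray(p_true, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("points must be finite")
    return float(np.linalg.norm(d))


def summarize_groups(trials: Sequence[TrialRecord]) -> list[GroupSummary]:
    """One summary per (method, axis, displacement) group.

    Repeatability is sd/sqrt(n) with the sample (n-1) standard deviation.

    Raises
    ------
    EmptyGroupError
        If any group holds fewer than two trials.
    """
    frame = pd.DataFrame(
        {
            "method": [t.method for t in trials],
            "axis": [t.axis for t in trials],
            "displacement_mm": [t.displacement_mm for t in trials],
            "tre_mm": [t.tre_mm for t in trials],
        }
    )
    if frame.empty:
        raise EmptyGroupError("no trials to summarize")
    out = []
    for (method, axis, disp), grp in frame.groupby(
        ["method", "axis", "displacement_mm"], sort=True
    ):
        x = grp["tre_mm"].to_numpy()
        if x.size < 2:
            raise EmptyGroupError(
                f"group {method}/{axis}/{disp} has {x.size} trial(s); need >=2"
            )
        sd = float(np.std(x, ddof=1))
        out.append(
            GroupSummary(
                method=method,
                axis=axis,
                displacement_mm=float(disp),
                n=int(x.size),
                mean=float(np.mean(x)),
                sd=sd,
                min=float(np.min(x)),
                max=float(np.max(x)),
                repeatability=sd / np.sqrt(x.size),
            )
        )
    return out


def summaries_to_frame(
    summaries: Sequence[GroupSummary], rounded: bool = False
) -> pd.DataFrame:
    """Tabulate summaries; ``rounded=True`` prints one decimal for
    mean/sd/min/max and two for repeatability (report formatting)."""
    frame = pd.DataFrame([s.__dict__ for s in summaries])
    if rounded:
        for col in ("mean", "sd", "min", "max"):
            frame[col] = frame[col].round(1)
        frame["repeatability"] = frame["repeatability"].round(2)
    return frame


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Classical one-way fixed-effects ANOVA.

    F = MSB/MSW with (k-1, N-k) degrees of freedom; the p-value comes from
    the F distribution's survival function.

    Raises
    ------
    EmptyGroupError
        Fewer than two groups, or any group with fewer than two values.
    DegenerateError
        Zero within-group variance (MSW = 0).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise EmptyGroupError("ANOVA needs >=2 groups with >=2 values each")
    k = len(gs)
    n_total = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = k - 1, n_total - k
    msw = ssw / df_w
    if msw == 0.0:
        raise DegenerateError("zero within-group variance; F undefined")
    f = (ssb / df_b) / msw
    return TestResult(
        statistic=float(f),
        df=(float(df_b), float(df_w)),
        p_value=float(stats.f.sf(f, df_b, df_w)),
    )


def welch_test(g1: Sequence[float], g2: Sequence[float]) -> TestResult:
    """Welch's unequal-variance test of two means.

    Returns the t statistic with the Welch–Satterthwaite (fractional)
    degrees of freedom and the two-sided p-value.

    Raises
    ------
    EmptyGroupError
        Either group has fewer than two values.
    DegenerateError
        Both groups have zero variance.
    """
    x1 = np.asarray(g1, dtype=float)
    x2 = np.asarray(g2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise EmptyGroupError("Welch test needs >=2 values per group")
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        raise DegenerateError("both groups have zero variance")
    se1, se2 = v1 / x1.size, v2 / x2.size
    t = (x1.mean() - x2.mean()) / np.sqrt(se1 + se2)
    df = (se1 + se2) ** 2 / (
        se1**2 / (x1.size - 1) + se2**2 / (x2.size - 1)
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(statistic=float(t), df=float(df), p_value=min(p, 1.0))


def plot_tre_by_group(summaries: Sequence[GroupSummary], ax=None):
    """Simple TRE-by-group chart: mean ± sd per displacement, per method."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    frame = summaries_to_frame(summaries)
    for (method, axis), grp in frame.groupby(["method", "axis"]):
        grp = grp.sort_values("displacement_mm")
        ax.errorbar(
            grp["displacement_mm"],
            grp["mean"],
            yerr=grp["sd"],
            marker="o",
            capsize=3,
            label=f"{method} / {axis}",
        )
    ax.set_xlabel("displacement (mm)")
    ax.set_ylabel("TRE (mm)")
    ax.legend()
    return ax
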