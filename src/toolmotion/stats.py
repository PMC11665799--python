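"""Group statistics over the per-trial skill metrics.

Two experiments are supported, both reported with two-sided p-values from
the Student t distribution:

* novices vs. experts — a pooled-variance independent t-test per metric,
  every trial contributing one observation (df = n1 + n2 - 2; 46 at the
  full 6+6 participants x 4 trials design). Treating repeated trials of one
  participant as independent observations is a simplification; it is the
  procedure reproduced here, not a recommendation. Welch's unequal-variance
  variant is available behind a flag.
* first vs. last trial within a group — a paired t-test per metric on each
  participant's (trial 1, trial 4) values, df = n_participants - 1.

No multiple-testing correction is applied; p-values are reported raw, one
per metric.

Learning curves are per-trial-index group means of each metric, normalized
by the minimum raw value that metric attains over all expert trials, so
the best expert trial sits at 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import EXPERT, GROUPS, METRIC_NAMES, NOVICE, ValidationError


def t_two_sided_p(t: float, df: int) -> float:
    """Two-sided tail probability 2*P(T_df >= |t|) of the Student t."""
    if df < 1:
        raise ValidationError(f"degrees of freedom must be >= 1, got {df}")
    return float(2.0 * sps.t.sf(abs(t), df))


@dataclass(slots=True)
class TTestResult:
    """One t-test: statistic, df, two-sided p and group summaries."""

    kind: str  # "independent" or "paired"
    statistic: float
    degrees_of_freedom: int
    p_two_sided: float
    mean_1: float
    sd_1: float
    n_1: int
    mean_2: float
    sd_2: float
    n_2: int
    metric: Optional[str] = None
    zero_variance: bool = False

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "kind": self.kind,
            "t": self.statistic,
            "df": self.degrees_of_freedom,
            "p": self.p_two_sided,
            "mean_1": self.mean_1,
            "sd_1": self.sd_1,
            "n_1": self.n_1,
            "mean_2": self.mean_2,
            "sd_2": self.sd_2,
            "n_2": self.n_2,
            "zero_variance": self.zero_variance,
        }


def independent_t_test(
    novice_values: Sequence[float],
    expert_values: Sequence[float],
    welch: bool = False,
) -> TTestResult:
    """Two-sample t-test with novices as group 1 (t > 0 when novices higher).

    Pooled-variance Student t by default (df = n1 + n2 - 2); set ``welch``
    for the unequal-variance variant with Welch–Satterthwaite df.
    """
    a = np.asarray(novice_values, dtype=float)
    b = np.asarray(expert_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least two observations")
    var_a = float(a.var(ddof=1))
    var_b = float(b.var(ddof=1))
    diff = float(a.mean() - b.mean())

    zero_variance = var_a == 0.0 and var_b == 0.0
    if welch:
        res = sps.ttest_ind(a, b, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        df = int(round(float(res.df)))
        if zero_variance:
            t = math.inf if diff > 0 else (-math.inf if diff < 0 else 0.0)
            p = 0.0 if diff != 0 else 1.0
    else:
        df = a.size + b.size - 2
        pooled = ((a.size - 1) * var_a + (b.size - 1) * var_b) / df
        if pooled == 0.0:
            t = math.inf if diff > 0 else (-math.inf if diff < 0 else 0.0)
            p = 0.0 if diff != 0 else 1.0
        else:
            t = diff / math.sqrt(pooled * (1.0 / a.size + 1.0 / b.size))
            p = t_two_sided_p(t, df)
    return TTestResult(
        kind="independent",
        statistic=t,
        degrees_of_freedom=df,
        p_two_sided=p,
        mean_1=float(a.mean()),
        sd_1=math.sqrt(var_a),
        n_1=int(a.size),
        mean_2=float(b.mean()),
        sd_2=math.sqrt(var_b),
        n_2=int(b.size),
        zero_variance=zero_variance,
    )


def paired_t_test(first: Sequence[float], last: Sequence[float]) -> TTestResult:
    """Paired t-test on d = first - last (t > 0 when values decreased)."""
    a = np.asarray(first, dtype=float)
    b = np.asarray(last, dtype=float)
    if a.size != b.size:
        raise ValidationError(f"paired samples differ in length ({a.size} vs {b.size})")
    if a.size < 2:
        raise ValidationError("paired test needs at least two pairs")
    d = a - b
    n = d.size
    df = n - 1
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    zero_variance = sd == 0.0
    if zero_variance:
        t = math.inf if mean > 0 else (-math.inf if mean < 0 else 0.0)
        p = 0.0 if mean != 0 else 1.0
    else:
        t = mean / (sd / math.sqrt(n))
        p = t_two_sided_p(t, df)
    return TTestResult(
        kind="paired",
        statistic=t,
        degrees_of_freedom=df,
        p_two_sided=p,
        mean_1=float(a.mean()),
        sd_1=float(a.std(ddof=1)),
        n_1=n,
        mean_2=float(b.mean()),
        sd_2=float(b.std(ddof=1)),
        n_2=n,
        zero_variance=zero_variance,
    )


def compare_groups(metric_table: pd.DataFrame, welch: bool = False) -> list[TTestResult]:
    """Independent t-test per metric, novice trials vs. expert trials."""
    present = set(metric_table["group"])
    missing = set(GROUPS) - present
    if missing:
        raise ValidationError(f"metric table lacks group(s) {sorted(missing)}")
    results = []
    novice = metric_table[metric_table["group"] == NOVICE]
    expert = metric_table[metric_table["group"] == EXPERT]
    for name in METRIC_NAMES:
        res = independent_t_test(novice[name].to_numpy(), expert[name].to_numpy(), welch=welch)
        res.metric = name
        results.append(res)
    return results


def first_vs_last(metric_table: pd.DataFrame, group: str) -> list[TTestResult]:
    """Paired t-test per metric between each participant's first and last trial."""
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}; expected one of {GROUPS}")
    sub = metric_table[metric_table["group"] == group]
    if sub.empty:
        raise ValidationError(f"no trials for group {group!r}")
    first_idx = int(sub["trial_index"].min())
    last_idx = int(sub["trial_index"].max())
    if first_idx == last_idx:
        raise ValidationError("need at least two distinct trial indices")
    firsts, lasts = [], []
    for pid, rows in sub.groupby("participant_id", sort=True):
        by_trial = rows.set_index("trial_index")
        for idx in (first_idx, last_idx):
            if idx not in by_trial.index:
                raise ValidationError(
                    f"participant {pid!r} is missing trial {idx}"
                )
        firsts.append(by_trial.loc[first_idx])
        lasts.append(by_trial.loc[last_idx])
    results = []
    for name in METRIC_NAMES:
        res = paired_t_test(
            [row[name] for row in firsts], [row[name] for row in lasts]
        )
        res.metric = name
        results.append(res)
    return results


@dataclass(slots=True)
class LearningCurve:
    """Group-mean trajectory of one metric over trial indices.

    Means are divided by the minimum raw value the metric attains over all
    expert trials, so 1.0 marks the best expert trial.
    """

    metric: str
    trial_indices: list[int]
    novice_mean: list[float]
    expert_mean: list[float]
    normalizer: float

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "trial_indices": list(self.trial_indices),
            "novice_mean": list(self.novice_mean),
            "expert_mean": list(self.expert_mean),
            "normalizer": self.normalizer,
        }


def learning_curves(metric_table: pd.DataFrame) -> list[LearningCurve]:
    """Normalized per-trial-index group means for every metric."""
    expert = metric_table[metric_table["group"] == EXPERT]
    if expert.empty:
        raise ValidationError("normalization undefined without expert trials")
    indices = sorted(int(i) for i in metric_table["trial_index"].unique())
    curves = []
    for name in METRIC_NAMES:
        normalizer = float(expert[name].min())
        if normalizer == 0.0:
            raise ValidationError(
                f"minimum expert value of {name!r} is 0; normalization undefined"
            )
        novice_mean, expert_mean = [], []
        for idx in indices:
            rows = metric_table[metric_table["trial_index"] == idx]
            novice_mean.append(
                float(rows.loc[rows["group"] == NOVICE, name].mean()) / normalizer
            )
            expert_mean.append(
                float(rows.loc[rows["group"] == EXPERT, name].mean()) / normalizer
            )
        curves.append(
            LearningCurve(
                metric=name,
                trial_indices=indices,
                novice_mean=novice_mean,
                expert_mean=expert_mean,
                normalizer=normalizer,
            )
        )
    return curves


def learning_curve_table(curves: Sequence[LearningCurve]) -> pd.DataFrame:
    """Long-format table: metric, trial_index, group, normalized mean."""
    rows = []
    for curve in curves:
        for idx, nov, exp in zip(curve.trial_indices, curve.novice_mean, curve.expert_mean):
            rows.append({"metric": curve.metric, "trial_index": idx, "group": NOVICE, "normalized_mean": nov})
            rows.append({"metric": curve.metric, "trial_index": idx, "group": EXPERT, "normalized_mean": exp})
    return pd.DataFrame(rows, columns=["metric", "trial_index", "group", "normalized_mean"])
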