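"""Feature screening by one-way ANOVA with Tukey HSD pairwise comparisons.

A feature is informative for a cascade step when its class means separate.
Screening runs the classical one-way F test and then Tukey's honestly-
significant-difference procedure on every class pair (Tukey-Kramer standard
errors for unbalanced groups); under the default ``all_pairs`` rule a feature
is retained only when *every* pairwise comparison is significant at alpha.
The studentized-range tail probabilities come from the studentized-range
distribution (numerically integrated); a Monte-Carlo cross-check lives in
the test suite.  The module also provides the notched-boxplot interval
``median +/- 1.57 * IQR / sqrt(n)``, the visual median-difference heuristic
used alongside the formal test.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SelectionConfig",
    "FeatureScreen",
    "SelectionReport",
    "anova_f",
    "tukey_hsd",
    "select_features",
    "notch_interval",
]


@dataclass(frozen=True)
class SelectionConfig:
    alpha: float = 0.05
    rule: str = "all_pairs"  # all_pairs | any_pair
    scope: str = "train_only"  # train_only | all_data

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.rule not in ("all_pairs", "any_pair"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.scope not in ("train_only", "all_data"):
            raise ValueError(f"unknown scope {self.scope!r}")


def _group_stats(groups: Sequence[np.ndarray]) -> tuple[int, int, float, np.ndarray, np.ndarray]:
    ns = np.array([len(g) for g in groups])
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if (ns < 2).any():
        raise ValueError("every group needs at least 2 values")
    k = len(groups)
    n_tot = int(ns.sum())
    if n_tot - k < 1:
        raise ValueError("within-group degrees of freedom must be >= 1")
    means = np.array([float(np.mean(g)) for g in groups])
    ssw = float(sum(np.sum((np.asarray(g, float) - m) ** 2) for g, m in zip(groups, means)))
    msw = ssw / (n_tot - k)
    return k, n_tot, msw, means, ns


def anova_f(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA: F = MSB/MSW with df (k-1, N-k) and its
    p-value.

    A degenerate input with zero within-group variance and unequal means
    yields ``(inf, 0.0)``.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k, n_tot, msw, means, ns = _group_stats(arrs)
    grand = float(np.sum(ns * means) / n_tot)
    ssb = float(np.sum(ns * (means - grand) ** 2))
    msb = ssb / (k - 1)
    if msw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = msb / msw
    p = float(stats.f.sf(f, k - 1, n_tot - k))
    return f, p


@dataclass
class TukeyResult:
    """All-pairs Tukey HSD outcome."""

    pairs: list[tuple[int, int]]
    q: list[float]  # studentized-range statistics
    p: list[float]
    significant: list[bool]
    degenerate: bool = False  # zero within-group variance

    @property
    def all_significant(self) -> bool:
        return all(self.significant)

    @property
    def any_significant(self) -> bool:
        return any(self.significant)


def tukey_hsd(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> TukeyResult:
    """Tukey's HSD on every group pair.

    For pair (i, j): ``q_ij = |mean_i - mean_j| / sqrt(MSW*(1/n_i + 1/n_j)/2)``
    (Tukey-Kramer form, exact for balanced groups) compared against the
    studentized-range distribution with k groups and N-k degrees of freedom.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k, n_tot, msw, means, ns = _group_stats(arrs)
    df = n_tot - k
    pairs = list(itertools.combinations(range(k), 2))
    qs: list[float] = []
    ps: list[float] = []
    sig: list[bool] = []
    degenerate = msw == 0.0
    for i, j in pairs:
        diff = abs(means[i] - means[j])
        if degenerate:
            q = math.inf if diff > 0 else 0.0
            p = 0.0 if diff > 0 else 1.0
        else:
            q = diff / math.sqrt(msw * (1.0 / ns[i] + 1.0 / ns[j]) / 2.0)
            p = float(stats.studentized_range.sf(q, k, df))
        qs.append(q)
        ps.append(p)
        sig.append(p < alpha)
    return TukeyResult(pairs=pairs, q=qs, p=ps, significant=sig, degenerate=degenerate)


@dataclass
class FeatureScreen:
    """Per-feature audit record of the screening."""

    feature: str
    f_stat: float
    anova_p: float
    tukey_p: dict[str, float]
    selected: bool
    degenerate: bool = False


@dataclass
class SelectionReport:
    """Screening outcome for one cascade step."""

    step: str
    classes: list[str]
    config: SelectionConfig
    screens: list[FeatureScreen] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        return [s.feature for s in self.screens if s.selected]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "step": self.step,
            "classes": self.classes,
            "config": asdict(self.config),
            "retained": self.retained,
            "features": [asdict(s) for s in self.screens],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for s in self.screens:
            rec = {
                "feature": s.feature,
                "F": s.f_stat,
                "anova_p": s.anova_p,
                "selected": s.selected,
                "degenerate": s.degenerate,
            }
            rec.update({f"tukey_p[{k}]": v for k, v in s.tukey_p.items()})
            recs.append(rec)
        return pd.DataFrame(recs)


def select_features(
    table: pd.DataFrame,
    target: str | pd.Series,
    feature_columns: Sequence[str],
    config: SelectionConfig | None = None,
    step: str = "",
) -> SelectionReport:
    """Screen feature columns of ``table`` against a class label.

    A feature is retained iff its pairwise Tukey comparisons are significant
    at ``config.alpha`` — all of them under ``all_pairs`` (default), at least
    one under ``any_pair``.  Every statistic is kept in the report for audit.
    """
    config = config or SelectionConfig()
    labels = table[target] if isinstance(target, str) else target
    classes = sorted(pd.unique(labels.astype(str)))
    if len(classes) < 2:
        raise ValueError(f"screening needs >= 2 classes, got {classes}")
    counts = labels.astype(str).value_counts()
    too_small = [c for c in classes if counts.get(c, 0) < 2]
    if too_small:
        raise ValueError(
            f"step {step or '?'}: classes with fewer than 2 replicas: {too_small}"
        )
    group_index = [np.asarray(labels.astype(str) == c) for c in classes]
    report = SelectionReport(step=step or "unnamed", classes=classes, config=config)
    for col in feature_columns:
        values = table[col].to_numpy(dtype=float)
        groups = [values[idx] for idx in group_index]
        f_stat, p = anova_f(groups)
        tk = tukey_hsd(groups, alpha=config.alpha)
        selected = tk.all_significant if config.rule == "all_pairs" else tk.any_significant
        tukey_p = {
            f"{classes[i]}|{classes[j]}": tk.p[m] for m, (i, j) in enumerate(tk.pairs)
        }
        report.screens.append(
            FeatureScreen(
                feature=col,
                f_stat=f_stat,
                anova_p=p,
                tukey_p=tukey_p,
                selected=bool(selected),
                degenerate=tk.degenerate,
            )
        )
    return report


def notch_interval(values: Sequence[float]) -> tuple[float, float]:
    """Notched-boxplot interval around the median:
    ``median +/- 1.57 * IQR / sqrt(n)``.

    Non-overlapping notches of two groups are informal strong evidence (about
    95 % confidence) that the medians differ.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one value")
    med = float(np.median(x))
    q1, q3 = np.percentile(x, [25, 75])
    half = 1.57 * float(q3 - q1) / math.sqrt(x.size)
    return med - half, med + half
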