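"""Method-comparison statistics for tape vs scan limb volumes.

The agreement battery mirrors standard device-validation practice:

* ordinary least squares of scan volume on tape volume (tape is the
  clinical reference method) with the coefficient of determination R^2;
* a Bland-Altman analysis — per-pair difference (scan - tape) against the
  per-pair mean, summarised by the bias and the 1.96 * SD limits of
  agreement (sample SD, ddof = 1);
* per-operator stratification of R^2 to quantify inter-operator
  variability;
* one-way ANOVA of percent-difference changes across the 2–3 / 4–6 / 7–12
  week follow-up bins, followed by pairwise Welch t-tests (unequal
  variances, Welch–Satterthwaite degrees of freedom) with Bonferroni
  correction at alpha = 0.05.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, InsufficientDataError, InvalidParameterError

__all__ = [
    "PairedMeasurements",
    "BlandAltman",
    "PairwiseTest",
    "AgreementReport",
    "linear_fit",
    "bland_altman",
    "oneway_anova",
    "welch_pairwise",
    "compute_agreement",
    "plot_regression",
    "plot_bland_altman",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Same-limb, same-visit volume pairs from the two modalities (mL)."""

    tape_ml: np.ndarray
    scan_ml: np.ndarray
    operators: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        tape = np.asarray(self.tape_ml, dtype=float)
        scan = np.asarray(self.scan_ml, dtype=float)
        if tape.ndim != 1 or tape.shape != scan.shape:
            raise InvalidParameterError("tape_ml and scan_ml must be equal-length 1-D")
        if not (np.all(tape > 0) and np.all(scan > 0)):
            raise InvalidParameterError("volumes must be positive")
        if self.operators is not None and len(self.operators) != tape.size:
            raise InvalidParameterError("one operator label per pair required")
        object.__setattr__(self, "tape_ml", tape)
        object.__setattr__(self, "scan_ml", scan)

    @property
    def n(self) -> int:
        return int(self.tape_ml.size)


@dataclass(frozen=True)
class BlandAltman:
    bias_ml: float
    loa_low_ml: float
    loa_high_ml: float
    means_ml: np.ndarray
    diffs_ml: np.ndarray


@dataclass(frozen=True)
class PairwiseTest:
    group_a: str
    group_b: str
    welch_t: float
    df: float
    p_raw: float
    p_bonferroni: float
    significant: bool


@dataclass(frozen=True)
class AgreementReport:
    slope: float
    intercept: float
    r_squared: float
    bias_ml: float
    loa_low_ml: float
    loa_high_ml: float
    n_pairs: int
    per_operator_r_squared: Mapping[str, float] = field(default_factory=dict)
    anova_f: float | None = None
    anova_df: tuple[int, int] | None = None
    anova_p: float | None = None
    pairwise: tuple[PairwiseTest, ...] = ()

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "bias_ml": self.bias_ml,
            "loa_low_ml": self.loa_low_ml,
            "loa_high_ml": self.loa_high_ml,
            "n_pairs": self.n_pairs,
            "per_operator_r_squared": dict(self.per_operator_r_squared),
            "anova_f": self.anova_f,
            "anova_df": list(self.anova_df) if self.anova_df else None,
            "anova_p": self.anova_p,
            "pairwise": [
                {
                    "group_a": t.group_a,
                    "group_b": t.group_b,
                    "welch_t": t.welch_t,
                    "df": t.df,
                    "p_raw": t.p_raw,
                    "p_bonferroni": t.p_bonferroni,
                    "significant": t.significant,
                }
                for t in self.pairwise
            ],
        }


def _as_pairs(pairs) -> PairedMeasurements:
    if isinstance(pairs, PairedMeasurements):
        return pairs
    arr = np.asarray(pairs, dtype=float)
    return PairedMeasurements(tape_ml=arr[:, 0], scan_ml=arr[:, 1])


def linear_fit(pairs) -> tuple[float, float, float]:
    """OLS of scan on tape: returns ``(slope, intercept, r_squared)``.

    Requires at least 3 pairs and non-zero variance in the tape values.
    """
    p = _as_pairs(pairs)
    if p.n < 3:
        raise InsufficientDataError(f"regression needs >= 3 pairs, got {p.n}")
    if np.var(p.tape_ml) <= 0:
        raise DegenerateFitError("tape volumes have zero variance")
    res = stats.linregress(p.tape_ml, p.scan_ml)
    r_squared = float(res.rvalue**2)
    if not math.isfinite(r_squared):
        # zero response variance: a flat fit explains nothing, R^2 = 0
        r_squared = 0.0
    return float(res.slope), float(res.intercept), r_squared


def bland_altman(pairs) -> BlandAltman:
    """Bias and 1.96 * SD limits of agreement of scan - tape differences."""
    p = _as_pairs(pairs)
    if p.n < 3:
        raise InsufficientDataError(f"Bland-Altman needs >= 3 pairs, got {p.n}")
    diffs = p.scan_ml - p.tape_ml
    means = 0.5 * (p.scan_ml + p.tape_ml)
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltman(
        bias_ml=bias,
        loa_low_ml=bias - 1.96 * sd,
        loa_high_ml=bias + 1.96 * sd,
        means_ml=means,
        diffs_ml=diffs,
    )


def _check_groups(groups: Sequence[Sequence[float]], min_size: int) -> list[np.ndarray]:
    if len(groups) < 2:
        raise InsufficientDataError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < min_size:
            raise InsufficientDataError(
                f"group {i} has {g.size} observations (< {min_size})"
            )
    return arrays


def oneway_anova(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: returns ``(F, df_between, df_within, p)``.

    The between/within sum-of-squares decomposition is computed directly;
    groups of identical constants give ``F = 0, p = 1`` rather than the
    0/0 indeterminate.
    """
    arrays = _check_groups(groups, min_size=2)
    all_obs = np.concatenate(arrays)
    grand = all_obs.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrays)
    df1 = len(arrays) - 1
    df2 = all_obs.size - len(arrays)
    if ss_between <= 1e-300:
        return 0.0, df1, df2, 1.0
    if ss_within <= 1e-300:
        return math.inf, df1, df2, 0.0
    f_stat = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f_stat, df1, df2))
    return float(f_stat), df1, df2, p


def _welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, Welch–Satterthwaite df, and two-sided p.

    Zero-variance conventions: both groups constant with equal means gives
    ``t = 0, p = 1``; with unequal means the statistic diverges and ``p = 0``.
    """
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 <= 1e-300:
        if math.isclose(a.mean(), b.mean(), rel_tol=0.0, abs_tol=1e-12):
            return 0.0, float(na + nb - 2), 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), float(na + nb - 2), 0.0
    t_stat = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return float(t_stat), float(df), p


def welch_pairwise(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> tuple[PairwiseTest, ...]:
    """All pairwise Welch t-tests with Bonferroni correction.

    ``m`` is the number of pairwise comparisons actually performed, and
    ``p_bonferroni = min(1, m * p_raw)``; significance is judged on the
    corrected p-value at ``alpha``.
    """
    arrays = _check_groups(groups, min_size=2)
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    if len(labels) != len(arrays):
        raise InvalidParameterError("one label per group required")
    pairs = list(itertools.combinations(range(len(arrays)), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        t_stat, df, p_raw = _welch_test(arrays[i], arrays[j])
        p_bonf = min(1.0, m * p_raw)
        out.append(
            PairwiseTest(
                group_a=str(labels[i]),
                group_b=str(labels[j]),
                welch_t=t_stat,
                df=df,
                p_raw=p_raw,
                p_bonferroni=p_bonf,
                significant=p_bonf < alpha,
            )
        )
    return tuple(out)


def compute_agreement(
    pairs,
    groups_by_bin: Mapping[str, Sequence[float]] | None = None,
    alpha: float = 0.05,
) -> AgreementReport:
    """Assemble the full agreement report.

    ``groups_by_bin`` optionally maps follow-up-bin labels (e.g. ``w2_3``)
    to percent-difference changes; when given and every bin has >= 2
    observations the ANOVA and pairwise Welch tests are included.
    """
    p = _as_pairs(pairs)
    slope, intercept, r2 = linear_fit(p)
    ba = bland_altman(p)

    per_op: dict[str, float] = {}
    if p.operators is not None:
        for op in sorted(set(p.operators)):
            mask = np.array([o == op for o in p.operators])
            if mask.sum() >= 3 and np.var(p.tape_ml[mask]) > 0:
                _, _, r2_op = linear_fit(
                    PairedMeasurements(p.tape_ml[mask], p.scan_ml[mask])
                )
                per_op[op] = r2_op

    anova_f = anova_p = None
    anova_df = None
    pairwise: tuple[PairwiseTest, ...] = ()
    if groups_by_bin:
        labels = list(groups_by_bin)
        groups = [groups_by_bin[k] for k in labels]
        f_stat, df1, df2, p_val = oneway_anova(groups)
        anova_f, anova_df, anova_p = f_stat, (df1, df2), p_val
        pairwise = welch_pairwise(groups, labels=labels, alpha=alpha)

    return AgreementReport(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        bias_ml=ba.bias_ml,
        loa_low_ml=ba.loa_low_ml,
        loa_high_ml=ba.loa_high_ml,
        n_pairs=p.n,
        per_operator_r_squared=per_op,
        anova_f=anova_f,
        anova_df=anova_df,
        anova_p=anova_p,
        pairwise=pairwise,
    )


def _agg_axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_regression(pairs, path: str) -> None:
    """Scatter of scan vs tape volumes with the OLS line and identity."""
    p = _as_pairs(pairs)
    slope, intercept, r2 = linear_fit(p)
    plt = _agg_axes()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(p.tape_ml, p.scan_ml, s=18, alpha=0.7)
    xs = np.linspace(p.tape_ml.min(), p.tape_ml.max(), 50)
    ax.plot(xs, slope * xs + intercept, "r-", label=f"fit (R$^2$={r2:.4f})")
    ax.plot(xs, xs, "k--", lw=0.8, label="identity")
    ax.set_xlabel("tape volume (mL)")
    ax.set_ylabel("scan volume (mL)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_bland_altman(pairs, path: str) -> None:
    """Bland-Altman scatter with bias and limits-of-agreement lines."""
    ba = bland_altman(pairs)
    plt = _agg_axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ba.means_ml, ba.diffs_ml, s=18, alpha=0.7)
    for y, style in ((ba.bias_ml, "r-"), (ba.loa_low_ml, "k--"), (ba.loa_high_ml, "k--")):
        ax.axhline(y, ls=style[1:], color=style[0], lw=1)
    ax.set_xlabel("mean of methods (mL)")
    ax.set_ylabel("scan - tape (mL)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
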