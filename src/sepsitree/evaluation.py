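"""Diagnostic evaluation statistics for binary risk classifiers.

Everything needed to characterize a low/high-risk tree classification
against an observed binary outcome:

* 2x2 confusion tables and the six standard indices (sensitivity,
  specificity, PPV, NPV, LR+, LR-), each with a 95% CI — proportions via
  the *continuity-corrected Wilson* score interval, likelihood ratios via
  the log-transform method;
* ROC curves and AUROC with a Hanley-McNeil 95% CI (the trapezoidal AUC
  equals the tie-corrected Mann-Whitney statistic divided by n1*n0);
* Yates continuity-corrected chi-square for 2x2 contingency tables;
* the Mann-Whitney U test (midrank ties; exact enumeration for pooled
  n <= 12, tie-corrected normal approximation otherwise);
* median / interquartile-range descriptives.

Zero denominators yield explicit *undefined* markers (``None`` fields),
never NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

Z95 = float(sps.norm.ppf(0.975))


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("confusion counts must be >= 0")
        if self.total == 0:
            raise EvaluationError("empty confusion table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ProportionCI:
    """A proportion with its 95% confidence bounds."""

    estimate: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 <= self.lower <= self.estimate <= self.upper <= 1):
            raise EvaluationError(
                f"require 0 <= lower <= estimate <= upper <= 1, got "
                f"({self.lower}, {self.estimate}, {self.upper})"
            )


@dataclass(frozen=True)
class RatioCI:
    """A likelihood ratio with 95% CI; ``None`` fields mean *undefined*
    (printed as an em dash)."""

    estimate: Optional[float]
    lower: Optional[float] = None
    upper: Optional[float] = None

    @property
    def defined(self) -> bool:
        return self.estimate is not None


@dataclass(frozen=True)
class TestCharacteristics:
    table: ConfusionTable
    sensitivity: Optional[ProportionCI]
    specificity: Optional[ProportionCI]
    ppv: Optional[ProportionCI]
    npv: Optional[ProportionCI]
    lr_positive: RatioCI
    lr_negative: RatioCI


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_lower: float
    ci_upper: float
    points: tuple[tuple[float, float], ...]  # (1 - specificity, sensitivity)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_value: float
    df: int = 1


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    tie_corrected_variance: float
    exact: bool


# ---------------------------------------------------------------------------


def confusion_from_predictions(
    predicted: Sequence[bool], actual: Sequence[bool]
) -> ConfusionTable:
    """Cross-tabulate binary predictions against binary outcomes."""
    if len(predicted) != len(actual):
        raise EvaluationError(
            f"length mismatch: {len(predicted)} predictions vs {len(actual)} outcomes"
        )
    if len(predicted) == 0:
        raise EvaluationError("empty prediction vector")
    p = np.asarray(predicted, dtype=bool)
    a = np.asarray(actual, dtype=bool)
    return ConfusionTable(
        tp=int(np.sum(p & a)),
        fp=int(np.sum(p & ~a)),
        fn=int(np.sum(~p & a)),
        tn=int(np.sum(~p & ~a)),
    )


def wilson_cc_interval(successes: int, n: int) -> ProportionCI:
    """95% continuity-corrected Wilson score interval for a proportion.

    This is the small-sample interval with good coverage at extreme
    proportions (the method used by the classic VassarStats calculators);
    e.g. 21/21 yields (0.808, 1.0).  Bounds are clipped to [0, 1].
    """
    if n <= 0:
        raise EvaluationError("n must be > 0")
    if not (0 <= successes <= n):
        raise EvaluationError("successes must lie in [0, n]")
    z = Z95
    p = successes / n
    if successes == 0:
        lower = 0.0
    else:
        lower = (
            2 * n * p + z * z - 1
            - z * math.sqrt(z * z - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))
        ) / (2 * (n + z * z))
    if successes == n:
        upper = 1.0
    else:
        upper = (
            2 * n * p + z * z + 1
            + z * math.sqrt(z * z + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))
        ) / (2 * (n + z * z))
    return ProportionCI(p, max(0.0, min(lower, p)), min(1.0, max(upper, p)))


def _prop(successes: int, n: int) -> Optional[ProportionCI]:
    return None if n == 0 else wilson_cc_interval(successes, n)


def _lr_ci(estimate: float, var_log: float) -> RatioCI:
    if estimate == 0 or not math.isfinite(var_log):
        return RatioCI(estimate)
    half = Z95 * math.sqrt(var_log)
    return RatioCI(estimate, estimate * math.exp(-half), estimate * math.exp(half))


def test_characteristics(table: ConfusionTable) -> TestCharacteristics:
    """Six standard test indices with 95% CIs from a 2x2 table.

    LR+ = sens / (1 - spec) and LR- = (1 - sens) / spec, with log-method
    CIs.  Any index with a zero denominator — including LR- when there are
    no false negatives (sensitivity exactly 1) — is reported as undefined.
    """
    t = table
    sens = _prop(t.tp, t.tp + t.fn)
    spec = _prop(t.tn, t.tn + t.fp)
    ppv = _prop(t.tp, t.tp + t.fp)
    npv = _prop(t.tn, t.tn + t.fn)

    lr_pos = RatioCI(None)
    if sens is not None and spec is not None and spec.estimate < 1:
        est = sens.estimate / (1 - spec.estimate)
        if t.tp > 0 and t.fp > 0:
            var = (
                1 / t.tp - 1 / (t.tp + t.fn) + 1 / t.fp - 1 / (t.fp + t.tn)
            )
            lr_pos = _lr_ci(est, var)
        else:
            lr_pos = RatioCI(est)

    lr_neg = RatioCI(None)
    if sens is not None and spec is not None and spec.estimate > 0 and t.fn > 0:
        est = (1 - sens.estimate) / spec.estimate
        if t.tn > 0:
            var = (
                1 / t.fn - 1 / (t.tp + t.fn) + 1 / t.tn - 1 / (t.fp + t.tn)
            )
            lr_neg = _lr_ci(est, var)
        else:
            lr_neg = RatioCI(est)

    return TestCharacteristics(
        table=t, sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        lr_positive=lr_pos, lr_negative=lr_neg,
    )


def lr_from_rates(sensitivity: float, specificity: float) -> tuple[Optional[float], Optional[float]]:
    """Point likelihood ratios from (possibly rounded) sensitivity and
    specificity; ``None`` where the denominator vanishes."""
    lr_pos = sensitivity / (1 - specificity) if specificity < 1 else None
    lr_neg = (1 - sensitivity) / specificity if specificity > 0 else None
    return lr_pos, lr_neg


# ---------------------------------------------------------------------------
# ROC / AUROC


def roc_points(risks: Sequence[float], outcomes: Sequence[bool]) -> np.ndarray:
    """ROC operating points at every unique threshold, from (0,0) to (1,1),
    ordered by increasing false-positive rate."""
    r = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise EvaluationError("both outcome classes must be present")
    order = np.argsort(-r, kind="mergesort")
    r_sorted, y_sorted = r[order], y[order]
    # cumulative counts at each distinct threshold
    distinct = np.r_[np.diff(r_sorted) != 0, True]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    return np.column_stack([fpr, tpr])


def hanley_mcneil_se(auc: float, n1: int, n0: int) -> float:
    """Hanley-McNeil standard error of an AUC estimated from n1 events and
    n0 non-events."""
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
    return math.sqrt(max(var, 0.0))


def roc_auc_with_ci(risks: Sequence[float], outcomes: Sequence[bool]) -> RocResult:
    """AUROC by the trapezoidal rule with a Hanley-McNeil 95% CI.

    The trapezoidal area over unique-threshold ROC points is exactly the
    tie-corrected two-sample rank statistic divided by n1*n0 (ties count
    one half).
    """
    pts = roc_points(risks, outcomes)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    y = np.asarray(outcomes, dtype=bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    a = auc
    half = Z95 * hanley_mcneil_se(a, n1, n0)
    return RocResult(
        auc=auc,
        ci_lower=max(0.0, a - half),
        ci_upper=min(1.0, a + half),
        points=tuple(map(tuple, pts)),
    )


# ---------------------------------------------------------------------------
# Contingency and rank tests


def chi_square_yates(a: int, b: int, c: int, d: int) -> ChiSquareResult:
    """Yates continuity-corrected chi-square for the 2x2 table [[a,b],[c,d]].

    Each cell contributes (max(0, |O - E| - 1/2))^2 / E; the correction is
    clamped so a deviation smaller than 1/2 contributes zero.  One degree
    of freedom.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if obs.min() < 0:
        raise EvaluationError("counts must be >= 0")
    n = obs.sum()
    if n <= 0:
        raise EvaluationError("empty table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if rows.min() == 0 or cols.min() == 0:
        raise EvaluationError("zero marginal in 2x2 table")
    expected = np.outer(rows, cols) / n
    stat = float(
        (np.maximum(0.0, np.abs(obs - expected) - 0.5) ** 2 / expected).sum()
    )
    return ChiSquareResult(statistic=stat, p_value=float(sps.chi2.sf(stat, 1)))


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    U counts, over all (x_i, y_j) pairs, the times x_i exceeds y_j (ties
    one half).  For pooled sample size <= 12 the p-value is computed by
    exact enumeration of all group assignments of the pooled values
    (tie-aware); otherwise by a normal approximation with tie-corrected
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise EvaluationError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    mu = nx * ny / 2.0

    if n <= 12:
        dev = abs(u - mu)
        hits = 0
        total = 0
        idx = range(n)
        for comb in combinations(idx, nx):
            ru = float(ranks[list(comb)].sum() - nx * (nx + 1) / 2)
            total += 1
            if abs(ru - mu) >= dev - 1e-12:
                hits += 1
        p = hits / total
        return MannWhitneyResult(u=u, p_value=p, tie_corrected_variance=var, exact=True)

    if var <= 0:  # all pooled values identical
        return MannWhitneyResult(u=u, p_value=1.0, tie_corrected_variance=var, exact=False)
    z = (u - mu) / math.sqrt(var)
    p = float(2 * sps.norm.sf(abs(z)))
    return MannWhitneyResult(
        u=u, p_value=min(1.0, p), tie_corrected_variance=var, exact=False
    )


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation: (median, q1, q3)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise EvaluationError("empty sample")
    med, q1, q3 = np.percentile(v, [50, 25, 75], method="linear")
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# Report formatting


def format_p(p: float) -> str:
    """Report-layer p-value formatting: '<0.001' below a thousandth,
    otherwise three significant figures."""
    if p < 0.001:
        return "<0.001"
    return f"{p:.3g}"


def _fmt_prop(ci: Optional[ProportionCI]) -> str:
    if ci is None:
        return "—"
    return f"{100 * ci.estimate:.0f}% ({100 * ci.lower:.0f}–{100 * ci.upper:.0f})"


def _fmt_ratio(ci: RatioCI) -> str:
    if not ci.defined:
        return "—"
    if ci.lower is None:
        return f"{ci.estimate:.1f}"
    return f"{ci.estimate:.1f} ({ci.lower:.1f}–{ci.upper:.1f})"


def characteristics_row(label: str, tc: TestCharacteristics) -> dict[str, str]:
    return {
        "model": label,
        "sensitivity": _fmt_prop(tc.sensitivity),
        "specificity": _fmt_prop(tc.specificity),
        "ppv": _fmt_prop(tc.ppv),
        "npv": _fmt_prop(tc.npv),
        "lr_positive": _fmt_ratio(tc.lr_positive),
        "lr_negative": _fmt_ratio(tc.lr_negative),
    }


def format_characteristics_table(rows: list[dict[str, str]]) -> str:
    """Plain-text table of test characteristics (one row per model)."""
    cols = ["model", "sensitivity", "specificity", "ppv", "npv",
            "lr_positive", "lr_negative"]
    headers = {"model": "Model", "sensitivity": "Sensitivity",
               "specificity": "Specificity", "ppv": "PPV", "npv": "NPV",
               "lr_positive": "Positive LR", "lr_negative": "Negative LR"}
    widths = {
        c: max(len(headers[c]), *(len(r[c]) for r in rows)) if rows else len(headers[c])
        for c in cols
    }
    lines = ["  ".join(headers[c].ljust(widths[c]) for c in cols)]
    lines.append("  ".join("-" * widths[c] for c in cols))
    for r in rows:
        lines.append("  ".join(r[c].ljust(widths[c]) for c in cols))
    return "\n".join(lines)


def characteristics_to_dict(tc: TestCharacteristics) -> dict:
    """JSON-serializable view of a TestCharacteristics."""

    def prop(ci: Optional[ProportionCI]):
        return None if ci is None else {
            "estimate": ci.estimate, "lower": ci.lower, "upper": ci.upper
        }

    def ratio(ci: RatioCI):
        return None if not ci.defined else {
            "estimate": ci.estimate, "lower": ci.lower, "upper": ci.upper
        }

    t = tc.table
    return {
        "confusion": {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn},
        "sensitivity": prop(tc.sensitivity),
        "specificity": prop(tc.specificity),
        "ppv": prop(tc.ppv),
        "npv": prop(tc.npv),
        "lr_positive": ratio(tc.lr_positive),
        "lr_negative": ratio(tc.lr_negative),
    }
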