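"""Diagnostic statistics: ROC analysis of muscle density as a NASH marker,
cutoff selection, exact binomial confidence intervals, likelihood ratios,
density stratification and multivariable logistic adjustment.

The diagnostic question is oriented *lower-is-positive*: myosteatosis
lowers muscle attenuation, so a muscle-to-spleen density ratio *below* the
cutoff predicts NASH. Scores are negated internally so the ROC machinery
always works in higher-is-positive space; cutoffs are reported back in the
original density units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RocResult",
    "CutoffReport",
    "LogisticFit",
    "SeparationError",
    "pearson",
    "roc_curve",
    "select_cutoff",
    "exact_binomial_ci",
    "stratify_density",
    "logistic_fit",
    "bootstrap_auroc_ci",
    "plot_roc",
    "DENSITY_BINS",
]

#: Muscle-density strata: low, mild and high density.
DENSITY_BINS = ((0.4, 0.6), (0.6, 0.8), (0.8, 1.0))


class SeparationError(RuntimeError):
    """Logistic regression did not converge / data are separable."""


@dataclass
class RocResult:
    """ROC points and area for a lower-is-positive (or higher) marker."""

    fpr: np.ndarray  # monotone non-decreasing, (0,0) .. (1,1)
    tpr: np.ndarray
    auroc: float
    direction: str  # "lower" | "higher" — which scores indicate positives
    n_pos: int
    n_neg: int
    # internal: thresholds in *oriented* score space (higher = positive),
    # aligned with the fpr/tpr points after the initial (0, 0)
    _scores: np.ndarray = field(repr=False, default=None)
    _labels: np.ndarray = field(repr=False, default=None)


@dataclass
class CutoffReport:
    """A diagnostic cutoff with its 2×2 performance and exact CIs."""

    cutoff: float  # in original score units
    direction: str
    sensitivity: float
    specificity: float
    ci_sens: tuple[float, float]
    ci_spec: tuple[float, float]
    lr_positive: float  # +inf when specificity == 1
    tp: int
    fp: int
    tn: int
    fn: int

    def summary(self) -> str:
        op = "<" if self.direction == "lower" else ">"
        lr = "inf" if np.isinf(self.lr_positive) else f"{self.lr_positive:.1f}"
        return (
            f"cutoff {op}{self.cutoff:.4g}: sensitivity {100 * self.sensitivity:.2f}% "
            f"(95% CI {100 * self.ci_sens[0]:.2f}-{100 * self.ci_sens[1]:.2f}%), "
            f"specificity {100 * self.specificity:.2f}% "
            f"(95% CI {100 * self.ci_spec[0]:.2f}-{100 * self.ci_spec[1]:.2f}%), "
            f"LR+ {lr} "
            f"[TP {self.tp} FP {self.fp} TN {self.tn} FN {self.fn}]"
        )


@dataclass
class LogisticFit:
    """Binary logistic regression fit (Wald inference)."""

    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    converged: bool
    n: int
    dropped: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"logistic fit, n = {self.n}"]
        for name in self.params:
            lines.append(
                f"  {name:>24s}  beta = {self.params[name]:+.4f}  "
                f"SE = {self.bse[name]:.4f}  p = {self.pvalues[name]:.4g}"
            )
        if self.dropped:
            lines.append(f"  dropped (constant): {self.dropped}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------


def pearson(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def _oriented(scores, labels, direction):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1D and of equal length")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")
    oriented = -scores if direction == "lower" else scores
    return oriented, labels


def roc_curve(scores, labels, direction: str = "lower") -> RocResult:
    """ROC curve and AUROC for a continuous marker against a binary label.

    ``direction="lower"`` (the myosteatosis convention) means lower scores
    indicate the positive class; scores are negated internally. Thresholds
    sweep the unique observed values; tied scores advance TPR and FPR
    simultaneously, so the area (trapezoidal) equals the Mann–Whitney
    statistic with ½ credit for ties.
    """
    oriented, lab = _oriented(scores, labels, direction)
    order = np.argsort(-oriented, kind="mergesort")
    s_sorted = oriented[order]
    l_sorted = lab[order]
    n_pos = int(lab.sum())
    n_neg = lab.size - n_pos
    # collapse ties: one ROC point per unique threshold
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp_cum = np.cumsum(l_sorted)[distinct]
    fp_cum = np.cumsum(~l_sorted)[distinct]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    auroc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        auroc=auroc,
        direction=direction,
        n_pos=n_pos,
        n_neg=n_neg,
        _scores=s_sorted[distinct],
        _labels=lab,
    )


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson exact binomial interval by beta-quantile inversion."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError("require 0 <= k <= n and n >= 1")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return (lo, hi)


def select_cutoff(roc: RocResult, scores, labels, rule: str = "youden") -> CutoffReport:
    """Select the optimal cutoff on a ROC curve (Youden's J).

    The chosen threshold maximizes sensitivity + specificity − 1; ties go
    to the higher sensitivity. The reported cutoff is the midpoint between
    the adjacent observed scores straddling the optimum, in original score
    units, so that the decision rule reads "density below the cutoff ⇒
    NASH" when ``direction="lower"``. Exact 95 % Clopper–Pearson intervals
    and the positive likelihood ratio are attached.
    """
    if rule != "youden":
        raise ValueError("only the Youden rule is implemented")
    oriented, lab = _oriented(scores, labels, roc.direction)
    uniq = np.unique(oriented)  # ascending in oriented space
    best = None
    for i, t in enumerate(uniq):
        pred = oriented >= t
        tp = int((pred & lab).sum())
        fp = int((pred & ~lab).sum())
        fn = int((~pred & lab).sum())
        tn = int((~pred & ~lab).sum())
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        key = (j, sens)
        if best is None or key > best[0]:
            # midpoint with the next-lower oriented value (scores just below
            # t classify negative); at the extreme reuse the extreme value
            lower_neighbor = uniq[i - 1] if i > 0 else t
            thr = (t + lower_neighbor) / 2.0
            best = (key, thr, tp, fp, tn, fn, sens, spec)
    _, thr, tp, fp, tn, fn, sens, spec = best
    cutoff = -thr if roc.direction == "lower" else thr
    lr = sens / (1.0 - spec) if spec < 1.0 else float("inf")
    return CutoffReport(
        cutoff=float(cutoff),
        direction=roc.direction,
        sensitivity=sens,
        specificity=spec,
        ci_sens=exact_binomial_ci(tp, tp + fn),
        ci_spec=exact_binomial_ci(tn, tn + fp),
        lr_positive=lr,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def stratify_density(
    densities, nash_flags, bins: tuple = DENSITY_BINS
) -> pd.DataFrame:
    """Per-stratum NASH counts and proportions over density bins.

    Bins are half-open ``[lo, hi)`` except the last, which is closed.
    Densities falling in no bin are collected in an ``out_of_range``
    bucket. Empty bins report the percentage as missing (NaN), not zero.
    """
    densities = np.asarray(densities, dtype=float)
    nash = np.asarray(nash_flags).astype(bool)
    if densities.shape != nash.shape:
        raise ValueError("densities and flags must align")
    rows = []
    assigned = np.zeros(densities.shape, dtype=bool)
    for i, (lo, hi) in enumerate(bins):
        last = i == len(bins) - 1
        sel = (densities >= lo) & ((densities <= hi) if last else (densities < hi))
        sel &= ~assigned
        assigned |= sel
        n = int(sel.sum())
        k = int(nash[sel].sum())
        rows.append(
            {
                "bin": f"[{lo:g}, {hi:g}{']' if last else ')'}",
                "n": n,
                "nash": k,
                "pct_nash": 100.0 * k / n if n else float("nan"),
                "pct_no_nash": 100.0 * (n - k) / n if n else float("nan"),
            }
        )
    n_out = int((~assigned).sum())
    if n_out:
        k = int(nash[~assigned].sum())
        rows.append(
            {
                "bin": "out_of_range",
                "n": n_out,
                "nash": k,
                "pct_nash": 100.0 * k / n_out,
                "pct_no_nash": 100.0 * (n_out - k) / n_out,
            }
        )
    return pd.DataFrame(rows)


def logistic_fit(outcome, predictors: pd.DataFrame, maxiter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """Binary logistic regression (maximum likelihood, Newton/IRLS).

    Wald standard errors and p-values per coefficient. Constant predictors
    are dropped with a note; fewer than 10 events per predictor triggers a
    warning; non-convergence or (quasi-)separation raises
    :class:`SeparationError` rather than returning runaway coefficients.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    y = np.asarray(outcome).astype(float)
    X = pd.DataFrame(predictors).astype(float).copy()
    dropped = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    X = X.drop(columns=dropped)
    n = len(y)
    n_events = int(min(y.sum(), n - y.sum()))
    if len(X.columns) and n_events < 10 * len(X.columns):
        warnings.warn(
            f"only {n_events} events for {len(X.columns)} predictors; "
            "coefficients may be unstable",
            stacklevel=2,
        )
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=maxiter, tol=tol, warn_convergence=False)
    except (
        PerfectSeparationError,
        PerfectSeparationWarning,
        np.linalg.LinAlgError,
        RuntimeWarning,
    ) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge (possible separation)")
    slope_params = res.params.drop("const", errors="ignore").to_numpy()
    if slope_params.size and np.abs(slope_params).max() > 50:
        raise SeparationError("runaway coefficients indicate quasi-separation")
    return LogisticFit(
        params=dict(res.params),
        bse=dict(res.bse),
        pvalues=dict(res.pvalues),
        converged=True,
        n=n,
        dropped=dropped,
    )


def bootstrap_auroc_ci(
    scores, labels, direction: str = "lower", n_boot: int = 2000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile-bootstrap CI for the AUROC.

    Offered as a convenience only — no reference method is implied; a
    stratified resample keeps both classes present in every replicate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.r_[rng.choice(pos, pos.size), rng.choice(neg, neg.size)]
        aucs[b] = roc_curve(scores[idx], labels[idx], direction).auroc
    alpha = 1.0 - level
    return (
        float(np.quantile(aucs, alpha / 2.0)),
        float(np.quantile(aucs, 1.0 - alpha / 2.0)),
    )


def plot_roc(roc: RocResult, ax=None, **kwargs):
    """Plot a ROC curve onto *ax* (created when omitted)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc.fpr, roc.tpr, drawstyle="steps-post", **kwargs)
    ax.plot([0, 1], [0, 1], ls=":", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUROC = {roc.auroc:.3f} (n+ = {roc.n_pos}, n- = {roc.n_neg})")
    return ax
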