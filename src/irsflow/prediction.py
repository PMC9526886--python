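"""Statistical layer: normality, Gaussian-centile thresholds, classifier
metrics, ROC/AUC with a Youden-optimal cutoff, and correlations with grade.

The decision rule the indices feed is deliberately simple: under an
approximately Gaussian index distribution, 68% of patients fall within one
SD of the mean and 95% within two, so mean + k·SD (k ∈ {1, 2}) serves as a
one-sided threshold for flagging prospective overreactors (RTOG grade ≥ 2).
ROC analysis over all observed cutoffs then locates the operating point that
maximises Youden's J = sensitivity + specificity − 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.metrics import roc_curve

HIGH = "high_is_sensitive"
LOW = "low_is_sensitive"


@dataclass
class CorrelationResult:
    index_name: str
    r: float
    p_value: float
    n_used: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation {self.r} outside [-1, 1]")
        if self.n_used < 3:
            raise ValueError("correlation requires n >= 3")


@dataclass
class ThresholdRule:
    index_name: str
    direction: str  # HIGH or LOW
    k: int          # centile multiplier: 1 (~68th) or 2 (~95th)
    cutoff: float

    def __post_init__(self) -> None:
        if self.direction not in (HIGH, LOW):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.k not in (1, 2):
            raise ValueError("k must be 1 or 2")
        if not math.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    def predict(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return values >= self.cutoff if self.direction == HIGH else values <= self.cutoff


@dataclass
class ClassifierReport:
    """Confusion counts and derived metrics for one threshold rule.

    Percent metrics are None when their denominator is zero (e.g. PPV with
    no predicted positives) — undefined is reported as undefined, never 0.
    """

    rule: ThresholdRule
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None = field(init=False)
    specificity: float | None = field(init=False)
    accuracy: float | None = field(init=False)
    ppv: float | None = field(init=False)
    npv: float | None = field(init=False)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("negative confusion count")
        self.sensitivity = _pct(self.tp, self.tp + self.fn)
        self.specificity = _pct(self.tn, self.tn + self.fp)
        self.accuracy = _pct(self.tp + self.tn, self.n)
        self.ppv = _pct(self.tp, self.tp + self.fp)
        self.npv = _pct(self.tn, self.tn + self.fn)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int, rule: ThresholdRule | None = None) -> "ClassifierReport":
        rule = rule or ThresholdRule("counts", HIGH, 1, 0.0)
        return cls(rule=rule, tp=tp, fp=fp, tn=tn, fn=fn)

    def as_dict(self) -> dict:
        return {
            "index": self.rule.index_name,
            "direction": self.rule.direction,
            "k": self.rule.k,
            "cutoff": self.rule.cutoff,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "accuracy_pct": self.accuracy,
            "ppv_pct": self.ppv,
            "npv_pct": self.npv,
            "n_dropped": self.n_dropped,
        }


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


@dataclass
class ROCResult:
    points: np.ndarray       # rows of (1 - specificity, sensitivity)
    auc: float
    optimal_cutoff: float    # maximiser of Youden's J
    optimal_method: str = "youden"
    thresholds: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC {self.auc} outside [0, 1]")


def pearson(x, y, index_name: str = "") -> CorrelationResult:
    """Product-moment correlation with a two-sided t-test p-value.

    NaN pairs are dropped pairwise; zero variance in either vector is an
    error (r is undefined, not 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 finite pairs, have {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(index_name=index_name, r=float(r), p_value=float(p), n_used=int(x.size))


def ks_normality(values, n_bins: int | None = None) -> tuple[float, float, float]:
    """Gaussian goodness of fit: KS statistic, p-value, and histogram-fit R².

    The KS test compares the sample against a normal with the sample mean
    and SD. The p-value uses the standard asymptotic distribution; because
    the parameters are estimated from the same data it is conservative
    (a Lilliefors correction is not applied). The third return value is the
    R² of a Gaussian density fitted by least squares to a density-normalised
    histogram, the figure-of-merit style summary often quoted alongside.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 5:
        raise ValueError("need >= 5 values for a normality assessment")
    mu, sd = float(values.mean()), float(values.std(ddof=1))
    if sd == 0:
        raise ValueError("constant values: normality test undefined")
    d_stat, p_value = stats.kstest(values, "norm", args=(mu, sd))

    if n_bins is None:
        n_bins = max(8, int(math.ceil(math.log2(values.size) + 1)))  # Sturges floor 8
    density, edges = np.histogram(values, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, amp, loc, scale):
        return amp * np.exp(-0.5 * ((x - loc) / scale) ** 2)

    p0 = (1.0 / (sd * math.sqrt(2 * math.pi)), mu, sd)
    try:
        popt, _ = optimize.curve_fit(gauss, centers, density, p0=p0, maxfev=5000)
        fitted = gauss(centers, *popt)
    except RuntimeError:
        fitted = gauss(centers, *p0)
    ss_res = float(np.sum((density - fitted) ** 2))
    ss_tot = float(np.sum((density - density.mean()) ** 2))
    fit_r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(d_stat), float(p_value), fit_r2


def gaussian_threshold(values, k: int, direction: str = HIGH, index_name: str = "") -> ThresholdRule:
    """Centile threshold mean ± k·SD (sample SD, n−1 denominator).

    k=1 bounds the central ~68% of a Gaussian population, k=2 the central
    ~95%; the bound in the sensitive direction becomes the cutoff.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 3:
        raise ValueError("need >= 3 values to place a threshold")
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise ValueError("zero SD: threshold undefined")
    mu = float(values.mean())
    cutoff = mu + k * sd if direction == HIGH else mu - k * sd
    return ThresholdRule(index_name=index_name, direction=direction, k=k, cutoff=cutoff)


def classify_and_score(
    values, grades, rule: ThresholdRule, positive_grade: int = 2
) -> ClassifierReport:
    """Score a threshold rule against the clinical truth (grade ≥ 2 positive).

    Pairs with NaN index values are dropped pairwise and counted in
    ``n_dropped``.
    """
    values = np.asarray(values, dtype=float)
    grades = np.asarray(grades)
    if values.shape != grades.shape:
        raise ValueError("values and grades must align")
    keep = np.isfinite(values)
    n_dropped = int((~keep).sum())
    values, grades = values[keep], grades[keep]
    truth = grades >= positive_grade
    if truth.all() or not truth.any():
        raise ValueError("single-class truth vector: classifier metrics undefined")
    pred = rule.predict(values)
    report = ClassifierReport(
        rule=rule,
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )
    report.n_dropped = n_dropped
    return report


def roc_analysis(scores, labels, direction: str = HIGH) -> ROCResult:
    """ROC curve over all distinct score cutoffs, trapezoidal/Mann–Whitney
    AUC, and the Youden-J-optimal cutoff.

    Ties contribute half a concordance each, so the reported AUC equals the
    Mann–Whitney U statistic. Youden ties break toward higher specificity
    (then toward the more extreme cutoff).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    keep = np.isfinite(scores)
    scores, labels = scores[keep], labels[keep]
    if labels.all() or not labels.any():
        raise ValueError("single-class labels: ROC undefined")
    oriented = scores if direction == HIGH else -scores
    fpr, tpr, thresholds = roc_curve(labels, oriented, drop_intermediate=False)
    # trapezoid over the full curve; with thresholds at every distinct score
    # this equals the rank-average Mann-Whitney statistic
    auc = float(np.trapezoid(tpr, fpr))

    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    best = best[np.argmin(fpr[best])]  # among max-J points, highest specificity
    opt = float(thresholds[best])
    if not math.isfinite(opt):  # sklearn's sentinel threshold above all scores
        opt = float(oriented.max()) + 1.0
    if direction == LOW:
        opt = -opt
    points = np.column_stack([fpr, tpr])
    return ROCResult(points=points, auc=auc, optimal_cutoff=opt, thresholds=thresholds)


def bootstrap_auc_ci(
    scores, labels, direction: str = HIGH, n_boot: int = 2000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC (patients resampled with
    replacement; resamples with a single class are redrawn)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    keep = np.isfinite(scores)
    scores, labels = scores[keep], labels[keep]
    oriented = scores if direction == HIGH else -scores
    rng = np.random.default_rng(seed)
    n = scores.size
    # vectorised rank-based (Mann-Whitney) AUC over all resamples at once
    idx = rng.integers(0, n, size=(n_boot, n))
    lab = labels[idx]
    n_pos = lab.sum(axis=1)
    bad = (n_pos == 0) | (n_pos == n)
    while bad.any():  # single-class resamples are redrawn
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
        lab = labels[idx]
        n_pos = lab.sum(axis=1)
        bad = (n_pos == 0) | (n_pos == n)
    ranks = stats.rankdata(oriented[idx], axis=1)
    n_neg = n - n_pos
    aucs = ((ranks * lab).sum(axis=1) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(aucs, alpha)), float(np.quantile(aucs, 1.0 - alpha))


def anova_across_doses(groups: dict[float, np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA of per-patient 30-min GM grouped by dose."""
    if len(groups) < 2:
        raise ValueError("need >= 2 dose groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each dose group needs >= 2 observations")
    f_stat, p = stats.f_oneway(*arrays)
    return float(f_stat), float(p)
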