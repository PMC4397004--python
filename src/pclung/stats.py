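"""Normality screening and optimal univariate discrimination.

Texture measures are screened with a Kolmogorov-Smirnov statistic against
a normal distribution whose mean and SD are estimated from the sample,

    K-stat = max |F(x) - G(x)|,

evaluated at both one-sided steps of the empirical CDF F.  Normality is
rejected when K-stat exceeds a critical value of the form c / sqrt(n);
the default convention uses c = 0.94, with the asymptotic two-sided KS
value (c = 1.358, alpha = 0.05) and the Lilliefors approximation
(c = 0.886, alpha = 0.05, appropriate when parameters are estimated)
available as alternatives.

Measures that pass are discriminated with the optimal two-class rule
based on the log density ratio Q(x) = ln(f1(x) / f2(x)) of two univariate
normal classes.  With equal variances this is the linear discriminant
function (LDF) using the pooled variance

    S = ((n1 - 1) S1 + (n2 - 1) S2) / (n1 - 1 + n2 - 1),

otherwise the quadratic discriminant function (QDF); the form is chosen
by a two-sided F-test of variance equality at alpha = 0.05.  A case is
assigned to class 1 when Q(x) >= ln C, where C combines the
misclassification-cost ratio and the prior-probability ratio.  The
resulting error probabilities are delta = P(class 2 | class 1) (Type I)
and beta = P(class 1 | class 2) (Type II).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: critical-value coefficients c in K_crit = c / sqrt(n)
KS_CONVENTIONS = {"c94": 0.94, "asymptotic": 1.358, "lilliefors": 0.886}


@dataclass(frozen=True)
class NormalityResult:
    k_stat: float
    critical_value: float
    accept: bool
    n: int
    convention: str

    def __post_init__(self):
        if not 0 <= self.k_stat <= 1:
            raise ValueError("K-stat must lie in [0, 1]")


def ks_normality(
    sample: np.ndarray,
    *,
    convention: str = "c94",
    mean: float | None = None,
    sd: float | None = None,
) -> NormalityResult:
    """KS test of a sample against a (sample-estimated) normal CDF.

    ``mean``/``sd`` may be fixed externally; by default they are estimated
    from the sample (mean and SD with one delta degree of freedom).
    """
    if convention not in KS_CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least five observations")
    if mean is None:
        mean = float(x.mean())
    if sd is None:
        sd = float(x.std(ddof=1))
    if not sd > 0:
        raise ValueError("sample is constant; normal CDF undefined")
    k = float(sps.kstest(x, sps.norm(mean, sd).cdf).statistic)
    crit = KS_CONVENTIONS[convention] / np.sqrt(n)
    return NormalityResult(
        k_stat=k, critical_value=float(crit), accept=k <= crit, n=n, convention=convention
    )


def variance_equality(
    s1: float, s2: float, n1: int, n2: int, *, alpha: float = 0.05
) -> str:
    """Two-sided F-test of H0: sigma1^2 = sigma2^2; 'equal' or 'unequal'."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per class")
    if not (s1 > 0 and s2 > 0):
        raise ValueError("variances must be positive")
    f = s1 / s2
    lo = sps.f.ppf(alpha / 2, n1 - 1, n2 - 1)
    hi = sps.f.ppf(1 - alpha / 2, n1 - 1, n2 - 1)
    return "unequal" if (f < lo or f > hi) else "equal"


@dataclass(frozen=True)
class DiscriminantModel:
    """Fitted univariate LDF or QDF for class 1 vs class 2."""

    mean1: float
    mean2: float
    var1: float
    var2: float
    n1: int
    n2: int
    form: str  # 'ldf' | 'qdf'

    def __post_init__(self):
        if not (self.var1 > 0 and self.var2 > 0):
            raise ValueError("class variances must be positive")
        if self.form not in ("ldf", "qdf"):
            raise ValueError("form must be 'ldf' or 'qdf'")

    @property
    def pooled_var(self) -> float:
        """Pooled variance with (n - 1) weights."""
        w1, w2 = self.n1 - 1, self.n2 - 1
        return (w1 * self.var1 + w2 * self.var2) / (w1 + w2)

    @property
    def qdf_constant(self) -> float:
        """k_q = ln(S1/S2)/2 + (m1^2/S1 - m2^2/S2)/2."""
        return 0.5 * np.log(self.var1 / self.var2) + 0.5 * (
            self.mean1**2 / self.var1 - self.mean2**2 / self.var2
        )

    def to_dict(self) -> dict:
        return {
            "mean1": self.mean1,
            "mean2": self.mean2,
            "var1": self.var1,
            "var2": self.var2,
            "n1": self.n1,
            "n2": self.n2,
            "form": self.form,
        }


def fit_discriminant(
    x1: np.ndarray, x2: np.ndarray, *, form: str | None = None
) -> DiscriminantModel:
    """Fit the optimal discriminant for class 1 (x1) vs class 2 (x2).

    The LDF/QDF form follows the variance-equality F-test unless forced
    via ``form``.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("need at least two observations per class")
    v1 = float(x1.var(ddof=1))
    v2 = float(x2.var(ddof=1))
    if not (v1 > 0 and v2 > 0):
        raise ValueError("degenerate (constant) class sample")
    if form is None:
        form = "ldf" if variance_equality(v1, v2, x1.size, x2.size) == "equal" else "qdf"
    return DiscriminantModel(
        mean1=float(x1.mean()),
        mean2=float(x2.mean()),
        var1=v1,
        var2=v2,
        n1=int(x1.size),
        n2=int(x2.size),
        form=form,
    )


def score(model: DiscriminantModel, x0):
    """Discriminant score Q(x0), the log density ratio of class 1 to 2.

    LDF: (m1 - m2)/S * x0 - (m1 - m2)(m1 + m2)/(2S) with pooled S.
    QDF: -x0^2 (1/S1 - 1/S2)/2 + (m1/S1 - m2/S2) x0 - k_q.
    """
    x0 = np.asarray(x0, dtype=float)
    if model.form == "ldf":
        s = model.pooled_var
        diff = model.mean1 - model.mean2
        q = diff / s * x0 - 0.5 * diff * (model.mean1 + model.mean2) / s
    else:
        q = (
            -0.5 * x0**2 * (1.0 / model.var1 - 1.0 / model.var2)
            + (model.mean1 / model.var1 - model.mean2 / model.var2) * x0
            - model.qdf_constant
        )
    if q.ndim == 0:
        return float(q)
    return q


def classify(model: DiscriminantModel, x0, cost_ratio: float = 1.0):
    """Assign class 1 where Q(x0) >= ln(C), else class 2."""
    if not cost_ratio > 0:
        raise ValueError("cost-prior ratio C must be positive")
    q = score(model, x0)
    labels = np.where(np.asarray(q) >= np.log(cost_ratio), 1, 2)
    if labels.ndim == 0:
        return int(labels)
    return labels


@dataclass(frozen=True)
class ErrorRates:
    """Empirical Type I (delta) and Type II (beta) error probabilities."""

    delta: float
    beta: float
    cost_ratio: float

    def __post_init__(self):
        if not (0 <= self.delta <= 1 and 0 <= self.beta <= 1):
            raise ValueError("error rates must lie in [0, 1]")


def error_rates(
    model: DiscriminantModel, x1, x2, cost_ratio: float = 1.0
) -> ErrorRates:
    """delta = P(classified 2 | class 1), beta = P(classified 1 | class 2)."""
    x1 = np.atleast_1d(np.asarray(x1, dtype=float))
    x2 = np.atleast_1d(np.asarray(x2, dtype=float))
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both classes must be present in the test set")
    delta = float(np.mean(classify(model, x1, cost_ratio) == 2))
    beta = float(np.mean(classify(model, x2, cost_ratio) == 1))
    return ErrorRates(delta=delta, beta=beta, cost_ratio=cost_ratio)
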