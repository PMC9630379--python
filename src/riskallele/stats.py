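"""Statistical procedures: one-tailed t-tests and Deming regression.

Two questions drive the analysis of a risk-allele catalog:

* Is the mean (weighted) risk-allele frequency higher in one population
  than the other?  Answered by a one-tailed t-test, since each disease
  hypothesis has a single direction of interest.  Paired, pooled-variance
  Student, and Welch variants are available; the per-SNP pairing of the two
  populations makes the paired variant the statistically natural default.

* Does the scatter of per-SNP frequencies (population A vs population B)
  deviate from the identity line that equal frequencies would produce?
  Answered by Deming errors-in-variables regression, which treats both axes
  as noisy, followed by a t-test of the fitted slope against 1.  The slope
  standard error is a delete-one jackknife; the reference distribution is
  t with n - 2 degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .aggregate import AggregatedSnp


class InferenceError(ValueError):
    pass


class DegenerateDataError(InferenceError):
    pass


VARIANTS = ("paired", "student", "welch")
DIRECTIONS = ("greater", "less")


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_one_tailed: float
    direction: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    variant: str


@dataclass(frozen=True)
class DemingFit:
    """A Deming regression line for frequencies of population y on x.

    ``lam`` is the assumed ratio of x-axis to y-axis error variance:
    lam = 1 gives orthogonal regression, lam -> 0 recovers ordinary least
    squares of y on x (error-free x).  ``slope_se`` and the two p-values
    are filled by :func:`deming_regression`.
    """

    slope: float
    intercept: float
    n: int
    lam: float
    slope_se: float | None = None
    p_slope_vs_one: float | None = None
    p_slope_vs_zero: float | None = None


def one_tailed_t_test(a, b, direction: str = "greater", variant: str = "paired") -> TTestResult:
    """One-tailed two-sample t-test.

    ``direction="greater"`` tests H1: mean(a) > mean(b); the p-value is the
    upper-tail probability of the t statistic (mirrored for ``"less"``).
    """
    if direction not in DIRECTIONS:
        raise InferenceError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    if variant not in VARIANTS:
        raise InferenceError(f"variant must be one of {VARIANTS}, got {variant!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InferenceError("need at least two observations per sample")

    if variant == "paired":
        if a.size != b.size:
            raise InferenceError("paired t-test requires equal-length samples")
        d = a - b
        sd = d.std(ddof=1)
        if sd == 0.0:
            raise DegenerateDataError("paired differences have zero variance")
        t = d.mean() / (sd / math.sqrt(d.size))
        df = float(d.size - 1)
    else:
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va == 0.0 and vb == 0.0:
            raise DegenerateDataError("both samples have zero variance")
        na, nb = a.size, b.size
        if variant == "student":
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
            df = float(na + nb - 2)
        else:  # welch
            se2 = va / na + vb / nb
            t = (a.mean() - b.mean()) / math.sqrt(se2)
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))

    p = sps.t.sf(t, df) if direction == "greater" else sps.t.cdf(t, df)
    return TTestResult(
        statistic=float(t),
        df=df,
        p_one_tailed=float(p),
        direction=direction,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=int(a.size),
        n_b=int(b.size),
        variant=variant,
    )


def _deming_slope(x: np.ndarray, y: np.ndarray, lam: float) -> float:
    sxx = x.var()
    syy = y.var()
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    if sxx == 0.0 and syy == 0.0:
        raise DegenerateDataError("all points coincide")
    if sxx == 0.0:
        raise DegenerateDataError("x values are all equal; slope undefined")
    if sxy == 0.0:
        # no correlation: the scale-matching slope, positive by convention
        return math.sqrt(syy / (lam * sxx))
    disc = (lam * syy - sxx) ** 2 + 4.0 * lam * sxy**2
    return (lam * syy - sxx + math.sqrt(disc)) / (2.0 * lam * sxy)


def deming_fit(x, y, lam: float = 1.0) -> DemingFit:
    """Deming errors-in-variables line fit (slope and intercept only).

    Minimises the errors-in-variables objective
    sum (y_i - a - b x_i)^2 / (1 + lam b^2), i.e. squared residuals
    perpendicular to the line after rescaling the x axis by 1/sqrt(lam);
    the fitted line always passes through the centroid (x-bar, y-bar).
    """
    if lam <= 0:
        raise InferenceError(f"lambda must be positive, got {lam}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InferenceError("x and y must have equal length")
    if x.size < 3:
        raise InferenceError(f"need at least 3 points, got {x.size}")
    slope = _deming_slope(x, y, lam)
    intercept = float(y.mean() - slope * x.mean())
    return DemingFit(slope=float(slope), intercept=intercept, n=int(x.size), lam=float(lam))


def deming_slope_se(x, y, lam: float = 1.0) -> float:
    """Delete-one jackknife standard error of the Deming slope.

    SE² = ((n-1)/n) · Σ_i (b_i − b̄)² over leave-one-out slopes b_i.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise InferenceError(f"jackknife needs at least 4 points, got {n}")
    slopes = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        slopes[i] = _deming_slope(x[mask], y[mask], lam)
        mask[i] = True
    return float(math.sqrt((n - 1) / n * np.sum((slopes - slopes.mean()) ** 2)))


def test_slope(fit: DemingFit, reference: float = 1.0) -> float:
    """Two-sided p-value for H0: slope = reference, t with n - 2 df."""
    if fit.slope_se is None:
        raise InferenceError("fit carries no slope SE; use deming_regression")
    if fit.slope_se == 0.0:
        if fit.slope == reference:
            return 1.0
        warnings.warn("zero slope SE with slope != reference; reporting p = 0", stacklevel=2)
        return 0.0
    t = (fit.slope - reference) / fit.slope_se
    return float(2.0 * sps.t.sf(abs(t), fit.n - 2))


def deming_regression(x, y, lam: float = 1.0, reference: float = 1.0) -> DemingFit:
    """Full Deming analysis: fit + jackknife SE + slope tests.

    Returns a :class:`DemingFit` with ``slope_se``, ``p_slope_vs_one`` (the
    test against the supplied reference, by default the identity line) and
    ``p_slope_vs_zero`` filled in.
    """
    fit = deming_fit(x, y, lam)
    se = deming_slope_se(x, y, lam)
    fit = replace(fit, slope_se=se)
    return replace(
        fit,
        p_slope_vs_one=test_slope(fit, reference),
        p_slope_vs_zero=test_slope(fit, 0.0),
    )


@dataclass(frozen=True)
class ComparisonResult:
    pop_a: str
    pop_b: str
    use_weighted: bool
    mean_a: float
    mean_b: float
    ttest: TTestResult


def extract_frequency_vectors(
    aggregated: list[AggregatedSnp], pop_a: str, pop_b: str, use_weighted: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    field = "weighted" if use_weighted else "pooled"
    a = np.array([getattr(u, field)[pop_a] for u in aggregated])
    b = np.array([getattr(u, field)[pop_b] for u in aggregated])
    return a, b


def compare_populations(
    aggregated: list[AggregatedSnp],
    pop_a: str = "afr",
    pop_b: str = "eur",
    use_weighted: bool = True,
    direction: str = "greater",
    variant: str = "paired",
) -> ComparisonResult:
    """Compare mean per-unit frequencies between two populations."""
    a, b = extract_frequency_vectors(aggregated, pop_a, pop_b, use_weighted)
    tt = one_tailed_t_test(a, b, direction=direction, variant=variant)
    return ComparisonResult(
        pop_a=pop_a,
        pop_b=pop_b,
        use_weighted=use_weighted,
        mean_a=tt.mean_a,
        mean_b=tt.mean_b,
        ttest=tt,
    )
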