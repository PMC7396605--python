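"""Rayleigh and dual-element regression.

Under closed-system Rayleigh distillation the residual substrate's
isotope ratio obeys

    ln(R_t / R_0) = (eps / 1000) * ln(C_t / C_0)

where ``eps`` is the bulk enrichment factor in permil (negative for a
normal kinetic isotope effect).  :class:`RayleighModel` estimates
``eps`` per element by ordinary least squares of 1000*ln(R_t/R_0)
against ln f with a free intercept, so the slope is directly in permil;
the free intercept absorbs any mis-specification of the starting
composition and leaves the slope unbiased on exact data.

:class:`DualElementModel` fits the dual-element slope

    Lambda = m_2D  (delta13C regressed on delta37Cl)

which approximately equals eps_C / eps_Cl and is the
mechanism-diagnostic quantity of dual-element CSIA.  Both fits report
two-tailed t-based 95% confidence intervals on the slope with n - 2
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .core import (
    Element,
    ExperimentSeries,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "RayleighModel",
    "RayleighResults",
    "DualElementModel",
    "DualElementResults",
    "LambdaComparison",
    "fit_rayleigh",
    "fit_lambda",
    "compare_lambdas",
    "dual_fit_from_summary",
]


def _slope_fit(x: np.ndarray, y: np.ndarray, alpha: float):
    """OLS of y on x with intercept; returns statsmodels results."""
    if x.size < 3:
        raise InsufficientDataError(
            f"need >= 3 points for a slope with a t-based CI, got {x.size}"
        )
    if np.ptp(x) == 0.0:
        raise InvalidInputError("degenerate design: zero variance in the predictor")
    design = sm.add_constant(x)
    return sm.OLS(y, design).fit()


class _SlopeResultsMixin:
    """Shared accessors for a single-slope OLS fit."""

    _res: "sm.regression.linear_model.RegressionResultsWrapper"
    alpha: float

    @property
    def slope(self) -> float:
        return float(self._res.params[1])

    @property
    def intercept(self) -> float:
        return float(self._res.params[0])

    @property
    def stderr(self) -> float:
        return float(self._res.bse[1])

    @property
    def ci95(self) -> tuple[float, float]:
        lo, hi = np.asarray(self._res.conf_int(alpha=self.alpha))[1]
        return float(lo), float(hi)

    @property
    def ci_halfwidth(self) -> float:
        lo, hi = self.ci95
        return (hi - lo) / 2.0

    @property
    def r_squared(self) -> float:
        return float(self._res.rsquared)

    @property
    def n_points(self) -> int:
        return int(self._res.nobs)

    @property
    def pvalue_slope(self) -> float:
        return float(self._res.pvalues[1])


@dataclass
class _SeriesModelBase:
    series: ExperimentSeries

    @classmethod
    def from_dataframe(cls, df, *, series_id: str | None = None, **kwargs):
        """Build the model from a measurement table (see :mod:`dualcsia.io`)."""
        from .io import table_to_series

        series = table_to_series(df, series_id=series_id)
        return cls(series, **kwargs)


class RayleighModel(_SeriesModelBase):
    """Rayleigh-distillation regression for one element of one assay series.

    Parameters
    ----------
    series : ExperimentSeries
        Must provide >= 3 measurements of ``element`` at 0 < f <= 1 and a
        starting composition (explicit delta0 or an f = 1 reference).
    element : {"C", "Cl"}

    Examples
    --------
    >>> from dualcsia.simulate import SimulationConfig, simulate_rayleigh_series
    >>> cfg = SimulationConfig(epsilon_c=-27.5, epsilon_cl=-5.3, noise_sd=0.0)
    >>> series = simulate_rayleigh_series(cfg, "1,2-DCA", "1,2-DCA")
    >>> res = RayleighModel(series, "C").fit()
    >>> round(res.epsilon, 6)
    -27.5
    """

    def __init__(self, series: ExperimentSeries, element: Element):
        self.series = series
        self.element = element

    def fit(self, alpha: float = 0.05) -> "RayleighResults":
        series, element = self.series, self.element
        delta0 = series.delta0(element)
        if delta0 is None:
            raise InsufficientDataError(
                f"series {series.series_id!r}: no starting composition for {element}"
            )
        pts = series.points(element)
        if len(pts) < 3:
            raise InsufficientDataError(
                f"series {series.series_id!r}: {len(pts)} measurement(s) of "
                f"{element}, need >= 3"
            )
        f = np.array([p[0] for p in pts])
        delta = np.array([p[1] for p in pts])
        if np.any(f <= 0.0):
            raise InvalidInputError("fraction remaining must be > 0 for ln f")
        x = np.log(f)
        # permil-scaled ln-ratio so the slope is directly eps in permil
        y = 1000.0 * np.log((1.0 + delta / 1000.0) / (1.0 + delta0 / 1000.0))
        res = _slope_fit(x, y, alpha)
        return RayleighResults(self, res, alpha)


class RayleighResults(_SlopeResultsMixin):
    """Enrichment factor estimate with slope statistics.

    Attributes
    ----------
    epsilon : float
        Bulk enrichment factor in permil (the regression slope).
    stderr, ci95, r_squared, n_points, intercept
        Slope standard error (permil), two-tailed t-based CI, coefficient
        of determination, number of points, free intercept (permil
        ln-ratio units).
    """

    def __init__(self, model: RayleighModel, res, alpha: float):
        self.model = model
        self._res = res
        self.alpha = alpha
        self.element = model.element

    epsilon = _SlopeResultsMixin.slope

    def summary(self) -> str:
        lo, hi = self.ci95
        lines = [
            "Rayleigh enrichment-factor fit",
            "==============================",
            f"series:      {self.model.series.series_id}",
            f"compound:    {self.model.series.compound}"
            f" (cells grown on {self.model.series.cultivation_acceptor})",
            f"element:     {self.element}",
            f"n points:    {self.n_points}",
            f"epsilon:     {self.epsilon:.1f} permil",
            f"std err:     {self.stderr:.2f} permil",
            f"95% CI:      [{lo:.1f}, {hi:.1f}] permil",
            f"R-squared:   {self.r_squared:.2f}",
            f"intercept:   {self.intercept:.3f} (permil ln-ratio)",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<RayleighResults {self.element}: epsilon={self.epsilon:.2f} permil, "
            f"R2={self.r_squared:.3f}, n={self.n_points}>"
        )


class DualElementModel(_SeriesModelBase):
    """Dual-element regression: delta13C (response) on delta37Cl (predictor).

    The slope is the Lambda value; carbon sits on the ordinate so
    Lambda ~ eps_C / eps_Cl.  Requires >= 3 vials with both elements
    measured.
    """

    def __init__(self, series: ExperimentSeries):
        self.series = series

    def fit(self, alpha: float = 0.05) -> "DualElementResults":
        pts = self.series.paired_points()
        if len(pts) < 3:
            raise InsufficientDataError(
                f"series {self.series.series_id!r}: {len(pts)} paired "
                "(delta13C, delta37Cl) measurement(s), need >= 3"
            )
        x = np.array([p[0] for p in pts])  # delta37Cl
        y = np.array([p[1] for p in pts])  # delta13C
        res = _slope_fit(x, y, alpha)
        return DualElementResults(self, res, alpha)


class DualElementResults(_SlopeResultsMixin):
    """Lambda slope with t-based CI and R-squared."""

    def __init__(self, model: DualElementModel | None, res, alpha: float):
        self.model = model
        self._res = res
        self.alpha = alpha

    lam = _SlopeResultsMixin.slope

    def summary(self) -> str:
        lo, hi = self.ci95
        sid = self.model.series.series_id if self.model else "(summary-built)"
        lines = [
            "Dual-element (C vs Cl) fit",
            "==========================",
            f"series:      {sid}",
            f"n points:    {self.n_points}",
            f"Lambda:      {self.lam:.1f}",
            f"std err:     {self.stderr:.2f}",
            f"95% CI:      [{lo:.1f}, {hi:.1f}]",
            f"R-squared:   {self.r_squared:.2f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of delta13C vs delta37Cl with the fitted line."""
        from .plotting import dual_element_plot

        return dual_element_plot(self, ax=ax)

    def __repr__(self) -> str:
        return (
            f"<DualElementResults: Lambda={self.lam:.2f}, "
            f"R2={self.r_squared:.3f}, n={self.n_points}>"
        )


class _SummarySlopeResults:
    """Slope results reconstructed from a published (value, 95% half-width, n)."""

    def __init__(self, slope: float, halfwidth: float, n: int, alpha: float = 0.05):
        if n < 3:
            raise InsufficientDataError("need n >= 3 to reconstruct a slope CI")
        self._slope = slope
        self._n = n
        self.alpha = alpha
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
        self._stderr = halfwidth / tcrit
        self._ci = (slope - halfwidth, slope + halfwidth)

    slope = property(lambda self: self._slope)
    lam = slope
    stderr = property(lambda self: self._stderr)
    ci95 = property(lambda self: self._ci)
    n_points = property(lambda self: self._n)
    r_squared = float("nan")


def dual_fit_from_summary(
    lam: float, ci_halfwidth: float, n_points: int, alpha: float = 0.05
):
    """Reconstruct a Lambda fit from a published value and 95% CI half-width.

    Published tables report "Lambda +/- h" where h is the two-tailed
    t-based 95% half-width; the implied standard error is
    ``h / t_{1-alpha/2, n-2}``.  Useful for comparing a new fit against
    literature slopes via :func:`compare_lambdas`.
    """
    return _SummarySlopeResults(lam, ci_halfwidth, n_points, alpha)


@dataclass(frozen=True)
class LambdaComparison:
    """Welch-type comparison of two dual-element slopes."""

    verdict: str  # "distinct" | "indistinguishable"
    t_statistic: float
    p_value: float
    df: float
    ci_overlap: bool


def compare_lambdas(fit_a, fit_b, alpha: float = 0.05) -> LambdaComparison:
    """Welch t-test on two fitted slopes using their standard errors.

    Degrees of freedom by Welch-Satterthwaite with each slope carrying
    n_i - 2 df.  Also reports whether the two 95% CIs overlap.
    """
    b1, b2 = fit_a.slope, fit_b.slope
    se1, se2 = fit_a.stderr, fit_b.stderr
    if se1 == 0.0 and se2 == 0.0:
        same = b1 == b2
        return LambdaComparison(
            verdict="indistinguishable" if same else "distinct",
            t_statistic=0.0 if same else float("inf"),
            p_value=1.0 if same else 0.0,
            df=float(fit_a.n_points + fit_b.n_points - 4),
            ci_overlap=same,
        )
    se = np.hypot(se1, se2)
    t_stat = (b1 - b2) / se
    v1, v2 = se1**2, se2**2
    df1, df2 = fit_a.n_points - 2, fit_b.n_points - 2
    df = (v1 + v2) ** 2 / (v1**2 / df1 + v2**2 / df2)
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    lo1, hi1 = fit_a.ci95
    lo2, hi2 = fit_b.ci95
    overlap = (lo1 <= hi2) and (lo2 <= hi1)
    return LambdaComparison(
        verdict="distinct" if p < alpha else "indistinguishable",
        t_statistic=float(t_stat),
        p_value=float(min(p, 1.0)),
        df=float(df),
        ci_overlap=overlap,
    )


def fit_rayleigh(
    series: ExperimentSeries, element: Element, alpha: float = 0.05
) -> RayleighResults:
    """Estimate the bulk enrichment factor for one element of a series."""
    return RayleighModel(series, element).fit(alpha=alpha)


def fit_lambda(series: ExperimentSeries, alpha: float = 0.05) -> DualElementResults:
    """Estimate the dual-element Lambda slope of a series."""
    return DualElementModel(series).fit(alpha=alpha)
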