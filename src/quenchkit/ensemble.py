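"""Bulk titration analysis: relative quantum yields and quenching-model fits.

The ensemble workflow mirrors how the titrations are measured: for every
quencher concentration, fluorescence is recorded at several probe
concentrations and the relative quantum yield ``phi`` is the slope of
fluorescence against absorbance (robust against pipetting errors and,
because the absorbance stays in the dilute regime, free of inner-filter
corrections).  The quenching ratio ``phi0/phi`` is then assembled into a
:class:`QuenchCurve` and fitted with either the linear Stern-Volmer
model or the two-state static-quenching model, statsmodels-style: a
model object wraps the data, ``fit()`` returns a results object with
parameter estimates, standard errors, the reduced chi-square and a
``summary()`` table.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .equilibria import TwoStateParams, approx_ratio, precise_ratio

__all__ = [
    "FluorAbsSeries",
    "QuenchCurve",
    "FitResult",
    "relative_quantum_yield",
    "propagate_ratio_sigma",
    "build_quench_curve",
    "SternVolmerModel",
    "TwoStateQuenchModel",
    "fit_stern_volmer",
    "fit_two_state",
    "compare_models",
]

logger = logging.getLogger(__name__)

#: multi-start grid for the two-state fitter (logK x f), deterministic order
DEFAULT_STARTS = tuple((lk, f0) for lk in (4.0, 5.0, 6.0, 7.0, 8.0) for f0 in (0.05, 0.3, 0.7))


@dataclass(frozen=True)
class FluorAbsSeries:
    """Fluorescence vs. absorbance at one quencher concentration.

    One point per probe concentration (the measurement uses three).
    ``quencher_conc`` is mol/L; absorbance is dimensionless and
    fluorescence in arbitrary (but consistent) units.
    """

    quencher_conc: float
    absorbance: np.ndarray
    fluorescence: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "absorbance", a)
        object.__setattr__(self, "fluorescence", f)
        if a.shape != f.shape or a.ndim != 1:
            raise ValueError("absorbance and fluorescence must be 1-D arrays of equal length")
        if a.size < 2:
            raise ValueError("a fluorescence/absorbance series needs at least 2 points")
        if self.quencher_conc < 0:
            raise ValueError("quencher_conc must be non-negative")
        if np.any(a <= 0):
            raise ValueError("absorbance values must be positive")


@dataclass(frozen=True)
class QuenchCurve:
    """Quenching ratio ``phi0/phi`` versus quencher concentration.

    ``sigma`` carries per-point standard errors; it may be ``None``, in
    which case fits fall back to unit weights (and report an unreduced
    sum of squares with a warning).
    """

    conc: np.ndarray
    ratio: np.ndarray
    sigma: np.ndarray | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.conc, dtype=float)
        r = np.asarray(self.ratio, dtype=float)
        object.__setattr__(self, "conc", c)
        object.__setattr__(self, "ratio", r)
        if c.shape != r.shape or c.ndim != 1:
            raise ValueError("conc and ratio must be 1-D arrays of equal length")
        if np.any(c < 0):
            raise ValueError("quencher concentrations must be non-negative")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != c.shape:
                raise ValueError("sigma must match conc in shape")
            if np.any(s <= 0):
                raise ValueError("sigma values must be positive")
            if np.any(r < 1.0 - 3.0 * s):
                raise ValueError("quenching ratios below 1 by more than 3 sigma are unphysical")

    @property
    def n(self) -> int:
        return self.conc.size


@dataclass(frozen=True)
class FitResult:
    """Flat record of one quenching-model fit (one row of a Table-1-style report)."""

    logK: float
    f: float
    se_logK: float
    se_f: float
    chi2_red: float
    n_points: int
    model_tag: str
    converged: bool = True
    message: str = ""


def relative_quantum_yield(series: FluorAbsSeries) -> tuple[float, float]:
    """Relative quantum yield as the slope of fluorescence on absorbance.

    Ordinary least squares with a free intercept; returns the slope and
    its standard error.  With only two points the standard error is
    undefined (0 degrees of freedom) and comes back as ``nan``.
    """
    a = series.absorbance
    if np.ptp(a) == 0:
        raise ValueError("absorbance values are all equal; slope is undefined")
    res = stats.linregress(a, series.fluorescence)
    return float(res.slope), float(res.stderr)


def propagate_ratio_sigma(phi0: float, se0: float, phi: float, se: float) -> float:
    """First-order standard error of the ratio ``phi0/phi``.

    ``sqrt((se0/phi)^2 + (phi0*se/phi^2)^2)`` — both slopes treated as
    independent measurements.
    """
    return math.hypot(se0 / phi, phi0 * se / phi**2)


def build_quench_curve(series_list: list[FluorAbsSeries]) -> QuenchCurve:
    """Assemble a :class:`QuenchCurve` from per-concentration series.

    Exactly one series must have zero quencher concentration; its slope
    ``phi0`` defines the reference.  ``ratio_i = phi0/phi_i`` with the
    uncertainty propagated to first order from both slope standard
    errors, ``sigma_i = sqrt((se0/phi_i)^2 + (phi0*se_i/phi_i^2)^2)``.
    The zero-concentration point is fixed to ratio 1 with the relative
    uncertainty of ``phi0`` alone.
    """
    zeros = [s for s in series_list if s.quencher_conc == 0.0]
    if len(zeros) != 1:
        raise ValueError(
            f"need exactly one zero-quencher reference series, found {len(zeros)}"
        )
    phi0, se0 = relative_quantum_yield(zeros[0])
    conc, ratio, sigma = [], [], []
    for s in sorted(series_list, key=lambda s: s.quencher_conc):
        phi, se = relative_quantum_yield(s)
        if s.quencher_conc == 0.0:
            conc.append(0.0)
            ratio.append(1.0)
            sigma.append(se0 / phi0)
        else:
            conc.append(s.quencher_conc)
            ratio.append(phi0 / phi)
            sigma.append(propagate_ratio_sigma(phi0, se0, phi, se))
    # exact (noise-free) series give zero slope errors; floor keeps the
    # curve valid and the weights finite (and uniform) in that limit
    sigma = np.maximum(np.array(sigma), 1e-12)
    return QuenchCurve(conc=np.array(conc), ratio=np.array(ratio), sigma=sigma)


def _weights(curve: QuenchCurve) -> tuple[np.ndarray, bool]:
    """Inverse-sigma weights, or unit weights (flagged) when sigma is absent."""
    if curve.sigma is None:
        warnings.warn(
            "QuenchCurve has no per-point sigma; using unit weights, chi2 is "
            "an unreduced sum of squares",
            stacklevel=3,
        )
        return np.ones(curve.n), False
    return 1.0 / curve.sigma, True


class _QuenchResultsBase:
    """Shared results machinery: parameter table and summary()."""

    model_tag: str = ""

    def __init__(self, curve: QuenchCurve, chi2_red: float, weighted: bool):
        self.curve = curve
        self.chi2_red = float(chi2_red)
        self.weighted = weighted
        self.nobs = curve.n

    @property
    def params(self) -> dict[str, float]:  # pragma: no cover - overridden
        raise NotImplementedError

    @property
    def bse(self) -> dict[str, float]:  # pragma: no cover - overridden
        raise NotImplementedError

    def predict(self, conc=None) -> np.ndarray:  # pragma: no cover - overridden
        raise NotImplementedError

    def summary(self) -> str:
        lines = [
            f"Quenching-model fit: {self.model_tag}",
            "=" * 44,
            f"{'n points':<22}{self.nobs}",
            f"{'reduced chi2' if self.weighted else 'sum of squares':<22}{self.chi2_red:.4g}",
        ]
        for name, value in self.params.items():
            se = self.bse.get(name, float("nan"))
            lines.append(f"{name:<10}{value:>12.5g}  +/-{se:>10.3g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data with error bars and the fitted curve (diagnostic plot)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c_uM = self.curve.conc * 1e6
        yerr = self.curve.sigma if self.curve.sigma is not None else None
        ax.errorbar(c_uM, self.curve.ratio, yerr=yerr, fmt="o", label="data")
        grid = np.linspace(0, self.curve.conc.max(), 200)
        ax.plot(grid * 1e6, self.predict(grid), "-", label=self.model_tag)
        ax.set_xlabel("quencher concentration (µM)")
        ax.set_ylabel(r"$\varphi_0/\varphi_F$")
        ax.legend()
        return ax

    def as_record(self) -> FitResult:  # pragma: no cover - overridden
        raise NotImplementedError


class SternVolmerResults(_QuenchResultsBase):
    """Weighted through-origin fit of ``ratio - 1`` on concentration."""

    model_tag = "stern_volmer"

    def __init__(self, curve, ksv, se_ksv, chi2_red, weighted):
        super().__init__(curve, chi2_red, weighted)
        self.ksv = float(ksv)
        self.se_ksv = float(se_ksv)

    @property
    def params(self):
        return {"Ksv": self.ksv}

    @property
    def bse(self):
        return {"Ksv": self.se_ksv}

    def predict(self, conc=None):
        conc = self.curve.conc if conc is None else np.asarray(conc, dtype=float)
        return 1.0 + self.ksv * conc

    def as_record(self) -> FitResult:
        logK = math.log10(self.ksv) if self.ksv > 0 else float("nan")
        se_logK = (
            self.se_ksv / (self.ksv * math.log(10)) if self.ksv > 0 else float("nan")
        )
        return FitResult(
            logK=logK, f=float("nan"), se_logK=se_logK, se_f=float("nan"),
            chi2_red=self.chi2_red, n_points=self.nobs, model_tag=self.model_tag,
        )


class SternVolmerModel:
    """Linear Stern-Volmer model ``F0/F = 1 + Ksv*c`` for a quench curve.

    The slope is fitted by weighted least squares through the origin in
    ``(c, ratio-1)`` space — the null model against which the negative
    deviation characteristic of static two-state quenching is judged.
    """

    def __init__(self, curve: QuenchCurve):
        if curve.n < 3:
            raise ValueError("Stern-Volmer fit needs at least 3 points")
        self.curve = curve

    def fit(self) -> SternVolmerResults:
        c, y = self.curve.conc, self.curve.ratio - 1.0
        w, weighted = _weights(self.curve)
        sxx = np.sum((w * c) ** 2)
        if sxx == 0:
            raise ValueError("all concentrations are zero; Ksv undefined")
        ksv = np.sum(w * w * c * y) / sxx
        se = 1.0 / math.sqrt(sxx) if weighted else float("nan")
        resid = w * (y - ksv * c)
        dof = self.curve.n - 1
        chi2 = float(np.sum(resid**2))
        return SternVolmerResults(self.curve, ksv, se, chi2 / dof if weighted else chi2, weighted)


class TwoStateQuenchResults(_QuenchResultsBase):
    """Results of the two-state static-quenching fit over (logK, f)."""

    def __init__(self, curve, logK, f, cov, chi2_red, weighted, model_tag,
                 converged, message, L0=None):
        super().__init__(curve, chi2_red, weighted)
        self.model_tag = model_tag
        self.logK = float(logK)
        self.f = float(f)
        self.cov = cov
        self.converged = converged
        self.message = message
        self.L0 = L0

    @property
    def params(self):
        return {"logK": self.logK, "f": self.f}

    @property
    def bse(self):
        if self.cov is None:
            return {"logK": float("nan"), "f": float("nan")}
        se = np.sqrt(np.clip(np.diag(self.cov), 0, None))
        return {"logK": float(se[0]), "f": float(se[1])}

    @property
    def two_state_params(self) -> TwoStateParams:
        return TwoStateParams(K=10.0**self.logK, f=self.f)

    def predict(self, conc=None):
        conc = self.curve.conc if conc is None else np.asarray(conc, dtype=float)
        p = self.two_state_params
        if self.model_tag == "precise_two_state":
            return precise_ratio(p, self.L0, conc)
        return approx_ratio(p, conc)

    def as_record(self) -> FitResult:
        bse = self.bse
        return FitResult(
            logK=self.logK, f=self.f, se_logK=bse["logK"], se_f=bse["f"],
            chi2_red=self.chi2_red, n_points=self.nobs, model_tag=self.model_tag,
            converged=self.converged, message=self.message,
        )


class TwoStateQuenchModel:
    """Two-state static-quenching model fitted to a :class:`QuenchCurve`.

    Parameters
    ----------
    curve : QuenchCurve
    precise : bool
        If True, fit the exact mass-balance model (requires ``L0``);
        otherwise the dilute-probe approximation.
    L0 : float, optional
        Total probe concentration in mol/L, used only by the precise
        model.

    The fit is weighted least squares over ``(logK, f)`` with bounds
    ``logK in [0, 14]`` and ``f in (1e-6, 1]``, multi-started from a
    deterministic grid to avoid the local minima of the saturating
    model.
    """

    BOUNDS = ((0.0, 1e-6), (14.0, 1.0))

    def __init__(self, curve: QuenchCurve, precise: bool = False, L0: float | None = None):
        if curve.n < 4:
            raise ValueError("two-state fit needs at least 4 points (2 parameters)")
        if precise:
            if L0 is None or not (L0 > 0):
                raise ValueError("the precise model requires a positive probe concentration L0")
        self.curve = curve
        self.precise = precise
        self.L0 = L0

    def _model(self, theta: np.ndarray) -> np.ndarray:
        p = TwoStateParams(K=10.0 ** theta[0], f=theta[1])
        if self.precise:
            return precise_ratio(p, self.L0, self.curve.conc)
        return approx_ratio(p, self.curve.conc)

    def fit(self, starts: tuple[tuple[float, float], ...] = DEFAULT_STARTS) -> TwoStateQuenchResults:
        w, weighted = _weights(self.curve)
        y = self.curve.ratio

        def resid(theta):
            return w * (self._model(theta) - y)

        best = None
        for theta0 in starts:
            try:
                sol = optimize.least_squares(
                    resid, x0=np.array(theta0), bounds=self.BOUNDS, xtol=1e-12,
                    ftol=1e-12, gtol=1e-12, method="trf",
                )
            except Exception:  # pragma: no cover - defensive
                continue
            if sol.success and (best is None or sol.cost < best.cost - 1e-15):
                best = sol
        tag = "precise_two_state" if self.precise else "approx_two_state"
        dof = self.curve.n - 2
        if best is None:
            logger.warning("two-state fit failed to converge from all starts")
            return TwoStateQuenchResults(
                self.curve, float("nan"), float("nan"), None, float("nan"),
                weighted, tag, converged=False, message="no start converged", L0=self.L0,
            )
        chi2 = 2.0 * best.cost
        # covariance from the Gauss-Newton curvature of the weighted objective
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj)
            if not weighted:
                cov *= chi2 / dof  # scale by residual variance when unweighted
        except np.linalg.LinAlgError:  # pragma: no cover
            cov = None
        return TwoStateQuenchResults(
            self.curve, best.x[0], best.x[1], cov, chi2 / dof if weighted else chi2,
            weighted, tag, converged=True, message=best.message, L0=self.L0,
        )


def fit_stern_volmer(curve: QuenchCurve) -> FitResult:
    """Functional wrapper: Stern-Volmer fit as a flat :class:`FitResult`."""
    return SternVolmerModel(curve).fit().as_record()


def fit_two_state(curve: QuenchCurve, use_precise: bool = False, L0: float | None = None) -> FitResult:
    """Functional wrapper: two-state fit as a flat :class:`FitResult`."""
    return TwoStateQuenchModel(curve, precise=use_precise, L0=L0).fit().as_record()


def compare_models(curve: QuenchCurve, L0: float | None = None) -> list[FitResult]:
    """Fit the Stern-Volmer and two-state models, ranked by reduced chi2.

    Formalizes the visual model comparison of a curved Stern-Volmer
    plot: on genuinely two-state data the two-state fit ranks first by
    a wide chi2 margin, on linear data the models are statistically
    tied.
    """
    results = [fit_stern_volmer(curve), fit_two_state(curve)]
    if L0 is not None:
        results.append(fit_two_state(curve, use_precise=True, L0=L0))
    results.sort(key=lambda r: (not r.converged, r.chi2_red))
    return results
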