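"""Benesi-Hildebrand analysis of 1:1 binding absorbance titrations.

When a probe L (total concentration ``[L]0``) is titrated with a metal
ion in excess, the absorbance change at a wavelength on the wing of the
isosbestic point follows ``A - A0 = d*deps*[L]0*K*c/(1 + K*c)``, so the
transformed quantity ``y = d*[L]0*c/(A - A0)`` is linear in the metal
concentration ``c`` and the association constant is the quotient of the
slope and the y-intercept of that line — independent of the unknown
extinction-coefficient difference ``deps``.  At low metal concentration,
where the excess assumption fails (probe binding depletes the free
metal), the plot curves away from the line; that curvature is quantified
by :meth:`BenesiHildebrandResults.curvature`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AbsorbanceTitration",
    "bh_transform",
    "BenesiHildebrandModel",
    "BenesiHildebrandResults",
    "bh_fit",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AbsorbanceTitration:
    """An absorbance titration evaluated at a single wavelength.

    Parameters
    ----------
    L0 : float
        Total probe concentration, mol/L (> 0).
    d : float
        Optical path length, cm (> 0).
    lambda_eval : float
        Evaluation wavelength, nm (documentation only).
    metal_conc : array
        Total metal concentrations, mol/L, strictly increasing.
    absorbance : array
        Absorbance at each metal concentration.
    A0 : float
        Absorbance of the metal-free sample.
    """

    L0: float
    d: float
    lambda_eval: float
    metal_conc: np.ndarray
    absorbance: np.ndarray
    A0: float
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.metal_conc, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "metal_conc", c)
        object.__setattr__(self, "absorbance", a)
        if not (self.L0 > 0 and self.d > 0):
            raise ValueError("L0 and d must be positive")
        if c.ndim != 1 or c.shape != a.shape:
            raise ValueError("metal_conc and absorbance must be matching 1-D arrays")
        if np.any(np.diff(c) <= 0):
            raise ValueError("metal concentrations must be strictly increasing")
        dA = a - self.A0
        if np.any(np.diff(np.sign(dA[dA != 0]))):
            logger.warning("absorbance change crosses A0; not on one wing of the isosbestic point?")


def bh_transform(t: AbsorbanceTitration, floor: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Benesi-Hildebrand coordinates ``(c, d*L0*c/(A - A0))``.

    Rows with ``|A - A0| <= floor`` are excluded (the transform diverges
    as A approaches A0) and logged.  Raises if nothing survives.
    """
    dA = t.absorbance - t.A0
    keep = np.abs(dA) > max(floor, 0.0)
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info(
            "bh_transform: excluded %d row(s) with |A - A0| <= %g at metal conc %s",
            n_dropped, floor, t.metal_conc[~keep],
        )
    if not np.any(keep):
        raise ValueError("all titration rows fall below the |A - A0| exclusion floor")
    x = t.metal_conc[keep]
    y = t.d * t.L0 * x / dA[keep]
    return x, y


@dataclass(frozen=True)
class BenesiHildebrandResults:
    """Linear Benesi-Hildebrand fit; K = slope / intercept."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    cov_si: float
    r2: float
    x: np.ndarray
    y: np.ndarray
    converged: bool
    message: str = ""

    @property
    def K(self) -> float:
        return self.slope / self.intercept if self.converged else float("nan")

    @property
    def logK(self) -> float:
        return math.log10(self.K) if self.converged and self.K > 0 else float("nan")

    @property
    def se_logK(self) -> float:
        """First-order propagation through K = slope/intercept."""
        if not self.converged:
            return float("nan")
        rel_var = (
            (self.se_slope / self.slope) ** 2
            + (self.se_intercept / self.intercept) ** 2
            - 2.0 * self.cov_si / (self.slope * self.intercept)
        )
        return math.sqrt(max(rel_var, 0.0)) / math.log(10)

    def curvature(self) -> float:
        """Relative residual reduction of a quadratic over the linear fit.

        Zero for perfectly linear transformed data; positive when the
        plot bends (e.g. at low metal concentration, where the excess
        assumption breaks down).
        """
        lin = np.polyfit(self.x, self.y, 1)
        quad = np.polyfit(self.x, self.y, 2)
        rss_lin = float(np.sum((self.y - np.polyval(lin, self.x)) ** 2))
        rss_quad = float(np.sum((self.y - np.polyval(quad, self.x)) ** 2))
        if rss_lin == 0:
            return 0.0
        return (rss_lin - rss_quad) / rss_lin

    def summary(self) -> str:
        lines = [
            "Benesi-Hildebrand fit",
            "=" * 40,
            f"{'n points':<22}{self.x.size}",
            f"{'slope':<22}{self.slope:.6g} +/- {self.se_slope:.3g}",
            f"{'intercept':<22}{self.intercept:.6g} +/- {self.se_intercept:.3g}",
            f"{'R^2':<22}{self.r2:.6f}",
        ]
        if self.converged:
            lines.append(f"{'log10 K (M^-1)':<22}{self.logK:.4f} +/- {self.se_logK:.4f}")
        else:
            lines.append(f"FIT FLAGGED: {self.message}")
        return "\n".join(lines)


class BenesiHildebrandModel:
    """Estimate a 1:1 association constant from an absorbance titration.

    ``fit()`` applies :func:`bh_transform` and an ordinary least-squares
    line; a non-positive intercept (non-physical K) yields a flagged,
    non-converged result rather than an exception.
    """

    def __init__(self, titration: AbsorbanceTitration, floor: float = 0.0):
        self.titration = titration
        self.floor = floor

    def fit(self) -> BenesiHildebrandResults:
        x, y = bh_transform(self.titration, floor=self.floor)
        if x.size < 3:
            raise ValueError("Benesi-Hildebrand fit needs at least 3 usable points")
        res = stats.linregress(x, y)
        # covariance of (slope, intercept): cov = -xbar * var(slope)
        cov_si = -float(np.mean(x)) * res.stderr**2
        converged = res.intercept > 0
        return BenesiHildebrandResults(
            slope=float(res.slope), intercept=float(res.intercept),
            se_slope=float(res.stderr), se_intercept=float(res.intercept_stderr),
            cov_si=cov_si, r2=float(res.rvalue**2), x=x, y=y,
            converged=bool(converged),
            message="" if converged else "non-positive intercept implies non-physical K",
        )


def bh_fit(t: AbsorbanceTitration, floor: float = 0.0) -> tuple[float, float, float]:
    """Functional wrapper returning ``(logK, se_logK, r2)``.

    ``logK`` is ``nan`` (with a logged warning) when the intercept is
    non-positive.
    """
    res = BenesiHildebrandModel(t, floor=floor).fit()
    if not res.converged:
        logger.warning("bh_fit flagged: %s", res.message)
    return res.logK, res.se_logK, res.r2
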