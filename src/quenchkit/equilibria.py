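"""Closed-form models for reversible (static) fluorescence quenching.

A fluorescent probe ``L`` (here a dye-bipyridine-DNA conjugate) binds a
transition-metal ion ``M`` to form a 1:1 complex ``ML`` whose emission is
reduced to a fraction ``f`` (the residual relative quantum yield) of the
free probe's emission.  Three model curves for the quenching ratio
``F0/F`` as a function of quencher concentration are provided:

* :func:`stern_volmer_ratio` — the linear Stern-Volmer law expected for
  purely collisional quenching, ``F0/F = 1 + Ksv*c``.
* :func:`approx_ratio` — the two-state static model in the dilute-probe
  approximation, ``F0/F = (1 + K*c) / (1 + f*K*c)``, which saturates at
  ``1/f`` and therefore shows the negative deviation from the
  Stern-Volmer law characteristic of complex formation with a residual
  emissive state.
* :func:`precise_ratio` — the exact version that solves the 1:1 mass
  balance for the complex concentration instead of assuming the free
  quencher concentration equals the total one.

Concentrations are mol/L throughout; association constants are 1/(mol/L)
and reported as log10 elsewhere in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TwoStateParams",
    "EquilibriumState",
    "stern_volmer_ratio",
    "approx_ratio",
    "solve_equilibrium",
    "precise_ratio",
]


@dataclass(frozen=True)
class TwoStateParams:
    """Parameters of the two-state quenching model.

    Parameters
    ----------
    K : float
        Association constant of the probe/metal complex, 1/(mol/L).
        Strictly positive.
    f : float
        Residual relative quantum yield of the complex (emission of the
        bound probe relative to the free probe).  ``f = 1`` means the
        complex is as bright as the free probe (no quenching); ``f = 0``
        (a fully dark complex) is admitted as a limiting input to the
        model functions, in which case the approximate model reduces to
        the static Stern-Volmer form ``1 + K*c``.
    """

    K: float
    f: float

    def __post_init__(self) -> None:
        if not (self.K > 0) or not math.isfinite(self.K):
            raise ValueError(f"association constant K must be positive and finite, got {self.K}")
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"residual quantum yield f must lie in [0, 1], got {self.f}")

    @property
    def logK(self) -> float:
        """log10 of the association constant (the unit used in reports)."""
        return math.log10(self.K)


@dataclass(frozen=True)
class EquilibriumState:
    """Solution of the 1:1 binding mass balance L + M <-> ML.

    ``K*(L0-ML)*(M0-ML) = ML`` with total probe ``L0`` and total metal
    ``M0`` (both mol/L).
    """

    L0: float
    M0: float
    ML: float

    @property
    def free_probe(self) -> float:
        return self.L0 - self.ML

    @property
    def free_metal(self) -> float:
        return self.M0 - self.ML

    @property
    def bound_fraction(self) -> float:
        """Fraction of the probe present as complex, ML/L0."""
        if self.L0 == 0:
            return 0.0
        return self.ML / self.L0


def _check_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if np.any(np.asarray(value) < 0):
            raise ValueError(f"{name} must be non-negative")


def stern_volmer_ratio(ksv: float, c):
    """Stern-Volmer quenching ratio ``F0/F = 1 + ksv*c``.

    Parameters
    ----------
    ksv : float
        Stern-Volmer constant, 1/(mol/L); must be >= 0.
    c : float or array_like
        Quencher concentration, mol/L; must be >= 0.
    """
    _check_nonnegative(ksv=ksv, c=c)
    return 1.0 + ksv * np.asarray(c, dtype=float) if np.ndim(c) else 1.0 + ksv * float(c)


def approx_ratio(params: TwoStateParams, c):
    """Two-state quenching ratio in the dilute-probe approximation.

    ``F0/F = (1 + K*c) / (1 + f*K*c)`` — monotone nondecreasing in the
    quencher concentration ``c`` and bounded above by ``1/f``.  Valid
    when the probe concentration is small compared to 1/K so that
    complexation does not deplete the free quencher.
    """
    _check_nonnegative(c=c)
    c = np.asarray(c, dtype=float)
    Kc = params.K * c
    out = (1.0 + Kc) / (1.0 + params.f * Kc)
    return out if out.ndim else float(out)


def _complex_conc(K: float, L0, M0):
    """Vectorised physically admissible root of the 1:1 mass balance.

    The quadratic ``K*ML^2 - (K*(L0+M0)+1)*ML + K*L0*M0 = 0`` is solved
    in the cancellation-free form ``ML = 2*K*L0*M0 / (b + sqrt(b^2 -
    4*K^2*L0*M0))`` with ``b = K*(L0+M0)+1``, which stays accurate for
    the K = 1e4..1e12 range encountered with these chelators.
    """
    L0 = np.asarray(L0, dtype=float)
    M0 = np.asarray(M0, dtype=float)
    b = K * (L0 + M0) + 1.0
    disc = b * b - 4.0 * K * K * L0 * M0
    # disc >= 1 analytically; clip guards rounding at extreme K*L0*M0
    ml = 2.0 * K * L0 * M0 / (b + np.sqrt(np.maximum(disc, 0.0)))
    return np.minimum(ml, np.minimum(L0, M0))


def solve_equilibrium(K: float, L0: float, M0: float) -> EquilibriumState:
    """Solve the 1:1 binding mass balance for the complex concentration.

    Returns the smaller (physical) root of the binding quadratic, which
    satisfies ``0 <= ML <= min(L0, M0)``.
    """
    if not (K > 0):
        raise ValueError("K must be positive")
    _check_nonnegative(L0=L0, M0=M0)
    ml = float(_complex_conc(K, L0, M0))
    return EquilibriumState(L0=float(L0), M0=float(M0), ML=ml)


def precise_ratio(params: TwoStateParams, L0: float, M0):
    """Exact two-state quenching ratio with full mass balance.

    Computes the bound fraction ``x = ML/L0`` from
    :func:`solve_equilibrium` and returns ``F0/F = 1 / (1 - (1-f)*x)``.
    Coincides with :func:`approx_ratio` in the dilute-probe limit
    ``K*L0 -> 0`` and is never larger than it (probe-driven depletion of
    the free quencher can only reduce quenching).

    Parameters
    ----------
    params : TwoStateParams
    L0 : float
        Total probe concentration, mol/L; must be > 0.
    M0 : float or array_like
        Total quencher concentration(s), mol/L.
    """
    if not (L0 > 0):
        raise ValueError("precise_ratio requires a positive probe concentration L0")
    _check_nonnegative(M0=M0)
    if not (params.K > 0):
        raise ValueError("K must be positive")
    x = _complex_conc(params.K, L0, M0) / L0
    out = 1.0 / (1.0 - (1.0 - params.f) * x)
    return out if np.ndim(M0) else float(out)
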