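"""Synthetic-data generators for every stage of the quenching analysis.

The generators emulate the statistical structure of the measurements:

* ensemble titrations — fluorescence vs. absorbance at three probe
  concentrations per quencher concentration (0-20 µM grid), with
  multiplicative photometric noise on fluorescence;
* direct quench curves — the assembled ratio phi0/phi with known
  per-point uncertainty, for fitter calibration;
* 1:1 absorbance titrations via the full mass balance, for the
  Benesi-Hildebrand analysis;
* single-molecule blinking traces — a continuous-time two-state Markov
  chain (bright <-> dim) with single-step photobleaching to a
  background level and Poisson photon counting per bin;
* smooth Gaussian-band emission/extinction spectra for the Förster
  calculations.

All generators are reproducible given their seed and record the seed
and parameters in the output ``meta``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .benesi import AbsorbanceTitration
from .ensemble import FluorAbsSeries, QuenchCurve
from .equilibria import TwoStateParams, approx_ratio, precise_ratio, solve_equilibrium
from .forster import Spectrum
from .traces import PhotonTrace

__all__ = [
    "BlinkingModel",
    "DEFAULT_CONC_GRID",
    "TMR_PROBE_CONCS",
    "gen_ensemble_titration",
    "gen_quench_curve",
    "gen_absorbance_titration",
    "gen_blinking_trace",
    "gen_blinking_experiment",
    "gen_spectra",
]

#: 21 evenly spaced quencher concentrations covering 0-20 µM (mol/L)
DEFAULT_CONC_GRID = tuple(np.linspace(0.0, 20e-6, 21))

#: probe concentrations used for the TMR slope measurements (mol/L)
TMR_PROBE_CONCS = (0.34e-6, 0.47e-6, 0.68e-6)


def gen_ensemble_titration(
    params: TwoStateParams,
    conc_grid=DEFAULT_CONC_GRID,
    probe_concs=TMR_PROBE_CONCS,
    noise_frac: float = 0.02,
    seed: int = 0,
    *,
    model: str = "approx",
    phi0: float = 1000.0,
    eps_d: float = 2.85e4,
) -> list[FluorAbsSeries]:
    """Simulate fluorescence/absorbance series over a quencher titration.

    Absorbance is proportional to the probe concentration and
    independent of the quencher (``A = eps_d * L0`` with ``eps_d`` the
    extinction coefficient times path length, L/mol); fluorescence is
    ``A * phi0 / ratio(c) * (1 + noise)`` with multiplicative Gaussian
    noise of fractional width ``noise_frac``.  ``model='precise'``
    uses the full mass-balance ratio at each probe concentration,
    exposing the dilute-probe bias of the approximate fitter when
    ``K*L0`` is not small.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be non-negative")
    if model not in ("approx", "precise"):
        raise ValueError("model must be 'approx' or 'precise'")
    conc_grid = np.asarray(conc_grid, dtype=float)
    probe_concs = np.asarray(probe_concs, dtype=float)
    if conc_grid.size == 0 or probe_concs.size == 0:
        raise ValueError("concentration grids must be non-empty")
    rng = np.random.default_rng(seed)
    series = []
    for c in conc_grid:
        absorbance = eps_d * probe_concs
        if model == "precise":
            ratios = np.array([precise_ratio(params, L0, c) for L0 in probe_concs])
        else:
            ratios = np.full(probe_concs.size, approx_ratio(params, c))
        fluor = absorbance * (phi0 / ratios)
        fluor = fluor * (1.0 + noise_frac * rng.standard_normal(fluor.shape))
        series.append(
            FluorAbsSeries(
                quencher_conc=float(c), absorbance=absorbance, fluorescence=fluor,
                meta={"seed": seed, "noise_frac": noise_frac, "model": model,
                      "phi0": phi0, "eps_d": eps_d, "K": params.K, "f": params.f,
                      "probe_conc": probe_concs.copy()},
            )
        )
    return series


def gen_quench_curve(
    params: TwoStateParams,
    conc_grid=DEFAULT_CONC_GRID,
    noise_frac: float = 0.02,
    seed: int = 0,
    *,
    model: str = "approx",
    L0: float | None = None,
) -> QuenchCurve:
    """Simulate an assembled quench curve with known per-point sigma.

    ``ratio_i = m(c_i) * (1 + noise_frac * eps_i)`` with independent
    standard-normal ``eps_i`` and ``sigma_i = noise_frac * m(c_i)`` —
    i.e. the noise model the weighted fitters assume, which makes this
    generator the reference for chi-square calibration.  ``eps`` is
    truncated symmetrically at ±3 (affecting 0.3% of draws, no bias) so
    every generated curve satisfies the physicality bound
    ``ratio >= 1 - 3*sigma``.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be non-negative")
    conc = np.asarray(conc_grid, dtype=float)
    if model == "approx":
        truth = approx_ratio(params, conc)
    elif model == "precise":
        if L0 is None:
            raise ValueError("model='precise' requires L0")
        truth = precise_ratio(params, L0, conc)
    else:
        raise ValueError("model must be 'approx' or 'precise'")
    truth = np.atleast_1d(np.asarray(truth, dtype=float))
    rng = np.random.default_rng(seed)
    if noise_frac > 0:
        eps = np.clip(rng.standard_normal(truth.shape), -2.99, 2.99)
        ratio = truth * (1.0 + noise_frac * eps)
        sigma = noise_frac * truth
    else:
        ratio = truth.copy()
        sigma = np.full_like(truth, 1e-6)
    return QuenchCurve(
        conc=conc, ratio=ratio, sigma=sigma,
        meta={"seed": seed, "noise_frac": noise_frac, "model": model,
              "K": params.K, "f": params.f, "L0": L0},
    )


def gen_absorbance_titration(
    K: float,
    L0: float,
    delta_eps: float,
    d: float,
    A0: float,
    metal_grid,
    noise_abs: float = 0.0,
    seed: int = 0,
    lambda_eval: float = 551.0,
) -> AbsorbanceTitration:
    """Simulate a 1:1 binding absorbance titration (full mass balance).

    ``A(c) = A0 + delta_eps * d * ML(K, L0, c)`` with the complex
    concentration from the exact binding quadratic — not the
    excess-metal approximation — plus additive Gaussian noise of
    standard deviation ``noise_abs``.  At low metal concentration the
    exact ML deviates from the excess-metal form, which is what bends
    the Benesi-Hildebrand plot there.
    """
    if noise_abs < 0:
        raise ValueError("noise_abs must be non-negative")
    metal = np.asarray(metal_grid, dtype=float)
    ml = np.array([solve_equilibrium(K, L0, m).ML for m in metal])
    A = A0 + delta_eps * d * ml
    rng = np.random.default_rng(seed)
    if noise_abs > 0:
        A = A + noise_abs * rng.standard_normal(A.shape)
    return AbsorbanceTitration(
        L0=L0, d=d, lambda_eval=lambda_eval, metal_conc=metal, absorbance=A, A0=A0,
        meta={"seed": seed, "K": K, "delta_eps": delta_eps, "noise_abs": noise_abs},
    )


@dataclass(frozen=True)
class BlinkingModel:
    """Parameters of the two-state blinking simulation.

    The molecule starts bright (free probe), switches to the dim
    (metal-bound) state with rate ``k_on`` and back with ``k_off``
    (exponential dwell times), and photobleaches at rate
    ``bleach_rate`` to a constant background.  ``rate_*`` are expected
    photon counts per bin; per-bin expectations are the time-weighted
    mixture of the state rates within the bin, and observed counts are
    Poisson.  Defaults emulate low-excitation confocal traces: 1 ms
    bins, 30 s duration, bright ≈ 40 counts/bin, background 2
    counts/bin, bleaching after 20 s on average.
    """

    k_on: float = 1.0
    k_off: float = 1.5
    rate_bright: float = 40.0
    rate_dim: float = 8.84
    rate_bg: float = 2.0
    bleach_rate: float = 0.05
    duration: float = 30.0
    bin_width: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "rate_bright", "rate_dim", "rate_bg", "bleach_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.rate_bg <= self.rate_dim <= self.rate_bright):
            raise ValueError("rates must satisfy rate_bg <= rate_dim <= rate_bright")
        if not (self.duration > 0 and self.bin_width > 0):
            raise ValueError("duration and bin_width must be positive")

    @property
    def true_f(self) -> float:
        """Background-corrected dim/bright ratio implied by the rates."""
        return (self.rate_dim - self.rate_bg) / (self.rate_bright - self.rate_bg)

    def with_true_f(self, f: float) -> "BlinkingModel":
        """Copy with ``rate_dim`` set so the true ratio equals ``f``."""
        kw = asdict(self)
        kw["rate_dim"] = self.rate_bg + f * (self.rate_bright - self.rate_bg)
        return BlinkingModel(**kw)


def gen_blinking_trace(model: BlinkingModel) -> PhotonTrace:
    """Simulate one binned photon-count trace from a blinking model.

    The piecewise-constant emission-rate path (bright/dim dwells, then
    background after the bleach time) is integrated exactly over each
    bin — the cumulative intensity is piecewise linear, so per-bin
    expectations come from interpolating it at the bin edges — and
    counts are drawn Poisson.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(model.seed)
    T = model.duration
    t_bleach = (
        rng.exponential(1.0 / model.bleach_rate) if model.bleach_rate > 0 else math.inf
    )
    t_active = min(T, t_bleach)

    knots = [0.0]
    dens = []  # photon rate density (counts per second) on each segment
    t, bright = 0.0, True
    while t < t_active:
        k = model.k_on if bright else model.k_off
        dwell = rng.exponential(1.0 / k) if k > 0 else math.inf
        seg_end = min(t + dwell, t_active)
        dens.append((model.rate_bright if bright else model.rate_dim) / model.bin_width)
        knots.append(seg_end)
        t += dwell
        bright = not bright
    if t_bleach < T:
        dens.append(model.rate_bg / model.bin_width)
        knots.append(T)

    knots = np.asarray(knots)
    cum = np.concatenate([[0.0], np.cumsum(np.asarray(dens) * np.diff(knots))])
    n_bins = int(round(T / model.bin_width))
    edges = np.arange(n_bins + 1) * model.bin_width
    expected = np.diff(np.interp(edges, knots, cum))
    counts = rng.poisson(np.clip(expected, 0.0, None))
    return PhotonTrace(
        bin_width=model.bin_width, counts=counts,
        meta={**asdict(model), "t_bleach": t_bleach},
    )


def gen_blinking_experiment(model: BlinkingModel, n_traces: int, seed: int) -> list[PhotonTrace]:
    """Simulate ``n_traces`` molecules with per-trace seeds spawned from ``seed``."""
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    ss = np.random.SeedSequence(seed)
    traces = []
    for i, child in enumerate(ss.spawn(n_traces)):
        sub = int(child.generate_state(1)[0] % (2**31))
        kw = asdict(model)
        kw["seed"] = sub
        trace = gen_blinking_trace(BlinkingModel(**kw))
        object.__setattr__(trace, "molecule_id", f"mol{i:03d}")
        traces.append(trace)
    return traces


def gen_spectra(bands, kind: str, grid=None) -> Spectrum:
    """Smooth synthetic spectrum as a sum of Gaussian bands.

    ``bands`` is a list of ``(center_nm, width_nm, amplitude)``; the
    default grid spans the bands ±4 widths at 0.5 nm spacing.
    """
    bands = list(bands)
    if not bands:
        raise ValueError("need at least one band")
    for _, width, _ in bands:
        if width <= 0:
            raise ValueError("band widths must be positive")
    if grid is None:
        lo = min(c - 4 * w for c, w, _ in bands)
        hi = max(c + 4 * w for c, w, _ in bands)
        grid = np.arange(lo, hi + 0.5, 0.5)
    grid = np.asarray(grid, dtype=float)
    value = np.zeros_like(grid)
    for center, width, amp in bands:
        value += amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return Spectrum(wavelength=grid, value=value, kind=kind,
                    meta={"bands": bands})
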