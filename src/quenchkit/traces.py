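"""Single-molecule blinking-trace analysis.

An immobilized probe switches between a bright state (free probe) and a
dim state (metal-bound, quenched probe) until single-step photobleaching
drops it to the background level.  The per-bin photon counts of one
trace are accumulated into an intensity histogram; a sum of three
Gaussians — background (b), dim (1) and bright (2) — is fitted to the
histogram; and the single-molecule residual relative quantum yield of
the quenched state is

    f = (mean_1 - mean_b) / (mean_2 - mean_b),

the background-corrected dim/bright brightness ratio.  Per-trace values
are averaged over 10-20 traces per sample to give the quantity reported
alongside the bulk fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "PhotonTrace",
    "CountHistogram",
    "GaussianComponent",
    "HistogramDecomposition",
    "AggregateQY",
    "accumulate_histogram",
    "fit_three_gaussians",
    "estimate_fpq",
    "aggregate_traces",
    "BlinkingTraceModel",
    "analyze_experiment",
]

logger = logging.getLogger(__name__)

#: components closer than this many (largest) sigmas are considered merged
MERGE_SIGMA_FACTOR = 1.5
#: minimum share of total histogram mass for a component to count as supported
MIN_MASS_SHARE = 1e-3
#: minimum relative weighted-RSS reduction of 3 vs 2 Gaussians for the
#: third component to count as a resolved mode
MIN_THIRD_COMPONENT_GAIN = 0.5
#: per-trace f outside [0,1] by more than this is excluded from aggregation
F_EXCLUSION_MARGIN = 0.1


@dataclass(frozen=True)
class PhotonTrace:
    """Binned photon counts of one immobilized molecule."""

    bin_width: float
    counts: np.ndarray
    molecule_id: str | None = None
    quencher_conc: float | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValueError("photon counts must be integers")
            c = np.round(c).astype(np.int64)
        if np.any(c < 0):
            raise ValueError("photon counts must be non-negative")
        if not (self.bin_width > 0):
            raise ValueError("bin_width must be positive")
        object.__setattr__(self, "counts", c)

    @property
    def duration(self) -> float:
        return self.counts.size * self.bin_width


@dataclass(frozen=True)
class CountHistogram:
    """Occupancy histogram of per-bin photon counts."""

    centers: np.ndarray
    occupancy: np.ndarray

    @property
    def n_occupied(self) -> int:
        return int(np.sum(self.occupancy > 0))

    @property
    def total(self) -> float:
        return float(np.sum(self.occupancy))


def accumulate_histogram(trace: PhotonTrace, nbins: int | str = "auto") -> CountHistogram:
    """Accumulate a trace's per-bin counts into an intensity histogram.

    With ``nbins='auto'`` the bin width is one count per bin for count
    ranges below 200 (so histogram bins align with the integer count
    values) and Freedman-Diaconis otherwise.
    """
    counts = trace.counts
    lo, hi = int(counts.min()), int(counts.max())
    if nbins == "auto":
        if hi < 200:
            edges = np.arange(lo - 0.5, hi + 1.5)
        else:
            edges = np.histogram_bin_edges(counts, bins="fd")
    else:
        nbins = int(nbins)
        if nbins < 1:
            raise ValueError("nbins must be >= 1")
        if nbins >= hi - lo:  # integer-aligned when the bin count covers the range
            edges = np.arange(lo - 0.5, hi + 1.5)
        else:
            edges = np.histogram_bin_edges(counts, bins=nbins)
    occ, edges = np.histogram(counts, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return CountHistogram(centers=centers, occupancy=occ.astype(float))


@dataclass(frozen=True)
class GaussianComponent:
    mean: float
    sigma: float
    amplitude: float  # peak height in occupancy units

    @property
    def mass(self) -> float:
        """Approximate occupancy mass (area) of the component."""
        return self.amplitude * self.sigma * math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class HistogramDecomposition:
    """Three-Gaussian decomposition of an intensity histogram.

    Components are ordered by construction:
    ``background.mean < dim.mean < bright.mean``.  ``flags`` records
    quality problems (merged or unsupported components); a flagged
    decomposition should not feed a Table-1-style aggregate.
    """

    background: GaussianComponent
    dim: GaussianComponent
    bright: GaussianComponent
    rss: float
    flags: tuple[str, ...] = ()

    @property
    def components(self) -> tuple[GaussianComponent, GaussianComponent, GaussianComponent]:
        return (self.background, self.dim, self.bright)

    @property
    def degenerate(self) -> bool:
        return len(self.flags) > 0


def _kmeans_seed(hist: CountHistogram, quantiles=(0.1, 0.5, 0.9), iters: int = 25) -> np.ndarray:
    """Deterministic occupancy-weighted 3-means on the count axis.

    Initialized at occupancy quantiles; returns a 9-vector seed
    (mean_b, d1, d2, sigmas, amplitudes) for the Gaussian fit.
    """
    x, w = hist.centers, hist.occupancy
    cum = np.cumsum(w) / np.sum(w)
    centers = np.array([x[np.searchsorted(cum, q)] for q in quantiles], dtype=float)
    centers = np.unique(centers)
    while centers.size < 3:  # degenerate histograms: pad with offsets
        centers = np.unique(np.append(centers, centers[-1] + np.arange(1, 4 - centers.size)))
    for _ in range(iters):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        for k in range(3):
            wk = w[assign == k]
            if wk.sum() > 0:
                centers[k] = np.average(x[assign == k], weights=wk)
        centers = np.sort(centers)
    assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    sigmas, amps = np.empty(3), np.empty(3)
    for k in range(3):
        sel = assign == k
        wk = w[sel]
        if wk.sum() > 0:
            var = np.average((x[sel] - centers[k]) ** 2, weights=wk)
            sigmas[k] = max(math.sqrt(var), 0.5)
            amps[k] = max(wk.max(), 1.0)
        else:
            sigmas[k], amps[k] = 1.0, 1.0
    d1 = max(centers[1] - centers[0], 1e-3)
    d2 = max(centers[2] - centers[1], 1e-3)
    # photon counting: per-state spread is at least Poisson, sqrt(mean)
    sigmas = np.maximum(sigmas, np.sqrt(np.maximum(centers, 1.0)))
    return np.array([centers[0], d1, d2, *sigmas, *amps])


def _peak_seed(hist: CountHistogram) -> np.ndarray | None:
    """Seed from the three highest local maxima of the occupancy curve.

    Complements the k-means seed, which can merge narrow neighbouring
    peaks (e.g. background right next to the dim state).  Returns None
    when fewer than three interior maxima exist.
    """
    x, y = hist.centers, hist.occupancy
    if y.size < 5:
        return None
    interior = (y[1:-1] >= y[:-2]) & (y[1:-1] > y[2:]) & (y[1:-1] > 0)
    idx = np.flatnonzero(interior) + 1
    if idx.size < 3:
        return None
    top = idx[np.argsort(y[idx])[::-1][:3]]
    centers = np.sort(x[top])
    if np.any(np.diff(centers) < 1e-9):
        return None
    sigmas = np.sqrt(np.maximum(centers, 1.0))
    amps = [max(float(y[x == c][0]) if np.any(x == c) else y.max(), 1.0) for c in centers]
    return np.array([centers[0], centers[1] - centers[0], centers[2] - centers[1],
                     *sigmas, *amps])


def _double_gauss_wrss(hist: CountHistogram) -> float:
    """Weighted RSS of the best two-Gaussian fit (the no-dim-state reference)."""
    x, y = hist.centers, hist.occupancy
    lo, hi = float(x.min()), float(x.max())
    span = hi - lo
    w = 1.0 / np.sqrt(y + 1.0)
    cum = np.cumsum(y) / np.sum(y)
    c1 = float(x[np.searchsorted(cum, 0.15)])
    c2 = float(x[np.searchsorted(cum, 0.85)])
    if c2 <= c1:
        c2 = c1 + 1.0
    t0 = [c1, c2 - c1, math.sqrt(max(c1, 1.0)), math.sqrt(max(c2, 1.0)), y.max(), y.max()]
    lower = [lo - span, 1e-3, 0.2, 0.2, 0.0, 0.0]
    upper = [hi, 2 * span + 1, span + 1, span + 1, 2 * y.max(), 2 * y.max()]

    def model(th):
        m1, d, s1, s2, a1, a2 = th
        return (a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2)
                + a2 * np.exp(-0.5 * ((x - m1 - d) / s2) ** 2))

    def resid(th):
        return w * (model(th) - y)

    sol = optimize.least_squares(resid, np.clip(t0, lower, upper), bounds=(lower, upper))
    return float(2.0 * sol.cost)


def _triple_gauss(x: np.ndarray, theta: np.ndarray) -> np.ndarray:
    mb, d1, d2, sb, s1, s2, ab, a1, a2 = theta
    mus = (mb, mb + d1, mb + d1 + d2)
    out = np.zeros_like(x, dtype=float)
    for mu, s, a in zip(mus, (sb, s1, s2), (ab, a1, a2)):
        out += a * np.exp(-0.5 * ((x - mu) / s) ** 2)
    return out


def fit_three_gaussians(hist: CountHistogram) -> HistogramDecomposition:
    """Least-squares fit of three Gaussians to a count histogram.

    The means are parameterized as cumulative positive increments
    (``mean_b``, ``mean_b + d1``, ``mean_b + d1 + d2`` with d1, d2 > 0),
    which enforces the background < dim < bright ordering and removes
    label switching.  Occupancies are count data, so residuals carry
    approximate Poisson weights ``1/sqrt(occupancy + 1)``; without them
    a long post-bleach background segment dominates the objective and
    drags the dim component off its peak.  Fits start from a
    deterministic occupancy-weighted k-means seed plus a variant that
    pins the background at the lowest occupied count; the lower-cost
    solution wins.  Merged or unsupported components are flagged, not
    raised.
    """
    if hist.n_occupied < 10:
        raise ValueError(
            f"histogram has only {hist.n_occupied} occupied bins; need >= 10 for a "
            "three-component fit"
        )
    x, y = hist.centers, hist.occupancy
    lo, hi = float(x.min()), float(x.max())
    span = hi - lo

    starts = [_kmeans_seed(hist)]
    alt = starts[0].copy()  # background pinned at the low edge of the histogram
    alt[0] = lo
    alt[1] = max(starts[0][0] + starts[0][1] - lo, 1e-3)
    starts.append(alt)
    peaks = _peak_seed(hist)
    if peaks is not None:
        starts.append(peaks)

    lower = [lo - span, 1e-3, 1e-3, 0.2, 0.2, 0.2, 0.0, 0.0, 0.0]
    upper = [hi, 2 * span + 1, 2 * span + 1, span + 1, span + 1, span + 1,
             2 * y.max(), 2 * y.max(), 2 * y.max()]

    w = 1.0 / np.sqrt(y + 1.0)

    def resid(theta):
        return w * (_triple_gauss(x, theta) - y)

    best = None
    for theta0 in starts:
        t0 = np.clip(theta0, lower, upper)
        try:
            sol = optimize.least_squares(resid, x0=t0, bounds=(lower, upper), method="trf")
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:  # pragma: no cover - least_squares is robust within bounds
        raise RuntimeError("three-Gaussian fit failed from all seeds")

    mb, d1, d2, sb, s1, s2, ab, a1, a2 = best.x
    comps = (
        GaussianComponent(mb, sb, ab),
        GaussianComponent(mb + d1, s1, a1),
        GaussianComponent(mb + d1 + d2, s2, a2),
    )
    flags: list[str] = []
    if d1 < MERGE_SIGMA_FACTOR * max(sb, s1):
        flags.append("merged:background-dim")
    if d2 < MERGE_SIGMA_FACTOR * max(s1, s2):
        flags.append("merged:dim-bright")
    total_mass = sum(c.mass for c in comps)
    for label, comp in zip(("background", "dim", "bright"), comps):
        if total_mass == 0 or comp.mass < MIN_MASS_SHARE * total_mass:
            flags.append(f"unsupported:{label}")
    # does the third component resolve a real mode?  Compare against the
    # best two-Gaussian fit: a histogram with only two modes (e.g. a
    # molecule that never bleached, or dim merged into background) gains
    # little from the extra component.
    wrss3 = float(2.0 * best.cost)
    wrss2 = _double_gauss_wrss(hist)
    if wrss2 > 0 and (wrss2 - wrss3) / wrss2 < MIN_THIRD_COMPONENT_GAIN:
        flags.append("two-modes")
    if flags:
        logger.info("three-Gaussian fit flagged: %s", ", ".join(flags))
    return HistogramDecomposition(
        background=comps[0], dim=comps[1], bright=comps[2],
        rss=float(2.0 * best.cost), flags=tuple(flags),
    )


def estimate_fpq(dec: HistogramDecomposition) -> float:
    """Background-corrected dim/bright brightness ratio of one trace.

    ``f = (mean_dim - mean_bg) / (mean_bright - mean_bg)``.  Values
    slightly outside [0, 1] (within ±0.1) are clipped with a logged
    anomaly; larger excursions are returned unclipped so callers can
    exclude them.
    """
    mb, m1, m2 = dec.background.mean, dec.dim.mean, dec.bright.mean
    if m2 <= mb:
        raise ValueError("bright-state mean must exceed the background mean")
    f = (m1 - mb) / (m2 - mb)
    if 0.0 <= f <= 1.0:
        return f
    if -F_EXCLUSION_MARGIN <= f <= 1.0 + F_EXCLUSION_MARGIN:
        clipped = min(max(f, 0.0), 1.0)
        logger.warning("per-trace f = %.4f outside [0,1]; clipped to %.1f", f, clipped)
        return clipped
    logger.warning("per-trace f = %.4f far outside [0,1]; caller should exclude it", f)
    return f


@dataclass(frozen=True)
class AggregateQY:
    """Mean and spread of the per-trace relative quantum yields."""

    f_mean: float
    f_sd: float
    n_traces: int
    n_excluded: int = 0

    def summary(self) -> str:
        return (
            f"single-molecule f_PQ = {self.f_mean:.3f} +/- {self.f_sd:.3f} "
            f"(n = {self.n_traces} traces, {self.n_excluded} excluded)"
        )


def aggregate_traces(f_list) -> AggregateQY:
    """Arithmetic mean and sample standard deviation over traces."""
    f = np.asarray(list(f_list), dtype=float)
    if f.size == 0:
        raise ValueError("cannot aggregate an empty list of per-trace values")
    bad = (f < -F_EXCLUSION_MARGIN) | (f > 1.0 + F_EXCLUSION_MARGIN)
    if np.any(bad):
        logger.warning("aggregate_traces: excluding %d value(s) far outside [0,1]", bad.sum())
        f = f[~bad]
        if f.size == 0:
            raise ValueError("all per-trace values excluded as anomalous")
    sd = float(np.std(f, ddof=1)) if f.size > 1 else 0.0
    return AggregateQY(
        f_mean=float(np.mean(f)), f_sd=sd, n_traces=int(f.size), n_excluded=int(bad.sum())
    )


class BlinkingTraceModel:
    """Histogram decomposition model for one photon-count trace.

    ``fit()`` accumulates the intensity histogram, fits the
    three-Gaussian mixture and, when the decomposition is clean,
    estimates the dim-state relative quantum yield.
    """

    def __init__(self, trace: PhotonTrace, nbins: int | str = "auto"):
        self.trace = trace
        self.nbins = nbins

    def fit(self) -> "BlinkingTraceResults":
        hist = accumulate_histogram(self.trace, nbins=self.nbins)
        dec = fit_three_gaussians(hist)
        f = None
        if not dec.degenerate and dec.bright.mean > dec.background.mean:
            raw = (dec.dim.mean - dec.background.mean) / (dec.bright.mean - dec.background.mean)
            if -F_EXCLUSION_MARGIN <= raw <= 1.0 + F_EXCLUSION_MARGIN:
                f = min(max(raw, 0.0), 1.0)
        return BlinkingTraceResults(trace=self.trace, hist=hist, decomposition=dec, f=f)


@dataclass(frozen=True)
class BlinkingTraceResults:
    trace: PhotonTrace
    hist: CountHistogram
    decomposition: HistogramDecomposition
    f: float | None  # None when the trace is excluded (flagged fit or wild f)

    @property
    def excluded(self) -> bool:
        return self.f is None

    def summary(self) -> str:
        d = self.decomposition
        lines = [
            f"Blinking trace {self.trace.molecule_id or ''}".rstrip(),
            "=" * 40,
            f"{'bins':<14}{self.trace.counts.size}  ({self.trace.bin_width*1e3:g} ms each)",
            f"{'background':<14}mean {d.background.mean:7.2f}  sigma {d.background.sigma:6.2f}",
            f"{'dim state':<14}mean {d.dim.mean:7.2f}  sigma {d.dim.sigma:6.2f}",
            f"{'bright state':<14}mean {d.bright.mean:7.2f}  sigma {d.bright.sigma:6.2f}",
        ]
        if self.f is not None:
            lines.append(f"{'f (dim/bright)':<14}{self.f:.4f}")
        else:
            lines.append(f"EXCLUDED: {', '.join(d.flags) or 'f outside [0,1]'}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(self.hist.centers, self.hist.occupancy, width=1.0, alpha=0.5, label="histogram")
        grid = np.linspace(self.hist.centers.min(), self.hist.centers.max(), 400)
        theta = np.array([
            self.decomposition.background.mean,
            self.decomposition.dim.mean - self.decomposition.background.mean,
            self.decomposition.bright.mean - self.decomposition.dim.mean,
            *(c.sigma for c in self.decomposition.components),
            *(c.amplitude for c in self.decomposition.components),
        ])
        ax.plot(grid, _triple_gauss(grid, theta), "r-", label="3-Gaussian fit")
        ax.set_xlabel("counts per bin")
        ax.set_ylabel("occupancy")
        ax.legend()
        return ax


def analyze_experiment(traces, nbins: int | str = "auto") -> AggregateQY:
    """Run the full per-trace pipeline and aggregate the clean traces.

    Traces whose decomposition is flagged (merged or unsupported
    components — e.g. molecules that never bleached, so no background
    level exists) or whose f falls outside [0, 1] by more than 0.1 are
    excluded from the aggregate, with the exclusions counted.
    """
    f_values: list[float] = []
    n_excluded = 0
    for trace in traces:
        try:
            res = BlinkingTraceModel(trace, nbins=nbins).fit()
        except ValueError as exc:
            logger.warning("trace %s excluded: %s", trace.molecule_id, exc)
            n_excluded += 1
            continue
        if res.excluded:
            n_excluded += 1
        else:
            f_values.append(res.f)
    if not f_values:
        raise ValueError("no trace survived quality screening; nothing to aggregate")
    agg = aggregate_traces(f_values)
    return AggregateQY(
        f_mean=agg.f_mean, f_sd=agg.f_sd, n_traces=agg.n_traces,
        n_excluded=n_excluded + agg.n_excluded,
    )
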