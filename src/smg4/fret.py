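"""FRET efficiency analysis: leakage correction, histograms, comparisons.

Apparent FRET efficiency per frame is the acceptor fraction of total
intensity after subtracting donor bleed-through into the acceptor channel:

    A' = A - leakage * D        E = A' / (A' + D)

Population histograms are built from per-molecule mean efficiencies at a
fixed 0.01 bin width on [0, 1] and fitted with a double Gaussian; two
conditions are compared by the shift in fitted component means and a
two-sample Kolmogorov–Smirnov test on the per-molecule means.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .trajectory import FretTrace

BIN_WIDTH = 0.01


@dataclass
class EfficiencyResult:
    """Per-frame efficiencies for one molecule after leakage correction."""

    efficiencies: np.ndarray
    n_excluded: int  # frames with non-positive total intensity
    n_clamped: int  # frames clamped into [0, 1]

    @property
    def mean(self) -> float:
        return float(self.efficiencies.mean())


@dataclass
class GaussianComponent:
    mean: float
    sd: float
    amplitude: float
    mean_se: float = float("nan")
    sd_se: float = float("nan")
    amplitude_se: float = float("nan")


@dataclass
class FretHistogram:
    """Binned per-molecule FRET efficiencies with a double-Gaussian fit."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_molecules: int
    molecule_means: np.ndarray
    components: list[GaussianComponent] = field(default_factory=list)
    fit_converged: bool = False
    single_gaussian_fallback: bool = False
    leakage: float = 0.0
    frac_out_of_range: float = 0.0

    @property
    def weights(self) -> np.ndarray:
        """Component weights from amplitude * sd (Gaussian area), normalized."""
        areas = np.array([c.amplitude * c.sd for c in self.components])
        return areas / areas.sum() if areas.size else areas


def fret_efficiency(trace: FretTrace, leakage: float = 0.10) -> EfficiencyResult:
    """Leakage-corrected FRET efficiency per frame, clamped to [0, 1].

    Frames whose corrected total intensity A' + D is non-positive carry no
    usable signal and are excluded (their count is reported).
    """
    if not 0 <= leakage < 0.5:
        raise ValueError("leakage must be in [0, 0.5)")
    d, a = trace.donor, trace.acceptor
    if np.all(d == 0) and np.all(a == 0):
        raise ValueError(f"all-zero trace {trace.molecule_id}")
    a_corr = a - leakage * d
    total = a_corr + d
    valid = total > 0
    e_raw = a_corr[valid] / total[valid]
    e = np.clip(e_raw, 0.0, 1.0)
    return EfficiencyResult(
        efficiencies=e,
        n_excluded=int((~valid).sum()),
        n_clamped=int(np.sum((e_raw < 0) | (e_raw > 1))),
    )


def _binned_gaussians(edges: np.ndarray, *params: float) -> np.ndarray:
    """Expected counts per bin for a sum of Gaussians.

    ``params`` are (area, mean, sd) triples; the model integrates each
    Gaussian over the bins (CDF differences), which stays well conditioned
    even when a population is narrower than one bin.
    """
    out = np.zeros(edges.size - 1)
    for area, m, s in zip(params[0::3], params[1::3], params[2::3]):
        cdf = stats.norm.cdf(edges, loc=m, scale=s)
        out = out + area * np.diff(cdf)
    return out


def build_histogram(
    traces: list[FretTrace],
    leakage: float = 0.10,
    per_molecule: bool = True,
    fit: bool = True,
) -> FretHistogram:
    """Pool efficiencies, bin at 0.01 on [0, 1] and fit a double Gaussian.

    The histogram unit is the per-molecule mean efficiency (``per_molecule``
    False pools frames instead). Weights are constrained non-negative; if
    the two-component fit fails, a single-Gaussian fallback is fitted and
    flagged.
    """
    if not traces:
        raise ValueError("no FRET traces given")
    values, n_clamped, n_frames = [], 0, 0
    for trace in traces:
        res = fret_efficiency(trace, leakage)
        n_clamped += res.n_clamped
        n_frames += res.efficiencies.size
        if per_molecule:
            values.append(res.mean)
        else:
            values.extend(res.efficiencies)
    values = np.asarray(values)

    edges = np.round(np.arange(0, 1 + BIN_WIDTH / 2, BIN_WIDTH), 10)
    counts, _ = np.histogram(np.clip(values, 0, 1 - 1e-12), bins=edges)

    hist = FretHistogram(
        bin_edges=edges,
        counts=counts.astype(float),
        n_molecules=len(traces),
        molecule_means=values,
        leakage=leakage,
        frac_out_of_range=n_clamped / max(n_frames, 1),
    )
    if fit:
        _fit_components(hist)
    return hist


def _fit_components(hist: FretHistogram) -> None:
    edges = hist.bin_edges
    counts = hist.counts
    vals = hist.molecule_means
    total = float(counts.sum())
    s_min = BIN_WIDTH / 4  # below ~a quarter bin the width is unidentifiable

    # seed the two components from the halves on either side of the midpoint
    mid = 0.5 * (vals.min() + vals.max())
    left, right = vals[vals <= mid], vals[vals > mid]
    if left.size == 0 or right.size == 0:
        lo, hi = np.quantile(vals, [0.25, 0.75])
        a_lo = a_hi = total / 2
        s_lo = s_hi = max(vals.std(), BIN_WIDTH)
    else:
        lo, hi = left.mean(), right.mean()
        a_lo, a_hi = float(left.size), float(right.size)
        s_lo = max(left.std(), s_min)
        s_hi = max(right.std(), s_min)

    def _fit(p0, lo_b, hi_b, k):
        popt, pcov = optimize.curve_fit(
            lambda _x, *p: _binned_gaussians(edges, *p),
            np.zeros(counts.size), counts, p0=p0, bounds=(lo_b, hi_b),
            maxfev=20000,
        )
        perr = np.sqrt(np.diag(pcov))
        comps = []
        for i in range(k):
            area, m, s = popt[3 * i], popt[3 * i + 1], popt[3 * i + 2]
            peak = area / (s * np.sqrt(2 * np.pi))
            comps.append(
                GaussianComponent(
                    mean=m, sd=s, amplitude=peak,
                    mean_se=perr[3 * i + 1], sd_se=perr[3 * i + 2],
                    amplitude_se=perr[3 * i] / (s * np.sqrt(2 * np.pi)),
                )
            )
        comps.sort(key=lambda c: c.mean)
        return comps

    try:
        hist.components = _fit(
            [a_lo, lo, s_lo, a_hi, hi, s_hi],
            [0, 0, s_min, 0, 0, s_min],
            [np.inf, 1, 1, np.inf, 1, 1],
            2,
        )
        hist.fit_converged = True
        return
    except (RuntimeError, ValueError):
        pass
    try:
        hist.components = _fit(
            [total, float(np.mean(vals)), max(vals.std(), s_min)],
            [0, 0, s_min], [np.inf, 1, 1], 1,
        )
        hist.fit_converged = True
        hist.single_gaussian_fallback = True
    except (RuntimeError, ValueError):
        hist.components = []
        hist.fit_converged = False


@dataclass
class ShiftReport:
    """Comparison of two FRET populations (e.g. +/- protein)."""

    delta_means: np.ndarray
    delta_ses: np.ndarray
    ks_statistic: float
    ks_p: float
    changed: bool
    delta_threshold: float
    ks_alpha: float

    @property
    def no_change(self) -> bool:
        return not self.changed


def compare_conditions(
    hist_a: FretHistogram,
    hist_b: FretHistogram,
    delta_threshold: float = 0.05,
    ks_alpha: float = 0.01,
) -> ShiftReport:
    """Test whether a FRET population shifted between two conditions.

    "No change" is declared when every matched fitted-component mean moved
    by less than ``delta_threshold`` *and* the two-sample KS test on
    per-molecule means is not significant at ``ks_alpha``.
    """
    if hist_a.bin_edges.shape != hist_b.bin_edges.shape or not np.allclose(
        hist_a.bin_edges, hist_b.bin_edges
    ):
        raise ValueError("histograms have mismatched binning")

    n = min(len(hist_a.components), len(hist_b.components))
    if n == 0:
        raise ValueError("both histograms need at least one fitted component")
    ca = sorted(hist_a.components, key=lambda c: c.mean)[:n]
    cb = sorted(hist_b.components, key=lambda c: c.mean)[:n]
    delta = np.array([b.mean - a.mean for a, b in zip(ca, cb)])
    delta_se = np.array(
        [np.hypot(a.mean_se, b.mean_se) for a, b in zip(ca, cb)]
    )

    ks = stats.ks_2samp(hist_a.molecule_means, hist_b.molecule_means)
    changed = bool(np.any(np.abs(delta) >= delta_threshold) or ks.pvalue <= ks_alpha)
    return ShiftReport(
        delta_means=delta,
        delta_ses=delta_se,
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        changed=changed,
        delta_threshold=delta_threshold,
        ks_alpha=ks_alpha,
    )
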