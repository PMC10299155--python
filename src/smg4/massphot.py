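"""Mass photometry: contrast calibration, mass histograms, stoichiometry.

An interferometric-scattering mass photometer reports a contrast per
landing (positive) or departure (negative) event; a linear calibration
against protein standards maps contrast to mass. Event masses are binned
into 3 kDa intervals and the histogram fitted with a sum of Gaussians;
fitted component means are interpreted as integer protein/DNA
stoichiometries by a bounded search.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

BIN_WIDTH_KDA = 3.0

#: Masses (kDa) of the conventional calibration standards:
#: beta-amylase monomer/dimer/tetramer and thyroglobulin.
CALIBRATION_STANDARD_MASSES = (56.0, 112.0, 224.0, 670.0)


@dataclass
class Calibration:
    """Linear contrast -> mass (kDa) map from >= 2 standards."""

    slope: float
    intercept: float
    standards: list[tuple[float, float]]
    residuals_kDa: np.ndarray
    r_squared: float

    def to_mass(self, contrast) -> np.ndarray:
        return self.slope * np.asarray(contrast, dtype=float) + self.intercept


def calibrate(standards: list[tuple[float, float]]) -> Calibration:
    """Ordinary least-squares line through (contrast, mass_kDa) standards.

    Requires >= 2 distinct contrasts and a strictly monotonic
    contrast-mass relation (the optical contrast is proportional to mass).
    """
    if len(standards) < 2:
        raise ValueError("need at least 2 calibration standards")
    contrast = np.array([c for c, _ in standards], dtype=float)
    mass = np.array([m for _, m in standards], dtype=float)
    if np.unique(contrast).size != contrast.size:
        raise ValueError("duplicate contrast values in standards")
    order = np.argsort(contrast)
    diffs = np.diff(mass[order])
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("contrast-mass relation is not monotonic")

    res = stats.linregress(contrast, mass)
    fitted = res.slope * contrast + res.intercept
    return Calibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        standards=list(standards),
        residuals_kDa=mass - fitted,
        r_squared=float(res.rvalue**2),
    )


@dataclass
class MassComponent:
    mean_kDa: float
    sd_kDa: float
    amplitude: float
    mean_se: float = float("nan")
    sd_se: float = float("nan")
    amplitude_se: float = float("nan")

    @property
    def area(self) -> float:
        return self.amplitude * self.sd_kDa * np.sqrt(2 * np.pi)


@dataclass
class MassHistogram:
    """3 kDa-binned mass events with fitted Gaussian components."""

    bin_edges: np.ndarray
    counts: np.ndarray
    components: list[MassComponent]
    sign: str
    n_events: int
    n_components_tried: int
    bic: float | None = None

    @property
    def weights(self) -> np.ndarray:
        areas = np.array([c.area for c in self.components])
        return areas / areas.sum() if areas.size else areas


def _multi_gaussian(x: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(x)
    for a, m, s in zip(params[0::3], params[1::3], params[2::3]):
        out = out + a * np.exp(-((x - m) ** 2) / (2 * s**2))
    return out


def _lsq_bic(counts: np.ndarray, fitted: np.ndarray, n_params: int) -> float:
    n = counts.size
    rss = float(np.sum((counts - fitted) ** 2))
    return n * np.log(max(rss, 1e-300) / n) + n_params * np.log(n)


def _fit_n_gaussians(centers, counts, k, sd0):
    # seed component means at the k tallest well-separated bins
    order = np.argsort(counts)[::-1]
    seeds: list[float] = []
    for idx in order:
        if len(seeds) >= k:
            break
        if all(abs(centers[idx] - s) > 2 * BIN_WIDTH_KDA for s in seeds):
            seeds.append(centers[idx])
    while len(seeds) < k:
        seeds.append(centers[np.argmax(counts)] * (1 + 0.5 * len(seeds)))

    p0, lo, hi = [], [], []
    for m in sorted(seeds):
        p0 += [counts.max(), m, sd0]
        lo += [0.0, centers.min() - BIN_WIDTH_KDA, BIN_WIDTH_KDA / 4]
        hi += [np.inf, centers.max() + BIN_WIDTH_KDA, np.ptp(centers) + BIN_WIDTH_KDA]
    popt, pcov = optimize.curve_fit(
        _multi_gaussian, centers, counts, p0=p0, bounds=(lo, hi), maxfev=40000
    )
    perr = np.sqrt(np.diag(pcov))
    comps = [
        MassComponent(popt[3 * i + 1], popt[3 * i + 2], popt[3 * i],
                      perr[3 * i + 1], perr[3 * i + 2], perr[3 * i])
        for i in range(k)
    ]
    comps.sort(key=lambda c: c.mean_kDa)
    bic = _lsq_bic(counts, _multi_gaussian(centers, *popt), 3 * k)
    return comps, bic


def fit_mass_histogram(
    events,
    n_components: int = 1,
    sign: str = "positive",
    choose_by_bic: bool = False,
    min_events: int = 50,
) -> MassHistogram:
    """Bin events at 3 kDa and fit a sum of Gaussians by least squares.

    ``sign`` selects landing ("positive"), departure ("negative") or all
    ("both") events. With ``choose_by_bic`` the component count is swept
    over 1..n_components and the best BIC kept; otherwise it is fixed.
    """
    events = np.asarray(events, dtype=float)
    if sign == "positive":
        sel = events[events > 0]
    elif sign == "negative":
        sel = events[events < 0]
    elif sign == "both":
        sel = events
    else:
        raise ValueError("sign must be 'positive', 'negative' or 'both'")
    if sel.size < min_events:
        raise ValueError(f"need at least {min_events} events of sign {sign!r}")

    lo = np.floor(sel.min() / BIN_WIDTH_KDA) * BIN_WIDTH_KDA
    hi = np.ceil(sel.max() / BIN_WIDTH_KDA) * BIN_WIDTH_KDA
    edges = np.arange(lo, hi + BIN_WIDTH_KDA / 2, BIN_WIDTH_KDA)
    counts, _ = np.histogram(sel, bins=edges)
    counts = counts.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])

    sd0 = max(sel.std() / max(n_components, 1), BIN_WIDTH_KDA / 2)
    candidates = range(1, n_components + 1) if choose_by_bic else [n_components]
    best: tuple[list[MassComponent], float] | None = None
    last_err: Exception | None = None
    for k in candidates:
        try:
            comps, bic = _fit_n_gaussians(centers, counts, k, sd0)
        except (RuntimeError, ValueError) as err:
            last_err = err
            continue
        if best is None or bic < best[1]:
            best = (comps, bic)
    if best is None:
        raise RuntimeError(f"multi-Gaussian fit failed to converge: {last_err}")

    return MassHistogram(
        bin_edges=edges,
        counts=counts,
        components=best[0],
        sign=sign,
        n_events=int(sel.size),
        n_components_tried=n_components,
        bic=best[1],
    )


@dataclass
class StoichiometryAssignment:
    component_mean_kDa: float
    counts: dict[str, int]
    combination_mass_kDa: float
    residual_kDa: float
    assigned: bool

    def __str__(self) -> str:
        if not self.assigned:
            return f"{self.component_mean_kDa:.1f} kDa: unassigned"
        combo = " + ".join(f"{n}x{s}" for s, n in self.counts.items() if n > 0)
        return f"{self.component_mean_kDa:.1f} kDa = {combo} ({self.combination_mass_kDa:.1f} kDa)"


def assign_stoichiometry(
    component_means,
    monomer_masses: list[tuple[str, float]],
    tolerance_kDa: float = 4.0,
    max_counts: tuple[int, ...] | None = None,
) -> list[StoichiometryAssignment]:
    """Match fitted masses to integer combinations of monomer masses.

    Each component mean is matched to the combination ``sum_i a_i * m_i``
    (``a_i >= 0``, bounded) with the smallest absolute residual; components
    farther than ``tolerance_kDa`` from every combination are reported
    unassigned — a valid outcome, not an error. Default bounds: 6 copies of
    the first species (protein), 4 of each further species (DNA).
    """
    names = [n for n, _ in monomer_masses]
    masses = np.array([m for _, m in monomer_masses], dtype=float)
    if np.any(masses <= 0):
        raise ValueError("monomer masses must be positive")
    if max_counts is None:
        max_counts = (6,) + (4,) * (len(masses) - 1)

    combos = []
    for counts in itertools.product(*(range(c + 1) for c in max_counts)):
        if sum(counts) == 0:
            continue
        combos.append((counts, float(np.dot(counts, masses))))

    out = []
    for mean in np.atleast_1d(np.asarray(component_means, dtype=float)):
        counts, combo_mass = min(combos, key=lambda cm: abs(cm[1] - mean))
        resid = mean - combo_mass
        ok = abs(resid) <= tolerance_kDa
        out.append(
            StoichiometryAssignment(
                component_mean_kDa=float(mean),
                counts=dict(zip(names, counts)) if ok else {},
                combination_mass_kDa=combo_mass if ok else float("nan"),
                residual_kDa=float(resid) if ok else float("nan"),
                assigned=ok,
            )
        )
    return out
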