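"""Dwell-time extraction and exponential fitting.

Dwells are maximal runs of constant state in the idealized trajectories.
The first and last run of every molecule are censored by the observation
window (their true duration is unknown) and are excluded from fits by
default.

Rates are estimated two ways:

* ``mle`` — maximum likelihood for an exponential (or two-component
  mixture), with left truncation at one frame interval: dwells shorter
  than a frame are invisible at 100 ms resolution, and ignoring that
  truncation biases rates low. For a single component the truncated MLE
  has the closed form ``rate = 1 / (mean - t_min)``.
* ``histogram_lsq`` — the conventional binned-histogram least-squares fit
  of ``A * exp(-k t)`` (the GraphPad-style procedure), kept for
  comparability.

Model order (one vs two exponential phases) is chosen by a likelihood-ratio
test for the MLE route and by the extra-sum-of-squares F-test for the
histogram route.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .hmm import IdealizedTrajectory


@dataclass
class DwellTable:
    """State-resolved dwell durations pooled over molecules.

    ``table`` columns: molecule_id, state, duration_s, censored_left,
    censored_right. Durations are positive integer multiples of the frame
    interval and, per molecule, tile the analysis segment exactly.
    """

    table: pd.DataFrame
    frame_interval: float

    def durations(self, state: int, include_censored: bool = False) -> np.ndarray:
        df = self.table[self.table["state"] == state]
        if not include_censored:
            df = df[~(df["censored_left"] | df["censored_right"])]
        return df["duration_s"].to_numpy()

    def n_dwells(self, state: int | None = None) -> int:
        if state is None:
            return len(self.table)
        return int((self.table["state"] == state).sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_interval: float) -> "DwellTable":
        return cls(pd.read_csv(path), frame_interval)


@dataclass
class ExpFit:
    """Exponential (mixture) fit of a dwell-time distribution."""

    n_components: int
    rates: np.ndarray
    weights: np.ndarray
    rate_se: np.ndarray
    method: str
    n_dwells: int
    log_likelihood: float | None = None
    rss: float | None = None
    n_bins: int | None = None
    f_test_p: float | None = None
    t_min: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.rate_se = np.atleast_1d(np.asarray(self.rate_se, dtype=float))
        if np.any(self.rates <= 0):
            raise ValueError("fitted rates must be positive")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")

    @property
    def rate(self) -> float:
        """Headline rate: the dominant component."""
        return float(self.rates[np.argmax(self.weights)])

    @property
    def se(self) -> float:
        return float(self.rate_se[np.argmax(self.weights)])

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "rates_per_s": self.rates.tolist(),
            "weights": self.weights.tolist(),
            "rate_se_per_s": self.rate_se.tolist(),
            "method": self.method,
            "n_dwells": self.n_dwells,
            "log_likelihood": self.log_likelihood,
            "rss": self.rss,
            "f_test_p": self.f_test_p,
            "t_min_s": self.t_min,
        }


def extract_dwells(ideals: list[IdealizedTrajectory]) -> DwellTable:
    """Convert idealized state paths into a pooled dwell table.

    Every maximal run of constant state becomes one dwell; the first and
    last run per molecule carry censoring flags. All dwells (censored
    included) are recorded so that they tile each analysis segment exactly;
    fits exclude censored dwells unless asked otherwise.
    """
    if not ideals:
        raise ValueError("no idealized trajectories given")
    rows = []
    dt = ideals[0].frame_interval
    for ideal in ideals:
        path = ideal.state_path
        if path.size == 0:
            raise ValueError(f"empty idealized path for {ideal.molecule_id}")
        boundaries = np.flatnonzero(np.diff(path)) + 1
        starts = np.concatenate([[0], boundaries])
        stops = np.concatenate([boundaries, [path.size]])
        n_runs = starts.size
        for i, (a, b) in enumerate(zip(starts, stops)):
            rows.append(
                {
                    "molecule_id": ideal.molecule_id,
                    "state": int(path[a]),
                    "duration_s": (b - a) * ideal.frame_interval,
                    "censored_left": i == 0,
                    "censored_right": i == n_runs - 1,
                }
            )
    return DwellTable(pd.DataFrame(rows), dt)


# ---------------------------------------------------------------------------
# Maximum likelihood, left-truncated at t_min
# ---------------------------------------------------------------------------

def _exp_loglik(dwells: np.ndarray, rate: float, t_min: float) -> float:
    # f(t | T >= t_min) = rate * exp(-rate (t - t_min))
    return dwells.size * np.log(rate) - rate * np.sum(dwells - t_min)


def _mixture_nll(theta: np.ndarray, dwells: np.ndarray, t_min: float) -> float:
    """Negative log-likelihood of a 2-component truncated exponential mixture.

    theta = (log r1, log r2, logit w1).
    """
    r1, r2 = np.exp(theta[0]), np.exp(theta[1])
    w1 = np.clip(1.0 / (1.0 + np.exp(-theta[2])), 1e-12, 1 - 1e-12)
    # density / survival at t_min, in a numerically safe form
    log_f = np.logaddexp(
        np.log(w1) + np.log(r1) - r1 * dwells,
        np.log1p(-w1) + np.log(r2) - r2 * dwells,
    )
    log_surv = np.logaddexp(
        np.log(w1) - r1 * t_min, np.log1p(-w1) - r2 * t_min
    )
    return -(np.sum(log_f) - dwells.size * log_surv)


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def _fit_mle(dwells: np.ndarray, n_components: int, t_min: float) -> ExpFit:
    if np.any(dwells < t_min - 1e-12):
        raise ValueError("dwells shorter than the truncation point t_min")
    if n_components == 1:
        mean = dwells.mean()
        if mean <= t_min:
            raise ValueError("mean dwell <= t_min; cannot fit truncated exponential")
        rate = 1.0 / (mean - t_min)
        se = rate / np.sqrt(dwells.size)
        return ExpFit(
            n_components=1,
            rates=[rate],
            weights=[1.0],
            rate_se=[se],
            method="mle",
            n_dwells=dwells.size,
            log_likelihood=_exp_loglik(dwells, rate, t_min),
            t_min=t_min,
        )

    # 2-component mixture: quasi-Newton from a spread of starts
    r0 = 1.0 / max(dwells.mean() - t_min, 1e-9)
    starts = [
        np.array([np.log(r0 * a), np.log(r0 / a), logit_w])
        for a in (3.0, 8.0)
        for logit_w in (-1.0, 0.0, 1.0)
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _mixture_nll, x0, args=(dwells, t_min), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("2-component MLE failed to converge")

    theta = best.x
    rates = np.exp(theta[:2])
    w1 = 1.0 / (1.0 + np.exp(-theta[2]))
    weights = np.array([w1, 1.0 - w1])

    H = _numeric_hessian(lambda th: _mixture_nll(th, dwells, t_min), theta)
    try:
        cov_theta = np.linalg.inv(H)
        # delta method: d(rate)/d(log rate) = rate
        rate_se = np.sqrt(np.clip(np.diag(cov_theta)[:2], 0, None)) * rates
        w_se = float(
            np.sqrt(max(cov_theta[2, 2], 0.0)) * w1 * (1 - w1)
        )
    except np.linalg.LinAlgError:
        rate_se = np.full(2, np.nan)
        w_se = float("nan")

    order = np.argsort(rates)
    return ExpFit(
        n_components=2,
        rates=rates[order],
        weights=weights[order],
        rate_se=rate_se[order],
        method="mle",
        n_dwells=dwells.size,
        log_likelihood=float(-best.fun),
        t_min=t_min,
        extra={"weight_se": w_se},
    )


# ---------------------------------------------------------------------------
# Histogram least squares (GraphPad-style)
# ---------------------------------------------------------------------------

def _histogram(dwells: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    upper = np.quantile(dwells, 0.95)
    n_bins = max(int(np.ceil(upper / bin_width)), 4)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(dwells, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts.astype(float)


def _fit_histogram(
    dwells: np.ndarray, n_components: int, bin_width: float
) -> ExpFit:
    centers, counts = _histogram(dwells, bin_width)
    r0 = 1.0 / dwells.mean()
    a0 = counts.max()

    if n_components == 1:
        def model(t, a, k):
            return a * np.exp(-k * t)
        p0, bounds = [a0, r0], ([0, 1e-12], [np.inf, np.inf])
    else:
        def model(t, a1, k1, a2, k2):
            return a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)
        p0 = [a0 * 0.7, r0 * 0.5, a0 * 0.3, r0 * 3.0]
        bounds = ([0, 1e-12, 0, 1e-12], [np.inf] * 4)

    popt, pcov = optimize.curve_fit(
        model, centers, counts, p0=p0, bounds=bounds, maxfev=20000
    )
    perr = np.sqrt(np.diag(pcov))
    rss = float(np.sum((counts - model(centers, *popt)) ** 2))

    if n_components == 1:
        rates, rate_se, weights = popt[1:2], perr[1:2], np.array([1.0])
    else:
        a = popt[[0, 2]]
        rates = popt[[1, 3]]
        rate_se = perr[[1, 3]]
        areas = a / rates  # integral of each phase
        weights = areas / areas.sum()
        order = np.argsort(rates)
        rates, rate_se, weights = rates[order], rate_se[order], weights[order]

    return ExpFit(
        n_components=n_components,
        rates=rates,
        weights=weights,
        rate_se=rate_se,
        method="histogram_lsq",
        n_dwells=dwells.size,
        rss=rss,
        n_bins=centers.size,
        t_min=0.0,
        extra={"bin_width": bin_width},
    )


def fit_exponential(
    dwells,
    n_components: int = 1,
    method: str = "mle",
    bin_width: float | None = None,
    t_min: float = 0.0,
    min_dwells: int = 10,
) -> ExpFit:
    """Fit a one- or two-phase exponential to pooled dwell durations.

    Parameters
    ----------
    dwells : array-like
        Dwell durations in seconds (uncensored).
    n_components : {1, 2}
    method : {"mle", "histogram_lsq"}
        ``mle`` supports left truncation at ``t_min`` (typically one frame
        interval); ``histogram_lsq`` is the binned least-squares procedure.
    bin_width : float, optional
        Histogram bin width (s); defaults to ``t_min`` if positive else the
        smallest dwell. Ignored for MLE.
    t_min : float
        Left-truncation point in seconds (0 disables truncation, in which
        case the single-component MLE reduces to 1/mean exactly).
    min_dwells : int
        Fits on fewer dwells are refused.
    """
    dwells = np.asarray(dwells, dtype=float)
    if dwells.size < min_dwells:
        raise ValueError(f"need at least {min_dwells} dwells, got {dwells.size}")
    if np.any(dwells <= 0):
        raise ValueError("dwell durations must be positive")
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")

    if method == "mle":
        return _fit_mle(dwells, n_components, t_min)
    if method == "histogram_lsq":
        if bin_width is None:
            bin_width = t_min if t_min > 0 else float(dwells.min())
        return _fit_histogram(dwells, n_components, bin_width)
    raise ValueError(f"unknown method {method!r}")


def choose_components(
    dwells,
    alpha: float = 0.05,
    method: str = "mle",
    **fit_kwargs,
) -> ExpFit:
    """Fit 1- and 2-phase models and pick one by a significance test.

    MLE route: likelihood-ratio test, 2*(ll2 - ll1) ~ chi2 with 2 df.
    Histogram route: extra-sum-of-squares F-test, as in the conventional
    Prism analysis. The preferred fit is returned with the test p-value
    attached; 2 phases are kept only when p < alpha.
    """
    fit1 = fit_exponential(dwells, 1, method=method, **fit_kwargs)
    try:
        fit2 = fit_exponential(dwells, 2, method=method, **fit_kwargs)
    except (RuntimeError, ValueError):
        fit1.f_test_p = None
        return fit1

    if method == "mle":
        lr = 2.0 * (fit2.log_likelihood - fit1.log_likelihood)
        p = float(stats.chi2.sf(max(lr, 0.0), df=2))
    else:
        df1 = fit1.n_bins - 2
        df2 = fit2.n_bins - 4
        if df2 <= 0 or fit2.rss <= 0:
            p = 1.0
        else:
            f_stat = ((fit1.rss - fit2.rss) / (df1 - df2)) / (fit2.rss / df2)
            p = float(stats.f.sf(max(f_stat, 0.0), df1 - df2, df2))

    chosen = fit2 if p < alpha else fit1
    chosen.f_test_p = p
    return chosen
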