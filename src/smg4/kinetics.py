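"""Headline binding kinetics: v+1, k_on, k_off, tau and Kd.

For a two-state binding model the unbound-dwell distribution gives the
observed association rate v+1 (events/s at one protein concentration) and
the bound-dwell distribution gives the concentration-independent
dissociation rate k_off. The association rate constant corrects for the
effective fluorescent protein concentration::

    k_on = v+1 / ([P] * labeling_efficiency)

and the equilibrium dissociation constant and mean bound lifetime follow
exactly from the rate constants::

    Kd = k_off / k_on          tau = 1 / k_off

Standard errors propagate by first-order (delta-method) rules; relative
SEs add in quadrature for the ratio.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .dwell import ExpFit


@dataclass
class ExperimentCondition:
    """One protein-DNA pair at one nominal protein concentration."""

    protein: str
    dna: str
    nominal_concentration: float  # molar
    labeling_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.nominal_concentration <= 0:
            raise ValueError("concentration must be positive")
        if not 0 < self.labeling_efficiency <= 1:
            raise ValueError("labeling_efficiency must be in (0, 1]")


class KoffResult(NamedTuple):
    k_off: float  # 1/s
    k_off_se: float
    tau: float  # s
    tau_se: float


class KonResult(NamedTuple):
    k_on: float  # 1/(M s)
    k_on_se: float


class KdResult(NamedTuple):
    kd: float  # molar
    kd_se: float


def compute_koff(bound_fit: ExpFit, allow_multicomponent: bool = False) -> KoffResult:
    """Dissociation rate and mean bound-state lifetime from the bound fit.

    tau = 1/k_off exactly; SE_tau = SE_k / k^2 (delta method). A
    two-component bound fit means the single-k_off summary is ill-defined;
    it is rejected unless ``allow_multicomponent`` explicitly asks for the
    dominant component.
    """
    if bound_fit.n_components != 1 and not allow_multicomponent:
        raise ValueError(
            "bound-state fit has 2 components; pass allow_multicomponent=True "
            "to report the dominant phase"
        )
    k = bound_fit.rate
    se = bound_fit.se
    return KoffResult(k, se, 1.0 / k, se / k**2)


def compute_kon(
    v_plus1: float, condition: ExperimentCondition, v_plus1_se: float = 0.0
) -> KonResult:
    """Association rate constant from the observed association rate.

    Divides v+1 by the *labeled* protein concentration — only the Cy3-
    carrying fraction of molecules produces a detectable binding event.
    """
    if v_plus1 <= 0:
        raise ValueError("v_plus1 must be positive")
    eff_conc = condition.nominal_concentration * condition.labeling_efficiency
    return KonResult(v_plus1 / eff_conc, v_plus1_se / eff_conc)


def compute_kd(
    k_off: float, k_on: float, k_off_se: float = 0.0, k_on_se: float = 0.0
) -> KdResult:
    """Kd = k_off / k_on with relative SEs added in quadrature."""
    if k_on <= 0:
        raise ValueError("k_on must be positive")
    if k_off < 0:
        raise ValueError("k_off must be non-negative")
    kd = k_off / k_on
    if k_off == 0:
        return KdResult(0.0, 0.0)
    rel = np.sqrt((k_off_se / k_off) ** 2 + (k_on_se / k_on) ** 2)
    return KdResult(kd, kd * rel)


@dataclass
class PerConcentration:
    """Dwell-fit summaries for one concentration of one condition."""

    condition: ExperimentCondition
    v_plus1: float
    v_plus1_se: float
    k_off: float
    k_off_se: float


@dataclass
class KineticResult:
    """Pooled kinetic parameters for one protein-DNA pair.

    ``tau = 1/k_off`` and ``kd = k_off/k_on`` hold exactly by construction.
    ``koff_slope_p`` is the p-value of a weighted regression of k_off on
    concentration — k_off must be concentration independent under the
    model, and a significant slope (p < 0.01) is flagged as a violation.
    """

    protein: str
    dna: str
    k_on: float
    k_on_se: float
    k_off: float
    k_off_se: float
    tau: float
    tau_se: float
    kd: float
    kd_se: float
    n_states_selected: int = 2
    per_concentration: pd.DataFrame | None = None
    koff_slope_p: float | None = None
    koff_concentration_dependent: bool = False
    v_plus1_monotonic: bool | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def kd_nM(self) -> float:
        return self.kd * 1e9

    def to_dict(self) -> dict:
        return {
            "protein": self.protein,
            "dna": self.dna,
            "k_on_per_M_s": self.k_on,
            "k_on_se_per_M_s": self.k_on_se,
            "k_off_per_s": self.k_off,
            "k_off_se_per_s": self.k_off_se,
            "tau_s": self.tau,
            "tau_se_s": self.tau_se,
            "kd_M": self.kd,
            "kd_se_M": self.kd_se,
            "kd_nM": self.kd_nM,
            "n_states_selected": self.n_states_selected,
            "koff_slope_p": self.koff_slope_p,
            "koff_concentration_dependent": self.koff_concentration_dependent,
            "v_plus1_monotonic": self.v_plus1_monotonic,
            "warnings": list(self.warnings),
        }


def _inverse_variance_pool(values: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    if np.any(ses <= 0):
        # unweighted fallback when any SE is degenerate
        return float(values.mean()), float(values.std(ddof=1) / np.sqrt(values.size))
    w = 1.0 / ses**2
    pooled = float(np.sum(w * values) / np.sum(w))
    return pooled, float(np.sqrt(1.0 / np.sum(w)))


def _weighted_slope_test(x: np.ndarray, y: np.ndarray, se: np.ndarray) -> float | None:
    """p-value for slope != 0 in a weighted least-squares line fit."""
    if x.size < 3:
        return None
    w = 1.0 / se**2 if np.all(se > 0) else np.ones_like(x)
    W = np.sum(w)
    xbar = np.sum(w * x) / W
    ybar = np.sum(w * y) / W
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx == 0:
        return None
    slope = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    resid = y - ybar - slope * (x - xbar)
    dof = x.size - 2
    s2 = np.sum(w * resid**2) / dof
    slope_se = np.sqrt(s2 / sxx)
    if slope_se == 0:
        return None
    t = slope / slope_se
    return float(2 * stats.t.sf(abs(t), dof))


def aggregate_concentration_series(
    per_conc: list[PerConcentration],
    n_states_selected: int = 2,
    slope_alpha: float = 0.01,
) -> KineticResult:
    """Pool per-concentration estimates into one kinetic result.

    k_on is computed at each concentration from its v+1 (labeling-adjusted)
    and pooled by inverse-variance weighting, as is k_off. Two model checks
    are reported: v+1 must increase with concentration (monotonicity
    warning otherwise) and k_off must not depend on concentration (weighted
    slope test; p < ``slope_alpha`` flags a model violation).
    """
    if not per_conc:
        raise ValueError("need at least one concentration")
    per_conc = sorted(per_conc, key=lambda p: p.condition.nominal_concentration)
    cond0 = per_conc[0].condition

    rows = []
    for p in per_conc:
        kon = compute_kon(p.v_plus1, p.condition, p.v_plus1_se)
        rows.append(
            {
                "concentration_M": p.condition.nominal_concentration,
                "labeling_efficiency": p.condition.labeling_efficiency,
                "v_plus1_per_s": p.v_plus1,
                "v_plus1_se_per_s": p.v_plus1_se,
                "k_on_per_M_s": kon.k_on,
                "k_on_se_per_M_s": kon.k_on_se,
                "k_off_per_s": p.k_off,
                "k_off_se_per_s": p.k_off_se,
            }
        )
    df = pd.DataFrame(rows)

    kon, kon_se = _inverse_variance_pool(
        df["k_on_per_M_s"].to_numpy(), df["k_on_se_per_M_s"].to_numpy()
    )
    koff, koff_se = _inverse_variance_pool(
        df["k_off_per_s"].to_numpy(), df["k_off_se_per_s"].to_numpy()
    )

    warnings = []
    conc = df["concentration_M"].to_numpy()
    v1 = df["v_plus1_per_s"].to_numpy()
    monotonic = bool(np.all(np.diff(v1) > 0)) if conc.size > 1 else None
    if monotonic is False:
        warnings.append("v+1 does not increase monotonically with concentration")

    slope_p = _weighted_slope_test(
        conc, df["k_off_per_s"].to_numpy(), df["k_off_se_per_s"].to_numpy()
    )
    concentration_dependent = slope_p is not None and slope_p < slope_alpha
    if concentration_dependent:
        warnings.append(
            f"k_off depends on concentration (p = {slope_p:.2e}): model violation"
        )

    koff_res = KoffResult(koff, koff_se, 1.0 / koff, koff_se / koff**2)
    kd = compute_kd(koff, kon, koff_se, kon_se)

    return KineticResult(
        protein=cond0.protein,
        dna=cond0.dna,
        k_on=kon,
        k_on_se=kon_se,
        k_off=koff,
        k_off_se=koff_se,
        tau=koff_res.tau,
        tau_se=koff_res.tau_se,
        kd=kd.kd,
        kd_se=kd.kd_se,
        n_states_selected=n_states_selected,
        per_concentration=df,
        koff_slope_p=slope_p,
        koff_concentration_dependent=concentration_dependent,
        v_plus1_monotonic=monotonic,
        warnings=warnings,
    )
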