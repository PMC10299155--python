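"""Equilibrium EMSA isotherm fitting and dye-labeling efficiency.

The fraction of DNA shifted into bound (and supershifted) species across a
protein titration is fitted with a binding isotherm

    f([P]) = [P]^n / (Kd^n + [P]^n)

with n fixed at 1 for the simple hyperbolic (one-site) model or free for a
Hill fit. Labeling efficiency of a Cy3-protein conjugate follows from
Beer–Lambert absorbances: C = A / (eps * l) per species, efficiency =
C_dye / C_protein, with an optional correction for dye absorbance at
280 nm.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize


@dataclass
class BindingIsotherm:
    """Fraction bound vs protein concentration (nM)."""

    concentrations: np.ndarray
    fraction_bound: np.ndarray
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.fraction_bound = np.asarray(self.fraction_bound, dtype=float)
        if self.concentrations.shape != self.fraction_bound.shape:
            raise ValueError("concentrations and fractions must align")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any((self.fraction_bound < 0) | (self.fraction_bound > 1)):
            raise ValueError("fraction bound must lie in [0, 1]")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "conc_nM": self.concentrations,
                "fraction_bound": self.fraction_bound,
                "replicate": self.replicates
                if self.replicates is not None
                else np.zeros(len(self.concentrations), dtype=int),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BindingIsotherm":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            df["conc_nM"].to_numpy(),
            df["fraction_bound"].to_numpy(),
            df["replicate"].to_numpy() if "replicate" in df else None,
        )


@dataclass
class IsothermFit:
    kd_nM: float
    kd_se_nM: float
    hill_n: float
    hill_n_se: float
    model: str
    extrapolated: bool
    rss: float

    def fraction_at(self, conc_nM) -> np.ndarray:
        c = np.asarray(conc_nM, dtype=float)
        return c**self.hill_n / (self.kd_nM**self.hill_n + c**self.hill_n)


def fit_isotherm(iso: BindingIsotherm, model: str = "hyperbolic") -> IsothermFit:
    """Nonlinear least-squares fit of the binding isotherm.

    A fitted Kd outside the titration range is flagged ``extrapolated``
    (the data do not bracket the transition).
    """
    conc, frac = iso.concentrations, iso.fraction_bound
    if np.unique(conc).size < 4:
        raise ValueError("need at least 4 distinct concentrations")

    kd0 = conc[np.argmin(np.abs(frac - 0.5))]
    if model == "hyperbolic":
        def f(c, kd):
            return c / (kd + c)
        popt, pcov = optimize.curve_fit(
            f, conc, frac, p0=[kd0], bounds=([1e-12], [np.inf]), maxfev=20000
        )
        kd, kd_se = popt[0], np.sqrt(pcov[0, 0])
        hill, hill_se = 1.0, 0.0
    elif model == "hill":
        def f(c, kd, n):
            return c**n / (kd**n + c**n)
        popt, pcov = optimize.curve_fit(
            f, conc, frac, p0=[kd0, 1.0],
            bounds=([1e-12, 0.2], [np.inf, 8.0]), maxfev=20000,
        )
        kd, hill = popt
        kd_se, hill_se = np.sqrt(np.diag(pcov))
    else:
        raise ValueError("model must be 'hyperbolic' or 'hill'")

    rss = float(np.sum((frac - f(conc, *popt)) ** 2))
    return IsothermFit(
        kd_nM=float(kd),
        kd_se_nM=float(kd_se),
        hill_n=float(hill),
        hill_n_se=float(hill_se),
        model=model,
        extrapolated=not (conc.min() <= kd <= conc.max()),
        rss=rss,
    )


@dataclass
class LabelingMeasurement:
    """Absorbance pair for determining dye:protein labeling ratio.

    ``dye_a280_factor`` is the fraction of the dye's 550 nm absorbance that
    the dye itself contributes at 280 nm (0 disables the correction; ~0.08
    is conventional for Cy3).
    """

    a280: float
    a550: float
    eps_protein: float  # 1/(M cm)
    eps_dye: float  # 1/(M cm)
    path_cm: float = 1.0
    dye_a280_factor: float = 0.0

    def __post_init__(self) -> None:
        if self.a280 < 0 or self.a550 < 0:
            raise ValueError("absorbances must be non-negative")
        if self.eps_protein <= 0 or self.eps_dye <= 0:
            raise ValueError("extinction coefficients must be positive")
        if self.path_cm <= 0:
            raise ValueError("path length must be positive")
        if self.dye_a280_factor < 0:
            raise ValueError("dye_a280_factor must be non-negative")


def labeling_efficiency(m: LabelingMeasurement) -> float:
    """Dye-to-protein molar ratio from Beer–Lambert absorbances.

    C_dye = A550 / (eps_dye * l); the protein's 280 nm absorbance is first
    corrected for dye contribution, C_protein = (A280 - factor * A550) /
    (eps_protein * l); efficiency = C_dye / C_protein (dimensionless,
    invariant to path length).
    """
    c_dye = m.a550 / (m.eps_dye * m.path_cm)
    a280_protein = m.a280 - m.dye_a280_factor * m.a550
    c_protein = a280_protein / (m.eps_protein * m.path_cm)
    if c_protein <= 0:
        raise ValueError(
            "protein concentration non-positive after dye A280 correction"
        )
    return c_dye / c_protein
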