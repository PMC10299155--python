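"""Published smTIRFM rate constants for the G4P variants.

These are the printed binding parameters for the four Cy3-labeled G4
sensors (G4P, 2G4P, FJG4P, 2FJG4P) against the c-MYC, telomeric and
tandem-telomeric quadruplexes, used as ground-truth inputs for synthetic
recovery studies and for internal-consistency checks of the derived
quantities (tau = 1/k_off, Kd = k_off/k_on). No raw data accompany them.

Columns: k_on (1/(M s)), k_off (1/s), tau (s), kd (nM), each with its
quoted uncertainty. The 2G4P-2hTelG4 pair was described by a three-state
model, so its k_off, tau and Kd are not defined (NaN here).

Two printed entries are not internally consistent with their own rate
constants (row "G4P-cMYCG4" Kd: 0.61/2.16e9 = 0.28 nM, printed 0.22; row
"2FJG4P-hTelG4" tau: 1/0.4 = 2.5 s, printed 2.8) — consistency checks use
the remaining rows.

Labeling efficiencies (fraction of protein molecules carrying a Cy3 dye):
G4P 55%, 2G4P 71%, FJG4P 42%, 2FJG4P 28.5%.
"""
from __future__ import annotations

import pandas as pd

LABELING_EFFICIENCY = {
    "G4P": 0.55,
    "2G4P": 0.71,
    "FJG4P": 0.42,
    "2FJG4P": 0.285,
}

_ROWS = [
    # protein, dna, kon(1e9 /M/s), kon_se, koff(/s), koff_se, tau(s), tau_se, kd(nM), kd_se, n_states
    ("G4P", "cMYCG4", 2.16, 0.2, 0.61, 0.010, 1.64, 0.03, 0.22, 0.02, 2),
    ("2G4P", "cMYCG4", 3.9, 0.2, 0.62, 0.010, 1.62, 0.03, 0.16, 0.01, 2),
    ("G4P", "hTelG4", 0.43, 0.036, 0.67, 0.015, 1.5, 0.03, 1.6, 0.1, 2),
    ("2G4P", "hTelG4", 0.0845, 0.007, 0.29, 0.014, 3.5, 0.2, 3.4, 0.3, 2),
    ("FJG4P", "cMYCG4", 3.45, 0.39, 0.94, 0.010, 1.1, 0.01, 0.27, 0.03, 2),
    ("2FJG4P", "cMYCG4", 4.7, 0.26, 1.0, 0.023, 1.0, 0.02, 0.20, 0.01, 2),
    ("FJG4P", "hTelG4", 0.01, 0.001428, 0.33, 0.011, 3.1, 0.1, 32.7, 4.8, 2),
    ("2FJG4P", "hTelG4", 0.0339, 0.005357, 0.4, 0.008, 2.8, 0.06, 10.7, 1.7, 2),
    ("G4P", "2hTelG4", 0.209, 0.1545, 0.4, 0.02, 2.5, 0.1, 1.9, 1.4, 2),
    ("2G4P", "2hTelG4", 0.0845, 0.00704, None, None, None, None, None, None, 3),
    ("FJG4P", "2hTelG4", 0.0238, 0.003571, 0.35, 0.01, 2.9, 0.09, 14.5, 2.2, 2),
    ("2FJG4P", "2hTelG4", 0.0642, 0.00714, 0.3, 0.01, 3.35, 0.137, 4.6, 0.55, 2),
]

#: Row labels (1-based, in published order) whose printed Kd agrees with
#: k_off/k_on at the printed precision; same idea for tau = 1/k_off.
SELF_CONSISTENT_KD_ROWS = (2, 3, 4, 5, 9)
SELF_CONSISTENT_TAU_ROWS = (1, 2, 4, 6)


def binding_parameters() -> pd.DataFrame:
    """Published binding parameter table as a DataFrame (SI-ish units).

    k_on in 1/(M s) (the table's 1e9 prefix applied), k_off in 1/s, tau in
    s, kd in nM. The index is the published 1-based row number.
    """
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "protein", "dna",
            "k_on_1e9", "k_on_se_1e9",
            "k_off_per_s", "k_off_se_per_s",
            "tau_s", "tau_se_s",
            "kd_nM", "kd_se_nM",
            "n_states",
        ],
        index=pd.RangeIndex(1, len(_ROWS) + 1, name="row"),
    )
    df["k_on_per_M_s"] = df.pop("k_on_1e9") * 1e9
    df["k_on_se_per_M_s"] = df.pop("k_on_se_1e9") * 1e9
    return df
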