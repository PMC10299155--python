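"""Mass photometry: calibration, mass histograms and stoichiometry.

Calibrates a contrast-to-mass line on the standard protein ladder
(beta-amylase 56/112/224 kDa, thyroglobulin 670 kDa), fits a 3 kDa-binned
mass histogram of a simulated protein + protein-DNA-complex mixture, and
reads off the stoichiometry of each fitted species.
"""
from smg4 import assign_stoichiometry, calibrate, fit_mass_histogram, simulate_mp_events
from smg4.massphot import CALIBRATION_STANDARD_MASSES

# --- calibration on noiseless synthetic contrasts ------------------------
SLOPE = -28000.0  # kDa per unit contrast (landing events darken the spot)
standards = [(m / SLOPE, m) for m in CALIBRATION_STANDARD_MASSES]
cal = calibrate(standards)
print(f"calibration: mass = {cal.slope:.0f} * contrast + {cal.intercept:.2f}, "
      f"max residual {abs(cal.residuals_kDa).max():.2e} kDa")

# --- a 17.32 kDa protein forming a protein2-DNA complex ------------------
PROTEIN, DNA = 17.32, 7.6  # kDa
events = simulate_mp_events(
    species=[(PROTEIN, 0.7), (2 * PROTEIN + DNA, 0.3)],
    mass_sd=2.0, n=5000, include_negatives=True, seed=3,
)
hist = fit_mass_histogram(events, n_components=2, sign="positive")
print(f"{hist.n_events} landing events, fitted species:")
for comp in hist.components:
    print(f"   {comp.mean_kDa:.1f} +/- {comp.mean_se:.1f} kDa "
          f"(sd {comp.sd_kDa:.1f})")

assignments = assign_stoichiometry(
    [c.mean_kDa for c in hist.components],
    [("protein", PROTEIN), ("G4", DNA)],
)
for a in assignments:
    print("   ->", a)
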