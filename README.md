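# smg4 — single-molecule kinetics of G-quadruplex binding proteins

G-quadruplexes (G4s) are four-stranded DNA structures that form in G-rich
sequences — telomeres, oncogene promoters — and engineered G4-recognition
proteins (G4P and its expanded variants) are used to visualize them in
vitro and in cells. Their usefulness is a kinetics question: how fast does
a sensor find a quadruplex, and how long does it stay? `smg4` is a Python
library for answering that question from single-molecule TIRF microscopy
(smTIRFM) data, together with the companion measurements that usually
accompany such a study: smFRET conformation checks, mass-photometry
stoichiometry, EMSA binding isotherms and dye-labeling efficiency.

Because raw single-molecule data sets of this kind are rarely deposited,
the package ships a first-class synthetic-data module that emulates the
experiment — two-/three-state Markov binding dynamics rendered as
camera-integrated fluorescence trajectories with a pre-injection baseline,
TIRF movies of diffraction-limited spots, donor/acceptor FRET traces with
leakage, mass-photometry event mixtures, titration isotherms — so every
stage of the analysis is testable against known ground truth.

## The model

A surface-tethered quadruplex visited by a labeled protein is a two-state
continuous-time Markov chain: unbound (dark) ⇌ bound (bright). Unbound
dwell times are exponential with the observed association rate
v₊₁ = k_on·[P]·f_label ([P] protein concentration, f_label the fraction
of molecules carrying a dye); bound dwells are exponential with the
concentration-independent dissociation rate k_off. The pipeline estimates
both from idealized trajectories and reports

    τ = 1 / k_off        k_on = v₊₁ / ([P] · f_label)        K_d = k_off / k_on

with delta-method standard errors. Idealization is a pooled Gaussian
hidden Markov model (Baum–Welch over all molecules, Viterbi decoding)
with BIC model-order selection and artifact screening; dwell-time fits
use a left-truncated exponential MLE (dwells shorter than one camera
frame are unobservable — ignoring that biases rates low) alongside the
conventional binned-histogram fit. See `docs/methods.md` for the full
account.

## Worked example

`examples/01_binding_kinetics.py` simulates 150 molecules at known rates
(k_off = 0.61 s⁻¹, v₊₁ = 0.5 s⁻¹, 100 ms frames, 300-frame baseline,
SNR 5) and runs the full chain — QC selection, pooled 2-state HMM,
Viterbi, dwell extraction, truncated MLE:

```text
$ python examples/01_binding_kinetics.py
selected 150/150 trajectories
bound dwells fitted: 9930
k_off  = 0.583 +/- 0.006 1/s  (truth 0.61)
tau    = 1.72 s (mean bound-state lifetime, 1/k_off)
v+1    = 0.471 1/s  (truth 0.5)
k_on   = 0.857e9 1/(M s)   (truth 0.909e9)
Kd     = 0.68 nM (k_off / k_on)
```

The recovered k_off sits within ~5% of the generator truth; the residual
negative bias comes from short events merged by camera integration, which
is exactly the regime the truncated likelihood and the methods note
discuss. The other examples cover model-order selection on two- vs
three-state ensembles (`02`), FRET population comparison (`03`), mass
photometry calibration/stoichiometry (`04`), EMSA isotherms and labeling
efficiency (`05`) and movie spot detection/extraction (`06`).

A thin CLI wraps the same stages for shell use:

```bash
smg4 simulate --config config.yaml --seed 1 --out run/
smg4 kinetics --config config.yaml --seed 1 --out run/
smg4 run-all  --config config.yaml --seed 1 --out run/
```

Every run emits a `manifest.json` recording all thresholds, seeds and the
package version; identical config + seed gives byte-identical results.

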