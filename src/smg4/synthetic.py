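"""Synthetic-data generators standing in for the microscope and instruments.

Every downstream stage of the pipeline can be exercised against data with a
known ground truth generated here:

* :func:`simulate_trajectory` — two-/three-state continuous-time Markov
  binding dynamics rendered as camera-integrated fluorescence trajectories,
  with the pre-injection baseline phase the selection criteria rely on;
* :func:`simulate_movie` — diffraction-limited spots on a noisy background;
* :func:`simulate_fret_traces` — donor/acceptor pairs with donor leakage;
* :func:`simulate_mp_events` — mass-photometry Gaussian mixtures with
  mirrored landing/departure events;
* :func:`simulate_emsa` — hyperbolic fraction-bound titrations.

The binding generator samples the continuous-time Markov chain exactly
(exponential waiting times) and integrates state intensity over each frame
with fractional-occupancy weighting, mimicking camera integration: a frame
that spans a transition takes an intermediate intensity value, which the
idealization stage has to tolerate. Sub-frame dwells can therefore be
invisible in the rendered trace; the ground truth records both the exact
chain dwells and the frame-discretized path so that missed-event bias can
be quantified.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import FretTrace, MovieStack, Trajectory

# Intensity conventions (AU): arbitrary, chosen so default SNR
# (state separation / noise_sd) is 5. Both are configurable.
DEFAULT_INTENSITIES = (0.0, 500.0)
DEFAULT_NOISE_SD = 100.0


@dataclass
class BindingModel:
    """Generative model for one surface-tethered DNA molecule.

    ``rate_matrix[i, j]`` is the transition rate from state ``i`` to state
    ``j`` in 1/s (diagonal ignored). For the two-state binding model state 0
    is unbound and state 1 bound: ``rate_matrix[0, 1]`` is the observed
    association rate v+1 = k_on * [P] * f_label and ``rate_matrix[1, 0]``
    is k_off.

    Frames before ``pre_frames`` are forced to the unbound state — the
    protein has not been injected yet.
    """

    n_states: int
    rate_matrix: np.ndarray
    state_intensities: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_INTENSITIES)
    )
    noise_sd: float = DEFAULT_NOISE_SD
    frame_interval: float = 0.1
    n_frames: int = 3000
    pre_frames: int = 300
    bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        self.state_intensities = np.asarray(self.state_intensities, dtype=float)
        if self.n_states not in (2, 3):
            raise ValueError("n_states must be 2 or 3")
        if self.rate_matrix.shape != (self.n_states, self.n_states):
            raise ValueError("rate_matrix must be (n_states, n_states)")
        off_diag = self.rate_matrix[~np.eye(self.n_states, dtype=bool)]
        if np.any(off_diag < 0):
            raise ValueError("transition rates must be non-negative")
        if self.state_intensities.shape != (self.n_states,):
            raise ValueError("state_intensities must have one entry per state")
        if np.any(np.diff(self.state_intensities) <= 0):
            raise ValueError("state intensities must increase with state index")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if not 0 <= self.pre_frames <= self.n_frames:
            raise ValueError("pre_frames must lie within [0, n_frames]")
        if self.noise_sd < 0 or self.bleach_rate < 0:
            raise ValueError("noise_sd and bleach_rate must be non-negative")

    @classmethod
    def two_state(
        cls,
        v_plus1: float,
        k_off: float,
        snr: float = 5.0,
        **kwargs,
    ) -> "BindingModel":
        """Two-state binding model at a given signal-to-noise ratio.

        ``snr`` is the bound/unbound intensity separation divided by the
        Gaussian emission SD.
        """
        intensities = np.asarray(
            kwargs.pop("state_intensities", DEFAULT_INTENSITIES), dtype=float
        )
        noise_sd = kwargs.pop("noise_sd", (intensities[1] - intensities[0]) / snr)
        rates = np.array([[0.0, v_plus1], [k_off, 0.0]])
        return cls(
            n_states=2,
            rate_matrix=rates,
            state_intensities=intensities,
            noise_sd=noise_sd,
            **kwargs,
        )

    @classmethod
    def three_state(
        cls,
        k01: float,
        k10: float,
        k12: float,
        k21: float,
        state_intensities=(0.0, 500.0, 1000.0),
        noise_sd: float = DEFAULT_NOISE_SD,
        **kwargs,
    ) -> "BindingModel":
        """Linear three-state model (unbound <-> bound1 <-> bound2)."""
        rates = np.array(
            [[0.0, k01, 0.0], [k10, 0.0, k12], [0.0, k21, 0.0]]
        )
        return cls(
            n_states=3,
            rate_matrix=rates,
            state_intensities=np.asarray(state_intensities, dtype=float),
            noise_sd=noise_sd,
            **kwargs,
        )


@dataclass
class GroundTruth:
    """What the generator actually did, for testing recovery.

    ``true_dwells`` are the exact continuous-time chain dwells (state,
    duration in s), including the forced pre-injection baseline dwell; they
    tile the full observation window. ``true_state_path`` is the
    frame-discretized path (state with the largest occupancy in each frame).
    """

    true_state_path: np.ndarray
    true_dwells: list[tuple[int, float]]
    params: BindingModel
    seed: int

    def dwell_durations(self, state: int, interior_only: bool = True) -> np.ndarray:
        """Durations of visits to ``state``, post-injection.

        With ``interior_only`` the first and last dwells of the record are
        dropped (they are censored by the observation window / injection).
        """
        dwells = self.true_dwells[1:-1] if interior_only else self.true_dwells
        return np.array([d for s, d in dwells if s == state])


def _sample_ctmc(
    rng: np.random.Generator,
    rate_matrix: np.ndarray,
    start_state: int,
    duration: float,
) -> list[tuple[int, float]]:
    """Exact continuous-time Markov chain path over [0, duration)."""
    dwells: list[tuple[int, float]] = []
    t, state = 0.0, start_state
    while t < duration:
        out_rates = rate_matrix[state].copy()
        out_rates[state] = 0.0
        total = out_rates.sum()
        if total <= 0:  # absorbing
            dwells.append((state, duration - t))
            break
        wait = rng.exponential(1.0 / total)
        if t + wait >= duration:
            dwells.append((state, duration - t))
            break
        dwells.append((state, wait))
        t += wait
        state = rng.choice(len(out_rates), p=out_rates / total)
    return dwells


def simulate_trajectory(
    model: BindingModel,
    seed: int | np.random.SeedSequence,
    start_state: int = 0,
    molecule_id: str | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Simulate one camera-integrated fluorescence trajectory.

    The chain is sampled exactly; each frame's noiseless intensity is the
    occupancy-weighted average of state intensities over the frame. Frames
    before ``model.pre_frames`` are baseline (unbound). If ``bleach_rate``
    is positive an exponential photobleaching time is drawn after injection
    and the fluorophore goes dark (state-0 intensity) from then on.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(int(seed))
    )
    seed_int = int(ss.generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(ss)

    dt = model.frame_interval
    n, pre = model.n_frames, model.pre_frames
    pre_time = pre * dt
    post_time = (n - pre) * dt

    post_dwells = _sample_ctmc(rng, model.rate_matrix, start_state, post_time)

    if model.bleach_rate > 0:
        t_bleach = rng.exponential(1.0 / model.bleach_rate)
        post_dwells = _truncate_dwells(post_dwells, t_bleach, post_time)

    # occupancy-weighted frame integration
    occ = np.zeros((n, model.n_states))
    occ[:pre, 0] = 1.0
    t = 0.0
    for state, dur in post_dwells:
        t0, t1 = t, t + dur
        i0 = int(t0 // dt)
        i1 = min(int(np.ceil(t1 / dt - 1e-12)), n - pre)
        frames = np.arange(i0, i1)
        lo = np.maximum(frames * dt, t0)
        hi = np.minimum((frames + 1) * dt, t1)
        occ[pre + frames, state] += (hi - lo) / dt
        t = t1

    clean = occ @ model.state_intensities
    noise = rng.normal(0.0, model.noise_sd, n) if model.noise_sd > 0 else 0.0
    intensities = clean + noise

    # merge the forced baseline dwell with the first post dwell if same state
    dwells: list[tuple[int, float]] = []
    if pre > 0:
        dwells.append((0, pre_time))
    for state, dur in post_dwells:
        if dwells and dwells[-1][0] == state:
            dwells[-1] = (state, dwells[-1][1] + dur)
        else:
            dwells.append((state, dur))

    truth = GroundTruth(
        true_state_path=np.argmax(occ, axis=1),
        true_dwells=dwells,
        params=model,
        seed=seed_int,
    )
    traj = Trajectory(
        intensities,
        dt,
        molecule_id=molecule_id or f"sim-{seed_int}",
        source="simulated",
    )
    return traj, truth


def _truncate_dwells(
    dwells: list[tuple[int, float]], t_cut: float, total: float
) -> list[tuple[int, float]]:
    """Cut a dwell sequence at t_cut; remainder becomes dark state 0."""
    if t_cut >= total:
        return dwells
    out, t = [], 0.0
    for state, dur in dwells:
        if t + dur <= t_cut:
            out.append((state, dur))
        else:
            if t_cut > t:
                out.append((state, t_cut - t))
            out.append((0, total - max(t_cut, t)))
            break
        t += dur
    return out


def simulate_ensemble(
    model: BindingModel, n_traces: int, seed: int
) -> tuple[list[Trajectory], list[GroundTruth]]:
    """Simulate ``n_traces`` independent molecules with derived seeds."""
    children = np.random.SeedSequence(int(seed)).spawn(n_traces)
    trajs, truths = [], []
    for i, child in enumerate(children):
        traj, truth = simulate_trajectory(model, child, molecule_id=f"mol-{i:04d}")
        trajs.append(traj)
        truths.append(truth)
    return trajs, truths


# ---------------------------------------------------------------------------
# Movies
# ---------------------------------------------------------------------------

@dataclass
class SimulatedMovie:
    """Movie stack plus the ground truth used to render it."""

    stack: MovieStack
    centers: np.ndarray  # (n_spots, 2) as (y, x)
    trajectories: list[Trajectory]
    ground_truths: list[GroundTruth]
    psf_sigma: float
    background: float
    noise_sd: float


def simulate_movie(
    models: list[BindingModel] | BindingModel,
    n_spots: int,
    field_size: int = 128,
    psf_sigma: float = 1.2,
    background: float = 100.0,
    noise_sd: float = 10.0,
    min_separation: float | None = None,
    edge_margin: int | None = None,
    start_state: int = 0,
    seed: int = 0,
) -> SimulatedMovie:
    """Render binding trajectories as diffraction-limited spots.

    Each spot is a 2-D Gaussian of width ``psf_sigma`` whose integrated
    (full-grid) intensity per frame equals its trajectory's intensity, on a
    constant ``background`` with Gaussian pixel noise. Spot centers are drawn
    by rejection sampling with a minimum pairwise separation (default
    ``6 * psf_sigma``) so that the overlap probability is negligible — the
    spot-density precondition of the detection stage holds by construction.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    if isinstance(models, BindingModel):
        models = [models]
    if min_separation is None:
        min_separation = 6.0 * psf_sigma
    if edge_margin is None:
        edge_margin = int(np.ceil(4 * psf_sigma)) + 4

    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    max_tries = 10000
    for _ in range(max_tries):
        if len(centers) >= n_spots:
            break
        cand = rng.uniform(edge_margin, field_size - edge_margin, 2)
        if all(np.hypot(*(cand - c)) >= min_separation for c in centers):
            centers.append(cand)
    if len(centers) < n_spots:
        raise ValueError(
            f"could not place {n_spots} spots with separation {min_separation}"
            f" in a {field_size}px field"
        )
    centers_arr = np.array(centers) if centers else np.empty((0, 2))

    trajs, truths = [], []
    children = np.random.SeedSequence(int(seed) + 1).spawn(max(n_spots, 1))
    for i in range(n_spots):
        model = models[i % len(models)]
        traj, truth = simulate_trajectory(
            model, children[i], start_state=start_state, molecule_id=f"spot-{i:03d}"
        )
        trajs.append(traj)
        truths.append(truth)

    n_frames = trajs[0].n_frames if trajs else 1
    frame_interval = trajs[0].frame_interval if trajs else 0.1
    stack = np.full((n_frames, field_size, field_size), background, dtype=float)

    yy, xx = np.mgrid[0:field_size, 0:field_size]
    for traj, (cy, cx) in zip(trajs, centers_arr):
        # render only a local window; tails beyond 6 sigma are negligible
        r = int(np.ceil(6 * psf_sigma))
        y0, y1 = int(cy) - r, int(cy) + r + 1
        x0, x1 = int(cx) - r, int(cx) + r + 1
        psf = np.exp(
            -((yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2)
            / (2 * psf_sigma**2)
        ) / (2 * np.pi * psf_sigma**2)
        stack[:, y0:y1, x0:x1] += traj.intensities[:, None, None] * psf[None]

    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, stack.shape)

    return SimulatedMovie(
        stack=MovieStack(stack, frame_interval),
        centers=centers_arr,
        trajectories=trajs,
        ground_truths=truths,
        psf_sigma=psf_sigma,
        background=background,
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# FRET
# ---------------------------------------------------------------------------

def simulate_fret_traces(
    e_low: float,
    e_high: float,
    frac_high: float,
    total_intensity: float = 1000.0,
    leakage: float = 0.0,
    n: int = 100,
    n_frames: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[FretTrace]:
    """Donor/acceptor traces for a two-population FRET mixture.

    Each molecule is assigned the high-FRET state with probability
    ``frac_high``. Donor leakage is added to the acceptor channel *before*
    noise, so the correction in :mod:`smg4.fret` inverts it exactly in the
    noiseless limit.
    """
    for name, e in (("e_low", e_low), ("e_high", e_high)):
        if not 0 <= e <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if not 0 <= frac_high <= 1:
        raise ValueError("frac_high must be in [0, 1]")
    if not 0 <= leakage < 0.5:
        raise ValueError("leakage must be in [0, 0.5)")

    rng = np.random.default_rng(seed)
    traces = []
    for i in range(n):
        e = e_high if rng.random() < frac_high else e_low
        donor = np.full(n_frames, (1 - e) * total_intensity)
        acceptor = np.full(n_frames, e * total_intensity)
        acceptor = acceptor + leakage * donor
        if noise_sd > 0:
            donor = donor + rng.normal(0, noise_sd, n_frames)
            acceptor = acceptor + rng.normal(0, noise_sd, n_frames)
        traces.append(FretTrace(donor, acceptor, molecule_id=f"fret-{i:04d}"))
    return traces


# ---------------------------------------------------------------------------
# Mass photometry
# ---------------------------------------------------------------------------

def simulate_mp_events(
    species: list[tuple[float, float]],
    mass_sd: float = 2.0,
    n: int = 1000,
    include_negatives: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Sample mass-photometry events (kDa) from a Gaussian mixture.

    ``species`` is a list of (mass_kDa, weight); weights must sum to 1.
    With ``include_negatives`` every landing event is mirrored by an exact
    negative-mass departure event, reproducing the mirror-image positive and
    negative distributions seen on a glass surface at equilibrium.
    """
    masses = np.array([m for m, _ in species], dtype=float)
    weights = np.array([w for _, w in species], dtype=float)
    if np.any(masses <= 0):
        raise ValueError("species masses must be positive")
    if mass_sd <= 0:
        raise ValueError("mass_sd must be positive")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("species weights must sum to 1")

    rng = np.random.default_rng(seed)
    comp = rng.choice(len(masses), size=n, p=weights)
    events = rng.normal(masses[comp], mass_sd)
    if include_negatives:
        events = np.concatenate([events, -events])
    return events


# ---------------------------------------------------------------------------
# EMSA
# ---------------------------------------------------------------------------

def simulate_emsa(
    kd: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
):
    """Hyperbolic fraction-bound titration with clamped Gaussian noise.

    f([P]) = [P] / (Kd + [P]), noise added then clamped to [0, 1].
    Returns a :class:`smg4.emsa.BindingIsotherm`.
    """
    from .emsa import BindingIsotherm

    if kd <= 0:
        raise ValueError("kd must be positive")
    concentrations = np.asarray(concentrations, dtype=float)
    if concentrations.size == 0:
        raise ValueError("concentration list must be non-empty")

    rng = np.random.default_rng(seed)
    conc = np.tile(concentrations, n_replicates)
    frac = conc / (kd + conc)
    if noise_sd > 0:
        frac = np.clip(frac + rng.normal(0, noise_sd, conc.size), 0.0, 1.0)
    replicates = np.repeat(np.arange(n_replicates), concentrations.size)
    return BindingIsotherm(conc, frac, replicates)
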