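"""Trajectory idealization with pooled Gaussian hidden Markov models.

All selected trajectories from one experiment are analyzed collectively:
one global emission model (state means and SDs shared across molecules) is
fit by Baum–Welch EM over the pooled sequences, candidate state counts are
compared by BIC, and each trajectory is idealized by Viterbi decoding.

States are always relabeled by ascending mean intensity, so state 0 is
unbound and state 1 (and 2, for three-state fits) are bound levels.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GaussianHMM
from sklearn.cluster import KMeans

from .trajectory import Trajectory

_KMEANS_SUBSAMPLE = 20000


@dataclass
class HmmModel:
    """Fitted pooled Gaussian HMM.

    ``model_score`` is the Bayesian information criterion on the pooled
    log-likelihood (lower is better), the model-selection criterion used in
    place of a variational evidence bound; ``score_name`` records this in
    output metadata. ``flags`` lists degeneracy diagnostics (near-empty
    states, indistinguishable means) — a flagged model is returned, never
    silently accepted.
    """

    n_states: int
    means: np.ndarray
    sds: np.ndarray
    transition_matrix: np.ndarray
    initial_probs: np.ndarray
    log_likelihood: float
    model_score: float
    n_params: int
    n_frames: int
    converged: bool
    flags: list[str] = field(default_factory=list)
    ll_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    score_name: str = "bic"
    candidate_scores: dict[int, float] = field(default_factory=dict)
    state_weights: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if np.any(self.sds <= 0):
            raise ValueError("emission SDs must be positive")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("states must be labeled by ascending mean")

    @property
    def degenerate(self) -> bool:
        return bool(self.flags)

    def to_hmmlearn(self) -> GaussianHMM:
        m = GaussianHMM(n_components=self.n_states, covariance_type="diag")
        m.means_ = self.means.reshape(-1, 1)
        m.covars_ = (self.sds**2).reshape(-1, 1)
        m.transmat_ = self.transition_matrix.copy()
        # floor the start distribution: a learned zero (every training
        # molecule began unbound) must not force the first decoded frame
        start = np.maximum(self.initial_probs, 1e-6)
        m.startprob_ = start / start.sum()
        m.n_features = 1
        return m

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "transition_matrix": self.transition_matrix.tolist(),
            "initial_probs": self.initial_probs.tolist(),
            "log_likelihood": self.log_likelihood,
            "model_score": self.model_score,
            "score_name": self.score_name,
            "n_params": self.n_params,
            "n_frames": self.n_frames,
            "converged": self.converged,
            "flags": list(self.flags),
            "candidate_scores": {str(k): v for k, v in self.candidate_scores.items()},
            "state_weights": self.state_weights.tolist(),
        }


@dataclass
class IdealizedTrajectory:
    """Viterbi state path for one molecule under a fitted model."""

    state_path: np.ndarray
    model: HmmModel
    molecule_id: str
    frame_interval: float

    def __post_init__(self) -> None:
        self.state_path = np.asarray(self.state_path, dtype=int)
        if self.state_path.size == 0:
            raise ValueError("empty idealized path")
        if self.state_path.max() >= self.model.n_states:
            raise ValueError("state index out of range for model")

    def __len__(self) -> int:
        return self.state_path.size


class _RelTolMonitor(ConvergenceMonitor):
    """EM convergence on *relative* log-likelihood change.

    hmmlearn's stock monitor uses an absolute tolerance, which is unusable
    across pooled datasets whose log-likelihoods span orders of magnitude.
    """

    @property
    def converged(self):
        if self.iter == self.n_iter:
            return True
        if len(self.history) < 2:
            return False
        prev, curr = self.history[-2], self.history[-1]
        return abs(curr - prev) < self.tol * (abs(curr) + 1.0)


def _pool(trajs: list[Trajectory]) -> tuple[np.ndarray, np.ndarray]:
    if not trajs:
        raise ValueError("need at least one trajectory")
    X = np.concatenate([t.intensities for t in trajs]).reshape(-1, 1)
    lengths = np.array([t.n_frames for t in trajs])
    return X, lengths


def fit_hmm(
    trajs: list[Trajectory],
    n_states: int,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 500,
    rtol: float = 1e-6,
    degenerate_weight: float = 1e-3,
    transient_frames: float = 1.5,
    sticky: float = 0.9,
) -> HmmModel:
    """Fit a pooled Gaussian HMM by multi-start Baum–Welch EM.

    Emission parameters are shared across molecules. Each restart is
    initialized from a k-means++ clustering of (a subsample of) the pooled
    intensities with a sticky transition prior (``sticky`` on the
    diagonal); the restart with the best final log-likelihood wins. States
    are relabeled by ascending mean.

    Degenerate fits are flagged in ``HmmModel.flags``: a state holding
    fewer than ``degenerate_weight`` of the frames, two states with
    overlapping means (closer than half the smaller emission SD), or a
    state whose expected lifetime ``1 / (1 - T[k,k])`` is below
    ``transient_frames`` frames. The last catches the spurious
    intermediate level that camera integration paints across transitions:
    a molecular state cannot live for less than the time resolution, so a
    sub-frame state is an artifact, not chemistry.
    """
    if n_states not in (2, 3, 4):
        raise ValueError("n_states must be 2, 3 or 4")
    X, lengths = _pool(trajs)
    n_total = X.shape[0]

    rng = np.random.default_rng(seed)
    sub = X if n_total <= _KMEANS_SUBSAMPLE else X[
        rng.choice(n_total, _KMEANS_SUBSAMPLE, replace=False)
    ]
    global_var = X.var()

    best = None
    for restart in range(n_restarts):
        km_seed = int(rng.integers(2**31))
        km = KMeans(
            n_clusters=n_states, n_init=1, random_state=km_seed, init="k-means++"
        ).fit(sub)
        means0 = np.sort(km.cluster_centers_.ravel())
        # per-cluster variance, floored to avoid zero-width emission states
        var0 = np.empty(n_states)
        order = np.argsort(km.cluster_centers_.ravel())
        for rank, cluster in enumerate(order):
            pts = sub[km.labels_ == cluster]
            var0[rank] = max(pts.var() if pts.size > 1 else global_var, 1e-12)

        model = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            n_iter=max_iter,
            init_params="",
            params="stmc",
            random_state=km_seed,
            min_covar=1e-10,
        )
        model.monitor_ = _RelTolMonitor(rtol, max_iter, False)
        model.means_ = means0.reshape(-1, 1)
        model.covars_ = var0.reshape(-1, 1)
        model.startprob_ = np.full(n_states, 1.0 / n_states)
        transmat = np.full((n_states, n_states), (1 - sticky) / max(n_states - 1, 1))
        np.fill_diagonal(transmat, sticky)
        model.transmat_ = transmat
        model.fit(X, lengths)

        ll = model.monitor_.history[-1]
        if best is None or ll > best[0]:
            best = (ll, model, np.array(model.monitor_.history))

    ll, model, history = best

    # relabel by ascending mean
    perm = np.argsort(model.means_.ravel())
    means = model.means_.ravel()[perm]
    sds = np.sqrt(np.asarray(model.covars_).reshape(n_states, -1).ravel()[perm])
    transmat = model.transmat_[np.ix_(perm, perm)]
    startprob = model.startprob_[perm]

    # occupancy weights from the decoded path
    inv = np.argsort(perm)
    states = inv[model.predict(X, lengths)]
    weights = np.bincount(states, minlength=n_states) / n_total

    flags = []
    for k in range(n_states):
        if weights[k] < degenerate_weight:
            flags.append(f"state {k} nearly empty (weight {weights[k]:.2e})")
    for k in range(n_states - 1):
        sep = means[k + 1] - means[k]
        # two equal Gaussians are unimodal up to a 2 SD separation, so
        # closer levels cannot be told apart in the intensity histogram
        if sep < 2.0 * min(sds[k], sds[k + 1]):
            flags.append(
                f"states {k} and {k + 1} indistinguishable "
                f"(separation {sep:.3g} < 2 emission SDs)"
            )
    for k in range(n_states):
        lifetime = 1.0 / max(1.0 - transmat[k, k], 1e-12)
        if lifetime < transient_frames:
            flags.append(
                f"state {k} lifetime {lifetime:.2f} frames < {transient_frames}: "
                "sub-resolution artifact state"
            )

    # free parameters: K-1 start, K(K-1) transitions, K means, K variances
    n_params = (n_states - 1) + n_states * (n_states - 1) + 2 * n_states
    bic = n_params * np.log(n_total) - 2.0 * ll

    return HmmModel(
        n_states=n_states,
        means=means,
        sds=np.maximum(sds, 1e-12),
        transition_matrix=transmat,
        initial_probs=startprob,
        log_likelihood=float(ll),
        model_score=float(bic),
        n_params=n_params,
        n_frames=int(n_total),
        converged=model.monitor_.iter < max_iter,
        flags=flags,
        ll_history=history,
        state_weights=weights,
    )


def select_model(
    trajs: list[Trajectory],
    candidate_states=(2, 3, 4),
    seed: int = 0,
    **fit_kwargs,
) -> HmmModel:
    """Fit each candidate state count and keep the best (lowest) BIC.

    Candidates with degeneracy flags (empty, indistinguishable or
    sub-resolution states) are ruled out first — an extra state that only
    models camera-blurred transition frames can win on raw likelihood but
    is not a molecular state. Among the remaining candidates the lowest
    BIC wins, ties broken toward fewer states; if every candidate is
    flagged, the lowest BIC overall is returned (with its flags). Scores
    of every candidate are retained in ``candidate_scores`` for audit.
    """
    candidate_states = sorted(candidate_states)
    if not candidate_states:
        raise ValueError("candidate_states must be non-empty")
    fits = {
        k: fit_hmm(trajs, k, seed=seed + i, **fit_kwargs)
        for i, k in enumerate(candidate_states)
    }
    scores = {k: f.model_score for k, f in fits.items()}
    clean = [k for k in candidate_states if not fits[k].flags]
    pool = clean if clean else candidate_states
    best_k = min(pool, key=lambda k: (scores[k], k))
    chosen = fits[best_k]
    chosen.candidate_scores = scores
    return chosen


def decode(traj: Trajectory, model: HmmModel) -> IdealizedTrajectory:
    """Viterbi most-probable state path for one trajectory."""
    hl = model.to_hmmlearn()
    _, path = hl.decode(traj.intensities.reshape(-1, 1), algorithm="viterbi")
    return IdealizedTrajectory(
        state_path=path,
        model=model,
        molecule_id=traj.molecule_id,
        frame_interval=traj.frame_interval,
    )


def decode_all(trajs: list[Trajectory], model: HmmModel) -> list[IdealizedTrajectory]:
    return [decode(t, model) for t in trajs]
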