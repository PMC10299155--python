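"""End-to-end orchestration of the analysis stages.

The smTIRFM chain is simulate (or extract from a movie) -> QC selection ->
HMM idealization -> dwell extraction -> exponential fits -> kinetic
constants; the FRET, mass-photometry and EMSA analyses are independent
stages. :func:`run` executes the stages named in a :class:`RunConfig` in
dependency order, passes intermediates in memory, writes every output as
plain text (TSV/CSV/JSON) and emits a machine-readable manifest recording
every threshold used, the seed and the package version, so a run is fully
auditable and two runs with the same config and seed produce identical
result files.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dwell import choose_components, extract_dwells, fit_exponential
from .emsa import BindingIsotherm, LabelingMeasurement, fit_isotherm, labeling_efficiency
from .fret import build_histogram
from .hmm import HmmModel, decode_all, fit_hmm, select_model
from .kinetics import (
    ExperimentCondition,
    KineticResult,
    PerConcentration,
    aggregate_concentration_series,
)
from .massphot import assign_stoichiometry, calibrate, fit_mass_histogram
from .movie import detect_spots, extract_trace, select_trajectories
from .synthetic import (
    BindingModel,
    simulate_emsa,
    simulate_ensemble,
    simulate_fret_traces,
    simulate_mp_events,
)
from .trajectory import MovieStack, Trajectory, read_manifest, write_manifest

STAGE_ORDER = ["simulate", "extract", "qc", "idealize", "dwell", "kinetics",
               "fret", "mp", "emsa"]

BOUND_STATE = 1
UNBOUND_STATE = 0


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, np.bool_):
            return bool(o)
        return super().default(o)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder, sort_keys=True))


@dataclass
class RunConfig:
    """Stage list plus per-stage parameter blocks.

    Any parameter omitted from a block takes the documented default of the
    underlying function; every value actually used is echoed into the run
    manifest.
    """

    stages: list[str] = field(default_factory=list)
    seed: int = 0
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} is not a mapping")
        stages = raw.pop("stages", [])
        seed = int(raw.pop("seed", 0))
        unknown = [s for s in stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stages in config: {unknown}")
        return cls(stages=stages, seed=seed, params=raw)

    def block(self, stage: str) -> dict:
        return dict(self.params.get(stage, {}))


# ---------------------------------------------------------------------------
# Reusable smTIRFM analysis chain (also the acceptance-path entry point)
# ---------------------------------------------------------------------------

@dataclass
class EnsembleAnalysis:
    """Everything the smTIRFM chain produced for one trajectory ensemble."""

    model: HmmModel
    n_selected: int
    n_total: int
    dwells: "object"
    bound_fit: "object"
    unbound_fit: "object"
    qc_reports: list


def analyze_trajectories(
    trajs: list[Trajectory],
    pre_frames: int = 300,
    n_states: int | None = 2,
    candidate_states=(2, 3, 4),
    seed: int = 0,
    qc_params: dict | None = None,
    hmm_params: dict | None = None,
    dwell_method: str = "mle",
    components: str = "1",
    alpha: float = 0.05,
    truncate: bool = True,
) -> EnsembleAnalysis:
    """QC -> pooled HMM -> Viterbi -> dwells -> exponential fits.

    With ``n_states`` None the state count is chosen by BIC over
    ``candidate_states``. Bound- and unbound-state dwell distributions are
    fitted single-exponential by default (``components="1"``); with
    ``components="auto"`` the one-vs-two-phase significance test at
    ``alpha`` picks the phase count instead. Phase testing on
    frame-discretized dwells is deliberately opt-in: the discrete
    single-frame spike can masquerade as a fast second phase. The MLE route
    is left-truncated at one frame interval when ``truncate`` is set.
    """
    selected, reports = select_trajectories(
        trajs, pre_frames=pre_frames, **(qc_params or {})
    )
    if not selected:
        raise RuntimeError("no trajectories passed QC selection")

    hmm_params = hmm_params or {}
    if n_states is None:
        model = select_model(selected, candidate_states, seed=seed, **hmm_params)
    else:
        model = fit_hmm(selected, n_states, seed=seed, **hmm_params)

    ideals = decode_all(selected, model)
    dwells = extract_dwells(ideals)

    dt = selected[0].frame_interval
    t_min = dt if (truncate and dwell_method == "mle") else 0.0
    kwargs = {"method": dwell_method, "t_min": t_min} if dwell_method == "mle" else {
        "method": dwell_method
    }

    def _fit(durations):
        if components == "auto":
            return choose_components(durations, alpha=alpha, **kwargs)
        return fit_exponential(durations, int(components), **kwargs)

    bound_fit = _fit(dwells.durations(BOUND_STATE))
    unbound_fit = _fit(dwells.durations(UNBOUND_STATE))
    return EnsembleAnalysis(
        model=model,
        n_selected=len(selected),
        n_total=len(trajs),
        dwells=dwells,
        bound_fit=bound_fit,
        unbound_fit=unbound_fit,
        qc_reports=reports,
    )


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, outdir: Path, seed: int, state: dict) -> dict:
    p = cfg.block("simulate")
    model = BindingModel.two_state(
        v_plus1=p.get("v_plus1", 0.5),
        k_off=p.get("k_off", 0.61),
        snr=p.get("snr", 5.0),
        frame_interval=p.get("frame_interval", 0.1),
        n_frames=p.get("n_frames", 3000),
        pre_frames=p.get("pre_frames", 300),
        bleach_rate=p.get("bleach_rate", 0.0),
    )
    trajs, truths = simulate_ensemble(model, p.get("n_traces", 100), seed)
    write_manifest(trajs, outdir / "traces")
    _dump_json(
        [
            {"molecule_id": t.molecule_id if hasattr(t, "molecule_id") else None,
             "seed": g.seed,
             "true_dwells": [[int(s), d] for s, d in g.true_dwells]}
            for t, g in zip(trajs, truths)
        ],
        outdir / "ground_truth.json",
    )
    state["trajectories"] = trajs
    state["pre_frames"] = model.pre_frames
    return {"n_traces": len(trajs), "model": {
        "v_plus1": model.rate_matrix[0, 1], "k_off": model.rate_matrix[1, 0],
        "noise_sd": model.noise_sd, "n_frames": model.n_frames,
        "pre_frames": model.pre_frames, "frame_interval": model.frame_interval,
    }}


def _stage_extract(cfg: RunConfig, outdir: Path, seed: int, state: dict) -> dict:
    p = cfg.block("extract")
    movie_path = p.get("movie")
    if not movie_path or not Path(movie_path).exists():
        raise FileNotFoundError(f"extract stage: movie file not found: {movie_path}")
    stack = MovieStack.from_tiff(movie_path, p.get("frame_interval", 0.1))
    spots = detect_spots(
        stack,
        detect_frames=slice(0, p.get("detect_frames", min(10, stack.n_frames))),
        threshold_sigmas=p.get("threshold_sigmas", 5.0),
        window_radius=p.get("window_radius", 3),
    )
    trajs = [
        extract_trace(stack, s, molecule_id=f"mol-{i:04d}")
        for i, s in enumerate(spots)
    ]
    write_manifest(trajs, outdir / "traces")
    state["trajectories"] = trajs
    state.setdefault("pre_frames", p.get("pre_frames", 300))
    return {"n_spots": len(spots), "threshold_sigmas": p.get("threshold_sigmas", 5.0)}


def _load_traces_if_needed(cfg: RunConfig, state: dict) -> None:
    if "trajectories" in state:
        return
    p = cfg.block("qc")
    traces_dir = p.get("traces_dir")
    if not traces_dir:
        raise FileNotFoundError(
            "qc stage: no in-memory trajectories and no qc.traces_dir configured"
        )
    if not Path(traces_dir).exists():
        raise FileNotFoundError(f"qc stage: trace directory not found: {traces_dir}")
    state["trajectories"] = read_manifest(traces_dir)


def _stage_qc(cfg: RunConfig, outdir: Path, seed: int, state: dict) -> dict:
    import pandas as pd

    p = cfg.block("qc")
    _load_traces_if_needed(cfg, state)
    pre = p.get("pre_frames", state.get("pre_frames", 300))
    qc_kwargs = {
        k: p[k]
        for k in ("event_sigmas", "min_event_frames", "min_events", "drift_tolerance")
        if k in p
    }
    selected, reports = select_trajectories(
        state["trajectories"], pre_frames=pre, **qc_kwargs
    )
    pd.DataFrame(
        [
            {
                "molecule_id": r.molecule_id,
                "passed": r.passed,
                "reasons": ";".join(r.reasons),
                "n_events_detected": r.n_events_detected,
                "baseline_mean": r.baseline_mean,
                "baseline_sd": r.baseline_sd,
            }
            for r in reports
        ]
    ).to_csv(outdir / "qc_report.csv", index=False)
    state["selected"] = selected
    return {
        "pre_frames": pre,
        **{k: qc_kwargs.get(k) for k in qc_kwargs},
        "n_selected": len(selected),
        "n_total": len(state["trajectories"]),
    }


def _stage_idealize(cfg: RunConfig, outdir: Path, seed: int, state: dict) -> dict:
    p = cfg.block("idealize")
    if "selected" not in state:
        raise RuntimeError("idealize stage requires the qc stage upstream")
    if not state["selected"]:
        raise RuntimeError("idealize stage: no trajectories passed QC")
    hmm_params = {
        k: p[k] for k in ("n_restarts", "max_iter", "rtol") if k in p
    }
    if "n_states" in p:
        model = fit_hmm(state["selected"], p["n_states"], seed=seed, **hmm_params)
    else:
        model = select_model(
            state["selected"],
            tuple(p.get("candidate_states", (2, 3, 4))),
            seed=seed,
            **hmm_params,
        )
    ideals = decode_all(state["selected"], model)
    _dump_json(model.to_dict(), outdir / "hmm_model.json")
    ideal_dir = outdir / "idealized"
    ideal_dir.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    for traj, ideal in zip(state["selected"], ideals):
        pd.DataFrame(
            {
                "frame": np.arange(len(ideal)),
                "intensity_AU": traj.intensities,
                "state": ideal.state_path,
            }
        ).to_csv(ideal_dir / f"{ideal.molecule_id}.tsv", sep="\t", index=False)
    state["model"] = model
    state["ideals"] = ideals
    return {"n_states": model.n_states, "model_score": model.model_score,
            "score_name": model.score_name, "flags": model.flags}


def _stage_dwell(cfg: RunConfig, outdir: Path, seed: int, state: dict) -> dict:
    p = cfg.block("dwell")
    if "ideals" not in state:
        raise RuntimeError("dwell stage requires the idealize stage upstream")
    dwells = extract_dwells(state["ideals"])
    dwells.to_csv(outdir / "dwells.csv")
    dt = dwells.frame_interval
    method = p.get("method", "mle")
    alpha = p.get("alpha", 0.05)
    components = str(p.get("components", "1"))
    t_min = p.get("t_min", dt if method == "mle" else 0.0)
    kwargs = {"method": method}
    if method == "mle":
        kwargs["t_min"] = t_min
    fits = {}
    for name, st in (("bound", BOUND_STATE), ("unbound", UNBOUND_STATE)):
        durations = dwells.durations(st)
        if components == "auto":
            fits[name] = choose_components(durations, alpha=alpha, **kwargs)
        else:
            fits[name] = fit_exponential(durations, int(components), **kwargs)
    _dump_json({k: f.to_dict() for k, f in fits.items()}, outdir / "dwell_fits.json")
    state["dwells"] = dwells
    state["fits"] = fits
    return {"method": method, "alpha": alpha, "t_min": t_min,
            "n_dwells_bound": int(fits["bound"].n_dwells),
            "n_dwells_unbound": int(fits["unbound"].n_dwells)}


def _stage_kinetics(cfg: RunConfig, outdir: Path, seed: int, state: dict) -> dict:
    import pandas as pd

    p = cfg.block("kinetics")
    if "fits" not in state:
        raise RuntimeError("kinetics stage requires the dwell stage upstream")
    cond = ExperimentCondition(
        protein=p.get("protein", "G4P"),
        dna=p.get("dna", "G4"),
        nominal_concentration=p.get("concentration_nM", 1.0) * 1e-9,
        labeling_efficiency=p.get("labeling_efficiency", 1.0),
    )
    bound, unbound = state["fits"]["bound"], state["fits"]["unbound"]
    result = aggregate_concentration_series(
        [
            PerConcentration(
                condition=cond,
                v_plus1=unbound.rate,
                v_plus1_se=unbound.se,
                k_off=bound.rate,
                k_off_se=bound.se,
            )
        ],
        n_states_selected=state["model"].n_states if "model" in state else 2,
    )
    _dump_json(result.to_dict(), outdir / "kinetics.json")
    pd.DataFrame(
        [
            {
                "protein_dna": f"{result.protein}-{result.dna}",
                "kon_per_M_s": result.k_on,
                "koff_per_s": result.k_off,
                "tau_s": result.tau,
                "kd_nM": result.kd_nM,
            }
        ]
    ).to_csv(outdir / "kinetics_table.csv", index=False)
    state["kinetics"] = result
    return {"condition": asdict(cond)}


def _stage_fret(cfg: RunConfig, outdir: Path, seed: int, state: dict) -> dict:
    p = cfg.block("fret")
    leakage = p.get("leakage", 0.10)
    traces = simulate_fret_traces(
        e_low=p.get("e_low", 0.3),
        e_high=p.get("e_high", 0.7),
        frac_high=p.get("frac_high", 0.5),
        total_intensity=p.get("total_intensity", 1000.0),
        leakage=leakage,
        n=p.get("n_molecules", 500),
        noise_sd=p.get("noise_sd", 30.0),
        seed=seed,
    )
    hist = build_histogram(traces, leakage=leakage)
    out = {
        "leakage": leakage,
        "n_molecules": hist.n_molecules,
        "components": [
            {"mean": c.mean, "sd": c.sd, "amplitude": c.amplitude}
            for c in hist.components
        ],
        "weights": hist.weights,
        "single_gaussian_fallback": hist.single_gaussian_fallback,
    }
    _dump_json(out, outdir / "fret_fit.json")
    import pandas as pd

    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    pd.DataFrame({"bin_center": centers, "count": hist.counts}).to_csv(
        outdir / "fret_histogram.csv", index=False
    )
    state["fret"] = hist
    return {"leakage": leakage, "n_molecules": hist.n_molecules}


def _stage_mp(cfg: RunConfig, outdir: Path, seed: int, state: dict) -> dict:
    p = cfg.block("mp")
    species = [tuple(s) for s in p.get("species", [(17.32, 1.0)])]
    events = simulate_mp_events(
        species=species,
        mass_sd=p.get("mass_sd", 2.0),
        n=p.get("n_events", 2000),
        include_negatives=p.get("include_negatives", False),
        seed=seed,
    )
    hist = fit_mass_histogram(
        events, n_components=p.get("n_components", len(species)),
        sign=p.get("sign", "positive"),
        choose_by_bic=p.get("choose_by_bic", False),
    )
    result = {
        "n_events": hist.n_events,
        "components": [
            {"mean_kDa": c.mean_kDa, "sd_kDa": c.sd_kDa, "amplitude": c.amplitude}
            for c in hist.components
        ],
    }
    if "monomers" in p:
        assignments = assign_stoichiometry(
            [c.mean_kDa for c in hist.components],
            [tuple(m) for m in p["monomers"]],
            tolerance_kDa=p.get("tolerance_kDa", 4.0),
        )
        result["stoichiometry"] = [str(a) for a in assignments]
    _dump_json(result, outdir / "mass_photometry.json")
    state["mp"] = hist
    return {"species": species, "n_events": hist.n_events}


def _stage_emsa(cfg: RunConfig, outdir: Path, seed: int, state: dict) -> dict:
    p = cfg.block("emsa")
    data = p.get("data_csv")
    if data:
        if not Path(data).exists():
            raise FileNotFoundError(f"emsa stage: data file not found: {data}")
        iso = BindingIsotherm.from_csv(data)
    else:
        iso = simulate_emsa(
            kd=p.get("kd_nM", 84.0),
            concentrations=p.get(
                "concentrations_nM",
                list(np.geomspace(1, 2000, 12)),
            ),
            noise_sd=p.get("noise_sd", 0.02),
            seed=seed,
        )
    fit = fit_isotherm(iso, model=p.get("model", "hyperbolic"))
    result = {"kd_nM": fit.kd_nM, "kd_se_nM": fit.kd_se_nM,
              "hill_n": fit.hill_n, "model": fit.model,
              "extrapolated": fit.extrapolated}
    if "labeling" in p:
        m = LabelingMeasurement(**p["labeling"])
        result["labeling_efficiency"] = labeling_efficiency(m)
    _dump_json(result, outdir / "emsa_fit.json")
    state["emsa"] = fit
    return {"kd_nM": fit.kd_nM, "model": fit.model}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "extract": _stage_extract,
    "qc": _stage_qc,
    "idealize": _stage_idealize,
    "dwell": _stage_dwell,
    "kinetics": _stage_kinetics,
    "fret": _stage_fret,
    "mp": _stage_mp,
    "emsa": _stage_emsa,
}


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages in dependency order; return the manifest.

    Each stage gets its own deterministic seed stream derived from the
    global seed. A stage failure stops the run with a diagnostic naming the
    stage; stages already completed keep their outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGE_ORDER if s in config.stages]

    stage_seeds = {
        name: int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % 2**31)
        for i, name in enumerate(STAGE_ORDER)
    }

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": stages,
        "stage_params": {},
    }
    state: dict = {}
    for name in stages:
        try:
            info = _STAGE_FUNCS[name](config, outdir, stage_seeds[name], state)
        except Exception as err:
            manifest["failed_stage"] = name
            manifest["error"] = str(err)
            _dump_json(manifest, outdir / "manifest.json")
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
        manifest["stage_params"][name] = info
    _dump_json(manifest, outdir / "manifest.json")
    return manifest
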