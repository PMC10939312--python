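"""End-to-end runs: grid simulation, model fitting and recovery.

A run simulates every plausible (family, sigma, a, b) grid point for a cohort
of simulated participants (each with their own trial sequence, voxel sampling
and noise draws), computes the seven outcome metrics, and fits the results to
an empirical (or pseudo-empirical) summary by sign matching and weighted MSE.

Noise draws, trial sequences and voxel compositions are pre-drawn per
participant/repetition from counter-derived seeds and shared across grid
points, so grid tasks are independent and the result is bit-identical for
any worker count.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .forward_model import (
    MODEL_FAMILIES,
    FeatureSpace,
    ModulationModel,
    ParameterGrid,
    build_bank,
    build_grid,
    modulated_stimulus_response,
    rejection_table,
    unmodulated_stimulus_response,
)
from .metrics import METRIC_NAMES, MetricEngine, raw_slopes
from .model_fit import (
    EmpiricalSummary,
    grand_medians,
    normalize_metrics,
    rank_models,
    sign_match,
    squared_errors,
    weighted_mse,
)
from .synthetic_data import (
    DESIGN_6x6,
    ExperimentDesign,
    GroundTruthSpec,
    generate_ground_truth_dataset,
    make_synthetic_stimuli,
    make_transition_matrix,
    participant_rng,
    place_positions,
    sample_trial_sequence,
)
from .voxel_sim import calibrate_noise, sample_voxels
from .metrics import compute_metrics

__all__ = [
    "RunConfig",
    "desk_grid",
    "full_grid",
    "run_full",
    "run_recovery",
    "pseudo_empirical_summary",
]


def desk_grid() -> ParameterGrid:
    """Reduced exploration grid (~216 family x point combinations)."""
    return ParameterGrid(
        sigmas=(0.3, 0.5, 1.0),
        a_values=(0.2, 0.4, 0.6, 0.8),
        b_values=(0.3, 0.5, 1.0, 2.0),
    )


def full_grid() -> ParameterGrid:
    """The full default exploration grid (17 sigma x 20 a x 23 b = 7820)."""
    return build_grid()


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one simulation-and-fit run (one ROI)."""

    space_kind: str = "circular"
    n_voxels: int = 300
    design: ExperimentDesign = DESIGN_6x6
    grid: ParameterGrid = field(default_factory=desk_grid)
    target_accuracy: float = 0.5
    n_participants: int = 10
    n_repetitions: int = 2
    master_seed: int = 0
    response_gain: float = 100.0
    noise_step: float = 1.0
    decoder: str = "lda"
    top_fraction: float = 0.02
    n_boot: int = 2000
    n_jobs: int = 1
    out_dir: str | None = None

    @property
    def space(self) -> FeatureSpace:
        return FeatureSpace(self.space_kind)


def study_stimuli(config: RunConfig):
    """The run's stimulus set (shared by data generation and fitting)."""
    return make_synthetic_stimuli(
        config.design.n_trailing, config.space,
        participant_rng(config.master_seed, 9, 0),
    )


def study_sequences(config: RunConfig, n_participants: int):
    """Per-participant trial sequences, reproducible in isolation."""
    tm = make_transition_matrix(
        config.design.n_leading, config.design.reliability
    )
    return [
        sample_trial_sequence(
            config.design, tm, participant_rng(config.master_seed, 9, p, 1)
        )
        for p in range(n_participants)
    ]


class GridSimulator:
    """Shared per-cohort state for simulating many grid points cheaply.

    Trial sequences are fixed per participant; voxel compositions and
    standard-normal noise fields are fixed per (participant, repetition) and
    rescaled by the sigma-specific calibrated noise SD, so differences
    between grid points reflect the modulation model rather than resampling
    noise.
    """

    def __init__(self, config: RunConfig, seed_tag: int):
        self.cfg = config
        self.space = config.space
        design = config.design
        ms = config.master_seed
        self.tm = make_transition_matrix(design.n_leading, design.reliability)
        # the study inputs: the same stimuli are presented on the same trials
        # to every simulation of a given participant, as in the experiments
        self.stimuli = study_stimuli(config)
        self.sequences = study_sequences(config, config.n_participants)
        self.engines = []
        for p in range(config.n_participants):
            seq = self.sequences[p]
            self.engines.append(
                MetricEngine(seq.trailing, seq.expected, design.n_trailing)
            )
        self.exp_rows = [np.flatnonzero(s.expected) for s in self.sequences]
        self.trail_exp = [
            s.trailing[rows] for s, rows in zip(self.sequences, self.exp_rows)
        ]
        self.comps = {}
        self.pool_w = {}  # (V, 8) pooling weights: counts / neurons-per-voxel
        self.noise_task = {}
        self.noise_loc = {}
        s, reps, v = design.n_trailing, design.n_localizer_reps, config.n_voxels
        for p in range(config.n_participants):
            t = design.n_trials
            for r in range(config.n_repetitions):
                rng_c = participant_rng(ms, 9, seed_tag, p, r, 2)
                comp = sample_voxels(v, rng_c)
                self.comps[p, r] = comp
                w = np.zeros((v, 8))
                np.add.at(w, (np.arange(v)[:, None], comp), 1.0)
                self.pool_w[p, r] = w / comp.shape[1]
                rng_n = participant_rng(ms, 9, seed_tag, p, r, 3)
                self.noise_task[p, r] = rng_n.standard_normal((t, v))
                self.noise_loc[p, r] = rng_n.standard_normal((s, reps, v))
        self._sigma_cache: dict = {}

    def prepare_sigma(self, sigma: float, noise_sd: float) -> dict:
        """Bank, placed stimuli and unmodulated/localizer precomputations."""
        key = (sigma, noise_sd)
        if key in self._sigma_cache:
            return self._sigma_cache[key]
        cfg = self.cfg
        bank = build_bank(self.space, sigma)
        positions = place_positions(bank, self.stimuli.unit_positions)
        pop_un = unmodulated_stimulus_response(bank, positions)
        ctx = {
            "bank": bank,
            "positions": positions,
            "noise_sd": noise_sd,
            "per_rep": {},
        }
        for (p, r), w in self.pool_w.items():
            v_un = w @ pop_un  # (V, S)
            seq = self.sequences[p]
            base = cfg.response_gain * v_un[:, seq.trailing].T
            if noise_sd > 0:
                base = base + noise_sd * self.noise_task[p, r]
            loc = cfg.response_gain * v_un.T[:, None, :] + (
                noise_sd / 2.0
            ) * self.noise_loc[p, r]
            ctx["per_rep"][p, r] = {
                "v_un": v_un,
                "base": base,
                "loc_summary": self.engines[p].localizer_summary(loc),
            }
        self._sigma_cache[key] = ctx
        # keep the cache small: contexts are only needed one sigma at a time
        for k in list(self._sigma_cache):
            if k != key:
                del self._sigma_cache[k]
        return ctx

    def cohort_slopes(self, ctx: dict, model: ModulationModel):
        """(raw, normalized) slope matrices (participants x 7) for one model,
        averaging each participant's repetitions."""
        cfg = self.cfg
        bank, positions, noise_sd = ctx["bank"], ctx["positions"], ctx["noise_sd"]
        pop_mod = modulated_stimulus_response(bank, model, positions)
        n_p = cfg.n_participants
        raw = np.zeros((n_p, len(METRIC_NAMES)))
        norm = np.zeros_like(raw)
        for p in range(n_p):
            exp_rows = self.exp_rows[p]
            trail_exp = self.trail_exp[p]
            for r in range(cfg.n_repetitions):
                rep = ctx["per_rep"][p, r]
                v_mod = self.pool_w[p, r] @ pop_mod
                task = rep["base"].copy()
                task[exp_rows] = cfg.response_gain * v_mod[:, trail_exp].T
                if noise_sd > 0:
                    task[exp_rows] += noise_sd * self.noise_task[p, r][exp_rows]
                mr = self.engines[p].evaluate(task, rep["loc_summary"])
                raw[p] += raw_slopes(mr).as_array()
                norm[p] += normalize_metrics(mr)
        raw /= cfg.n_repetitions
        norm /= cfg.n_repetitions
        return raw, norm


_CALIBRATION_MEMO: dict = {}


def _calibrated_noise(config: RunConfig, sigma: float) -> float:
    """One noise calibration per (ROI, sigma) on a dedicated voxel sample.

    Memoized on the run configuration and sigma *value*, so the generating
    side of a recovery run and the fit grid share one estimated noise level
    for a given sigma.
    """
    key = (
        config.master_seed, config.space_kind, config.design.label,
        config.n_voxels, config.target_accuracy, config.noise_step,
        config.response_gain, config.decoder, round(float(sigma), 12),
    )
    if key in _CALIBRATION_MEMO:
        return _CALIBRATION_MEMO[key]
    space = config.space
    bank = build_bank(space, sigma)
    rng = participant_rng(config.master_seed, 8, int(round(sigma * 1e6)))
    comp = sample_voxels(config.n_voxels, rng)
    positions = place_positions(bank, study_stimuli(config).unit_positions)
    level = calibrate_noise(
        bank,
        comp,
        positions,
        config.target_accuracy,
        rng,
        step=config.noise_step,
        reps=config.design.n_localizer_reps,
        response_gain=config.response_gain,
        decoder=config.decoder,
    )
    _CALIBRATION_MEMO[key] = level.sd
    return level.sd


def _simulate_sigma(config, sims, sigma_index, sigma, point_lists):
    """All grid points of one sigma: returns rows and per-point slope data."""
    noise_sd = _calibrated_noise(config, sigma)
    ctx = sims.prepare_sigma(sigma, noise_sd)
    out = []
    for (op_class, distance), a, b, plausible in point_lists:
        model = ModulationModel(op_class, distance, a=a, b=b)
        row = {
            "op_class": op_class,
            "distance": distance,
            "sigma": sigma,
            "a": a,
            "b": b if b is not None else np.nan,
            "noise_sd": noise_sd,
            "plausible": plausible,
        }
        if plausible:
            raw, norm = sims.cohort_slopes(ctx, model)
        else:
            raw = norm = None
        out.append((row, raw, norm))
    return out


def run_full(
    config: RunConfig,
    empirical: EmpiricalSummary | None = None,
    ground_truth: GroundTruthSpec | None = None,
    families=MODEL_FAMILIES,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the grid, fit to the empirical summary, rank the families.

    Exactly one of ``empirical`` (a prepared summary of real data) or
    ``ground_truth`` (a generating model for pseudo-empirical data) must be
    provided.  Returns the fit table (one row per family x grid point) and
    the ranking report.
    """
    if empirical is None and ground_truth is None:
        raise ValueError("need an empirical summary or a ground-truth spec")
    if empirical is None:
        empirical = pseudo_empirical_summary(ground_truth, config)

    t0 = time.time()
    grid = config.grid
    rej = rejection_table(config.space, grid, families=families, detail=True)
    detail = rej.attrs["detail"]
    plaus = {
        (r.op_class, r.distance, r.sigma, r.a,
         None if pd.isna(r.b) else r.b): bool(r.plausible)
        for r in detail.itertuples()
    }

    sims = GridSimulator(config, seed_tag=1)
    sigma_jobs = []
    for si, sigma in enumerate(grid.sigmas):
        pts = []
        for op_class, distance in families:
            bvals = [None] if distance == "global" else list(grid.b_values)
            for a in grid.a_values:
                for b in bvals:
                    pts.append(
                        ((op_class, distance), a, b,
                         bool(plaus[op_class, distance, sigma, a, b]))
                    )
        sigma_jobs.append((si, sigma, pts))

    results = Parallel(n_jobs=config.n_jobs)(
        delayed(_simulate_sigma)(config, sims, si, sigma, pts)
        for si, sigma, pts in sigma_jobs
    )

    rows, raw_store, norm_store = [], {}, {}
    for chunk in results:
        for row, raw, norm in chunk:
            idx = len(rows)
            rows.append(row)
            if raw is not None:
                raw_store[idx] = raw
                norm_store[idx] = norm
    fit_table = pd.DataFrame(rows)

    emp_mean = empirical.mean
    weights = empirical.weights
    err_rows = np.array(
        [squared_errors(norm_store[i], emp_mean) for i in sorted(norm_store)]
    )
    medians = grand_medians(err_rows)

    mse = np.full(len(fit_table), np.nan)
    matches = np.full(len(fit_table), -1)
    for i in norm_store:
        mse[i] = weighted_mse(norm_store[i], emp_mean, medians, weights)
        matches[i], _ = sign_match(raw_store[i], empirical.raw_signs)
    fit_table["mse"] = mse
    fit_table["sign_matches"] = matches

    ranking = rank_models(
        fit_table,
        sim_slopes=norm_store,
        empirical_mean=emp_mean,
        medians=medians,
        weights=weights,
        top_fraction=config.top_fraction,
        n_boot=config.n_boot,
    )
    ranking["grand_medians"] = medians.tolist()
    ranking["weights"] = weights.tolist()
    ranking["runtime_s"] = round(time.time() - t0, 2)

    if config.out_dir:
        _write_outputs(config, fit_table, ranking, rej)
    return fit_table, ranking


def pseudo_empirical_summary(
    spec: GroundTruthSpec, config: RunConfig
) -> EmpiricalSummary:
    """Summarize ground-truth datasets exactly like an empirical result:
    per-participant normalized slopes (repetitions averaged) and the signs of
    the group-mean raw slopes.

    The study stimuli and trial sequences are shared with the fitting
    simulations (the same stimuli on the same trials); voxel compositions and
    noise are independent, as they would be unknown for real data.
    """
    datasets = generate_ground_truth_dataset(
        spec,
        config.design,
        config.space,
        response_gain=config.response_gain,
        stimuli=study_stimuli(config),
        sequences=study_sequences(config, spec.n_participants),
    )
    norm_rows, raw_rows = [], []
    for reps in datasets:
        norm = np.zeros(len(METRIC_NAMES))
        raw = np.zeros(len(METRIC_NAMES))
        for ds in reps:
            mr = compute_metrics(ds)
            norm += normalize_metrics(mr)
            raw += raw_slopes(mr).as_array()
        norm_rows.append(norm / len(reps))
        raw_rows.append(raw / len(reps))
    slopes = pd.DataFrame(norm_rows, columns=list(METRIC_NAMES))
    signs = np.sign(np.mean(raw_rows, axis=0)).astype(int)
    return EmpiricalSummary(slopes=slopes, raw_signs=signs)


def run_recovery(
    truth: GroundTruthSpec,
    config: RunConfig,
    calibrate: bool = True,
) -> dict:
    """Generate pseudo-empirical data under a known model and re-fit.

    With ``calibrate=True`` the generating noise SD is first calibrated at
    the truth sigma (ignoring ``truth.noise_sd``).  Reports the winning
    family, whether it matches the truth, and the recovery error of the
    winning parameters; flags the unidentifiable a = 1 case and the large-b
    local/global gain equivalence.
    """
    if calibrate:
        truth = replace(truth, noise_sd=_calibrated_noise(config, truth.sigma))
    fit_table, ranking = run_full(config, ground_truth=truth)
    truth_family = f"{truth.model.distance} {truth.model.op_class}"
    winner = ranking["winner"]
    best = ranking["families"][winner]["best_params"]
    report = {
        "truth_family": truth_family,
        "truth_params": {"a": truth.model.a, "b": truth.model.b,
                         "sigma": truth.sigma},
        "noise_sd": truth.noise_sd,
        "winner": winner,
        "recovered": winner == truth_family,
        "winner_params": best,
        "param_error": {
            k: (None if best[k] is None or report_v is None
                else abs(best[k] - report_v))
            for k, report_v in (("a", truth.model.a), ("b", truth.model.b),
                                ("sigma", truth.sigma))
        },
        "ranking": ranking,
    }
    if truth.model.a == 1.0:
        report["unidentifiable_null"] = True
    if truth_family == "global gain" and winner == "local gain":
        wb = best.get("b")
        if wb is not None and wb >= max(config.grid.b_values):
            report["large_b_equivalence"] = True
    return report


def _write_outputs(config, fit_table, ranking, rejection):
    import os

    os.makedirs(config.out_dir, exist_ok=True)
    paths = {}
    fit_path = os.path.join(config.out_dir, "fit_table.csv")
    fit_table.to_csv(fit_path, index=False)
    paths["fit_table"] = fit_path
    rej_path = os.path.join(config.out_dir, "rejections.csv")
    rejection.to_csv(rej_path, index=False)
    paths["rejections"] = rej_path
    rank_path = os.path.join(config.out_dir, "ranking.json")
    with open(rank_path, "w") as fh:
        json.dump(ranking, fh, indent=2)
    paths["ranking"] = rank_path
    manifest = {
        "config": {
            k: (repr(v) if not isinstance(v, (int, float, str, type(None))) else v)
            for k, v in config.__dict__.items()
        },
        "files": {
            name: hashlib.sha256(open(p, "rb").read()).hexdigest()
            for name, p in paths.items()
        },
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
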