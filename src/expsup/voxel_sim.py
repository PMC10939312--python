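"""Simulated voxels: biased pooling of tuned populations, trials and noise.

Each voxel pools a small random sample of the eight tuned populations (eight
draws with replacement, response = mean of the sampled populations), which
yields voxel-level stimulus preferences analogous to biased sampling in real
fMRI.  Additive Gaussian noise is calibrated per (ROI, sigma) so that stimulus
decoding from simulated localizer data matches a target accuracy; localizer
runs receive half the calibrated noise, mirroring their higher SNR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import LinearSVC

from .forward_model import (
    ModulationModel,
    ResponseBank,
    modulated_stimulus_response,
    plausibility_check,
    unmodulated_stimulus_response,
)

__all__ = [
    "NoiseLevel",
    "TrialDataset",
    "sample_voxels",
    "voxel_responses",
    "simulate_responses",
    "simulate_localizer",
    "simulate_dataset",
    "calibrate_noise",
    "decoding_accuracy",
]

#: multiplicative gain mapping normalized responses (peak ~1) to the response
#: scale on which the noise SD advances in steps of 1
DEFAULT_RESPONSE_GAIN = 100.0


@dataclass
class TrialDataset:
    """Trial-wise voxel patterns plus metadata and a localizer.

    ``responses`` is trials x voxels; ``localizer`` stimuli x repetitions x
    voxels (noise SD = ``noise_sd`` / 2).  Works identically for simulated
    and (suitably formatted) empirical data.
    """

    responses: np.ndarray  # (T, V)
    leading: np.ndarray  # (T,)
    trailing: np.ndarray  # (T,)
    expected: np.ndarray  # (T,) bool
    localizer: np.ndarray  # (S, R, V)
    n_stimuli: int
    noise_sd: float = 0.0

    def __post_init__(self):
        t, v = self.responses.shape
        if not (len(self.leading) == len(self.trailing) == len(self.expected) == t):
            raise ValueError("trial metadata length does not match responses")
        if self.localizer.shape[0] != self.n_stimuli or self.localizer.shape[2] != v:
            raise ValueError("localizer shape inconsistent with dataset")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("non-finite trial responses")

    @property
    def n_trials(self) -> int:
        return self.responses.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.responses.shape[1]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Tidy (task, localizer) frames for CSV round-tripping."""
        vox_cols = [f"voxel_{i}" for i in range(self.n_voxels)]
        task = pd.concat(
            [
                pd.DataFrame(
                    {
                        "trial": np.arange(self.n_trials),
                        "leading_id": self.leading,
                        "trailing_id": self.trailing,
                        "expected": self.expected.astype(int),
                    }
                ),
                pd.DataFrame(self.responses, columns=vox_cols),
            ],
            axis=1,
        )
        s, r, v = self.localizer.shape
        loc = pd.concat(
            [
                pd.DataFrame(
                    {
                        "stimulus_id": np.repeat(np.arange(s), r),
                        "repetition": np.tile(np.arange(r), s),
                    }
                ),
                pd.DataFrame(self.localizer.reshape(s * r, v), columns=vox_cols),
            ],
            axis=1,
        )
        return task, loc

    @classmethod
    def from_frames(
        cls, task: pd.DataFrame, loc: pd.DataFrame, noise_sd: float = np.nan
    ) -> "TrialDataset":
        vox_cols = [c for c in task.columns if c.startswith("voxel_")]
        n_stim = int(loc["stimulus_id"].max()) + 1
        n_rep = int(loc["repetition"].max()) + 1
        loc_sorted = loc.sort_values(["stimulus_id", "repetition"])
        return cls(
            responses=task[vox_cols].to_numpy(float),
            leading=task["leading_id"].to_numpy(int),
            trailing=task["trailing_id"].to_numpy(int),
            expected=task["expected"].to_numpy(bool),
            localizer=loc_sorted[vox_cols].to_numpy(float).reshape(
                n_stim, n_rep, len(vox_cols)
            ),
            n_stimuli=n_stim,
            noise_sd=noise_sd,
        )


@dataclass(frozen=True)
class NoiseLevel:
    """Calibrated noise SD and the decoding accuracies that selected it."""

    sd: float
    achieved_accuracy: float
    target_accuracy: float


def sample_voxels(
    n_voxels: int,
    rng: np.random.Generator | int,
    n_populations: int = 8,
    neurons_per_voxel: int = 8,
) -> np.ndarray:
    """Voxel composition: ``neurons_per_voxel`` population indices per voxel,
    drawn uniformly with replacement."""
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    rng = np.random.default_rng(rng)
    return rng.integers(0, n_populations, size=(n_voxels, neurons_per_voxel))


def voxel_responses(composition: np.ndarray, pop_responses: np.ndarray) -> np.ndarray:
    """Noise-free voxel responses (V, S) as the mean of each voxel's sampled
    populations' responses (pop_responses: n_pop x S)."""
    return pop_responses[composition].mean(axis=1)


def simulate_responses(
    composition: np.ndarray,
    bank: ResponseBank,
    model: ModulationModel,
    sequence,
    positions: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator | int,
    response_gain: float = DEFAULT_RESPONSE_GAIN,
    on_implausible: str = "warn",
) -> np.ndarray:
    """Task-trial voxel responses (T, V).

    Trailing-stimulus responses come from the modulated bank on expected
    trials and the unmodulated bank otherwise; iid Gaussian noise of SD
    ``noise_sd`` is added per trial x voxel.  ``on_implausible`` controls the
    reaction to a model failing the plausibility criteria ("warn", "raise",
    or "ignore").
    """
    if on_implausible not in ("warn", "raise", "ignore"):
        raise ValueError("on_implausible must be warn|raise|ignore")
    if on_implausible != "ignore":
        res = plausibility_check(bank, model)
        if not res:
            msg = f"model fails plausibility criterion {res.fail_criterion}"
            if on_implausible == "raise":
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
    rng = np.random.default_rng(rng)
    v_un = voxel_responses(composition, unmodulated_stimulus_response(bank, positions))
    v_mod = voxel_responses(
        composition, modulated_stimulus_response(bank, model, positions)
    )
    trailing = np.asarray(sequence.trailing)
    expected = np.asarray(sequence.expected, dtype=bool)
    clean = np.where(expected[:, None], v_mod[:, trailing].T, v_un[:, trailing].T)
    out = response_gain * clean
    if noise_sd > 0:
        out = out + noise_sd * rng.standard_normal(out.shape)
    return out


def simulate_localizer(
    composition: np.ndarray,
    bank: ResponseBank,
    positions: np.ndarray,
    noise_sd: float,
    reps: int,
    rng: np.random.Generator | int,
    response_gain: float = DEFAULT_RESPONSE_GAIN,
) -> np.ndarray:
    """Expectation-free localizer responses (S, reps, V) with noise SD
    ``noise_sd`` / 2 per the localizer's higher SNR."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(rng)
    v_un = voxel_responses(composition, unmodulated_stimulus_response(bank, positions))
    clean = response_gain * v_un.T[:, None, :]  # (S, 1, V)
    out = np.broadcast_to(
        clean, (len(positions), reps, composition.shape[0])
    ).copy()
    if noise_sd > 0:
        out += (noise_sd / 2.0) * rng.standard_normal(out.shape)
    return out


def simulate_dataset(
    composition,
    bank,
    model,
    sequence,
    positions,
    noise_sd,
    rng,
    localizer_reps: int = 12,
    response_gain: float = DEFAULT_RESPONSE_GAIN,
    on_implausible: str = "warn",
) -> TrialDataset:
    """Convenience wrapper producing a complete TrialDataset."""
    rng = np.random.default_rng(rng)
    task = simulate_responses(
        composition, bank, model, sequence, positions, noise_sd, rng,
        response_gain=response_gain, on_implausible=on_implausible,
    )
    loc = simulate_localizer(
        composition, bank, positions, noise_sd, localizer_reps, rng,
        response_gain=response_gain,
    )
    return TrialDataset(
        responses=task,
        leading=np.asarray(sequence.leading),
        trailing=np.asarray(sequence.trailing),
        expected=np.asarray(sequence.expected, dtype=bool),
        localizer=loc,
        n_stimuli=len(positions),
        noise_sd=noise_sd,
    )


def _decoder(kind: str):
    if kind == "lda":
        return LinearDiscriminantAnalysis()
    if kind == "logistic":
        return LogisticRegression(max_iter=1000)
    if kind == "svm":
        return LinearSVC()
    raise ValueError(f"unknown decoder {kind!r}")


def decoding_accuracy(
    patterns: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 4,
    decoder: str = "lda",
) -> float:
    """Stratified cross-validated multiclass decoding accuracy."""
    cv = StratifiedKFold(n_splits=n_folds, shuffle=False)
    return float(cross_val_score(_decoder(decoder), patterns, labels, cv=cv).mean())


def calibrate_noise(
    bank: ResponseBank,
    composition: np.ndarray,
    positions: np.ndarray,
    target_accuracy: float,
    rng: np.random.Generator | int,
    step: float = 1.0,
    reps: int = 12,
    response_gain: float = DEFAULT_RESPONSE_GAIN,
    decoder: str = "lda",
    max_steps: int = 400,
) -> NoiseLevel:
    """Find the noise SD matching a target decoding accuracy.

    Starting at SD = 0, localizer-style data are simulated and decoded with a
    cross-validated linear classifier; the SD advances in steps of ``step``
    until simulated accuracy drops below ``target_accuracy``; the SD whose
    accuracy was closest to the target is returned.  One calibration per
    (ROI, sigma): the modulation parameters a and b never enter.
    """
    n_stim = len(positions)
    chance = 1.0 / n_stim
    if not chance < target_accuracy <= 1.0:
        raise ValueError("target_accuracy must be in (chance, 1]")
    rng = np.random.default_rng(rng)
    labels = np.repeat(np.arange(n_stim), reps)
    v_un = voxel_responses(composition, unmodulated_stimulus_response(bank, positions))
    clean = response_gain * np.repeat(v_un.T, reps, axis=0)  # (S*reps, V)
    best = None
    sd = 0.0
    for _ in range(max_steps):
        noisy = clean + sd * rng.standard_normal(clean.shape) if sd > 0 else clean
        acc = decoding_accuracy(noisy, labels, decoder=decoder)
        if best is None or abs(acc - target_accuracy) < abs(
            best.achieved_accuracy - target_accuracy
        ):
            best = NoiseLevel(
                sd=sd, achieved_accuracy=acc, target_accuracy=target_accuracy
            )
        if acc < target_accuracy:
            if sd == 0.0:
                warnings.warn(
                    "decoding already below target at sd=0; returning sd=0",
                    stacklevel=2,
                )
            return best
        sd += step
    warnings.warn(
        "noise calibration hit max_steps before crossing target", stacklevel=2
    )
    return best
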