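"""Synthetic study inputs: designs, trial sequences, stimuli, ground truth.

Two probabilistic-association designs are emulated: a 6 x 6 image transition
matrix at 50% reliability over 240 trials, and an 8 x 8 matrix at 56.25%
(9/16) reliability over the 456 analyzed non-oddball trials.  On each trial a
leading image cues one expected trailing image; the trailing image is drawn
from the leading image's transition-matrix row, so the expected image is
several times more likely than any unexpected one (5x at 50% reliability
with six images).

The module also produces ground-truth voxel datasets generated under a known
modulation model, which serve as the recovery oracle for the model-comparison
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_model import (
    FeatureSpace,
    ModulationModel,
    build_bank,
    plausibility_check,
)
from .voxel_sim import TrialDataset, sample_voxels, simulate_dataset

__all__ = [
    "ExperimentDesign",
    "TransitionMatrix",
    "TrialSequence",
    "StimulusSet",
    "GroundTruthSpec",
    "DESIGN_6x6",
    "DESIGN_8x8",
    "make_transition_matrix",
    "sample_trial_sequence",
    "make_synthetic_stimuli",
    "generate_ground_truth_dataset",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Trial-structure parameters of one emulated study."""

    n_leading: int
    n_trailing: int
    reliability: float
    n_trials: int
    n_localizer_reps: int = 12
    label: str = ""

    def __post_init__(self):
        if not 0 < self.reliability <= 1:
            raise ValueError("reliability must be in (0, 1]")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be > 0")
        if self.n_leading != self.n_trailing:
            raise ValueError("designs use matched leading/trailing counts")


DESIGN_6x6 = ExperimentDesign(6, 6, 0.5, 240, label="6x6-50pct")
DESIGN_8x8 = ExperimentDesign(8, 8, 0.5625, 456, label="8x8-56pct")


@dataclass(frozen=True)
class TransitionMatrix:
    """Leading x trailing transition probabilities with expected pairings."""

    probs: np.ndarray
    expected_pairs: np.ndarray  # expected trailing id per leading id

    def __post_init__(self):
        p = self.probs
        if np.any(p < 0):
            raise ValueError("negative transition probability")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        expected_cell = p[np.arange(p.shape[0]), self.expected_pairs]
        if np.any(expected_cell < p.max(axis=1) - 1e-12):
            raise ValueError("expected cell must be the row maximum")

    @property
    def n(self) -> int:
        return self.probs.shape[0]


def make_transition_matrix(n: int, reliability: float) -> TransitionMatrix:
    """Uniform-off-diagonal transition matrix with identity expected pairing.

    The expected cell holds ``reliability``; each of the n - 1 unexpected
    cells holds (1 - reliability) / (n - 1).
    """
    if n < 2:
        raise ValueError("need at least 2 images")
    if not 1.0 / n <= reliability <= 1.0:
        raise ValueError(
            "reliability below 1/n would make the expected image not the most likely"
        )
    off = (1.0 - reliability) / (n - 1)
    probs = np.full((n, n), off)
    np.fill_diagonal(probs, reliability)
    return TransitionMatrix(probs=probs, expected_pairs=np.arange(n))


@dataclass(frozen=True)
class TrialSequence:
    """Per-trial leading/trailing image ids and the expectation flag."""

    leading: np.ndarray
    trailing: np.ndarray
    expected: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.leading)


def sample_trial_sequence(
    design: ExperimentDesign, tm: TransitionMatrix, seed
) -> TrialSequence:
    """Sample one participant's trial sequence.

    Leading images are balanced exactly (round-robin, any remainder going to
    the lowest ids) and then shuffled; trailing images are drawn per the
    leading image's transition-matrix row.  Fully reproducible from ``seed``.
    """
    if tm.n != design.n_leading:
        raise ValueError("transition matrix does not match design")
    rng = np.random.default_rng(seed)
    n, t = design.n_leading, design.n_trials
    base, rem = divmod(t, n)
    counts = np.full(n, base) + (np.arange(n) < rem)
    leading = np.repeat(np.arange(n), counts)
    rng.shuffle(leading)
    cum = tm.probs.cumsum(axis=1)
    u = rng.random(t)
    trailing = (u[:, None] > cum[leading]).sum(axis=1)
    expected = trailing == tm.expected_pairs[leading]
    return TrialSequence(leading=leading, trailing=trailing, expected=expected)


# ---------------------------------------------------------------------------
# stimuli


@dataclass(frozen=True)
class StimulusSet:
    """Stimulus positions (normalized and placed) with optional toy images.

    ``unit_positions`` live on [0, 1) and are mapped into a bank's usable
    (clipped) range with :func:`place_positions`; ``positions`` are placed on
    the raw feature-space range for standalone use.
    """

    unit_positions: np.ndarray
    positions: np.ndarray
    images: list | None = None


def place_positions(bank, unit_positions: np.ndarray) -> np.ndarray:
    """Map unit positions into the stimulus-placeable range of a bank.

    Linear feature positions are only meaningful up to affine rescaling, so
    stimuli are placed inside the clip bounds of each bank; circular
    positions map onto the full orientation circle.
    """
    u = np.asarray(unit_positions, dtype=float)
    if bank.space.kind == "circular":
        return bank.space.lo + u * bank.space.width
    return bank.clip_lo + u * (bank.clip_hi - bank.clip_lo)


def make_grating(theta: float, size: int = 64, frequency: float = 8.0) -> np.ndarray:
    """Oriented sinusoidal grating; ``frequency`` in cycles per image."""
    ax = np.arange(size) - size / 2
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    rot = xx * np.cos(theta) + yy * np.sin(theta)
    return np.cos(2 * np.pi * frequency * rot / size)


def make_blob_silhouette(
    n_protrusions: int, size: int = 96, amplitude: float = 0.25
) -> np.ndarray:
    """Binary star-like silhouette with ``n_protrusions`` protrusions
    (0 = smooth ellipse-like disc)."""
    ax = np.arange(size) - size / 2
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    r = np.hypot(xx, yy)
    phi = np.arctan2(yy, xx)
    base = 0.33 * size
    boundary = base * (
        1.0 + (amplitude * np.cos(n_protrusions * phi) if n_protrusions else 0.0)
    )
    return (r <= boundary).astype(np.uint8)


def make_synthetic_stimuli(
    n: int,
    space: FeatureSpace,
    seed,
    with_images: bool = False,
    image_size: int = 64,
) -> StimulusSet:
    """Stimulus positions covering the space (stratified uniform), with
    optional matching toy images.

    Circular spaces get oriented gratings at the assigned orientation; linear
    spaces get blob silhouettes whose protrusion count grows along the axis
    (a toy shape-complexity continuum).
    """
    if n < 2:
        raise ValueError("need at least 2 stimuli")
    rng = np.random.default_rng(seed)
    # one draw per stratum, kept off stratum edges so positions never collide
    u = (np.arange(n) + 0.05 + 0.9 * rng.random(n)) / n
    positions = space.lo + u * space.width
    images = None
    if with_images:
        if space.kind == "circular":
            images = [make_grating(p, size=image_size) for p in positions]
        else:
            ks = np.round(3 + 7 * u).astype(int)
            images = [make_blob_silhouette(k, size=max(image_size, 96)) for k in ks]
    return StimulusSet(unit_positions=u, positions=positions, images=images)


# ---------------------------------------------------------------------------
# ground-truth datasets (the recovery oracle)


@dataclass(frozen=True)
class GroundTruthSpec:
    """A known generating modulation model plus simulation sizes."""

    model: ModulationModel
    sigma: float
    noise_sd: float
    n_participants: int
    n_repetitions: int
    master_seed: int
    n_voxels: int = 300

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_participants < 1 or self.n_repetitions < 1:
            raise ValueError("need at least one participant and repetition")


def participant_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Counter-derived generator: any (participant, repetition, stream) is
    reproducible in isolation from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, key)]))


def generate_ground_truth_dataset(
    spec: GroundTruthSpec,
    design: ExperimentDesign,
    space: FeatureSpace,
    response_gain: float = 100.0,
    stimuli: StimulusSet | None = None,
    sequences: list[TrialSequence] | None = None,
) -> list[list[TrialDataset]]:
    """Ground-truth voxel datasets per participant (outer) and repetition.

    Expected trials follow ``spec.model``; unexpected trials the unmodulated
    bank; Gaussian noise of ``spec.noise_sd`` is added per trial x voxel and
    half that to the localizer.  The generating model must pass the
    plausibility criteria.  ``stimuli`` / ``sequences`` may be supplied so
    that a fitting pipeline can present the same stimuli on the same trials
    (they default to spec-seeded draws).
    """
    bank = build_bank(space, spec.sigma)
    res = plausibility_check(bank, spec.model)
    if not res:
        raise ValueError(
            f"ground-truth model fails plausibility criterion {res.fail_criterion}"
        )
    tm = make_transition_matrix(design.n_leading, design.reliability)
    if stimuli is None:
        stimuli = make_synthetic_stimuli(
            design.n_trailing, space, participant_rng(spec.master_seed, 0, 0, 0)
        )
    positions = place_positions(bank, stimuli.unit_positions)
    out = []
    for p in range(spec.n_participants):
        if sequences is not None:
            seq = sequences[p]
        else:
            seq = sample_trial_sequence(
                design, tm, participant_rng(spec.master_seed, p, 1)
            )
        reps = []
        for r in range(spec.n_repetitions):
            comp = sample_voxels(
                spec.n_voxels, participant_rng(spec.master_seed, p, r, 2)
            )
            ds = simulate_dataset(
                comp,
                bank,
                spec.model,
                seq,
                positions,
                spec.noise_sd,
                participant_rng(spec.master_seed, p, r, 3),
                localizer_reps=design.n_localizer_reps,
                response_gain=response_gain,
                on_implausible="ignore",  # checked above
            )
            reps.append(ds)
        out.append(reps)
    return out
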