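"""Neural response spaces and expectation-modulation models.

A response bank is a set of eight feature-tuned neural populations covering a
1-D feature space: von Mises (circular-normal) curves on the doubled angle for
the circular orientation space, Gaussians for linear spaces.  Expectation
modulates the bank through one of six models: a gain or a tuning (width)
change, applied locally (populations tuned toward the expected feature),
remotely (tuned away) or globally, with suppression magnitude ``a`` and
distance scale ``b``.  Three biological-plausibility criteria reject
parameterizations producing response "blind spots", implausibly deep
modulation, or untuned populations.

Width convention
----------------
The width parameter sigma of the grid acts as the *squared-width* analogue for
the circular family: the von Mises concentration is ``kappa = 1 / sigma`` on
the doubled angle, so that ``exp(kappa (cos 2d - 1)) ~ exp(-2 d^2 / sigma)``
for small distances.  Linear-space Gaussians use sigma as their standard
deviation.  This convention is what reproduces the tabulated plausibility
rejection rates; see docs/methods.md.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSpace",
    "ModulationModel",
    "ResponseBank",
    "ParameterGrid",
    "PlausibilityResult",
    "MODEL_FAMILIES",
    "build_bank",
    "build_grid",
    "clip_space",
    "modulate",
    "modulated_stimulus_response",
    "plausibility_check",
    "rejection_table",
    "suppression_factor",
]

#: resolution of the discretized feature space, read as a point count
DEFAULT_RESOLUTION = round(180 * np.pi)  # = 565

N_POPULATIONS = 8

#: (op_class, distance) pairs of the six candidate models
MODEL_FAMILIES = [
    ("gain", "global"),
    ("gain", "local"),
    ("gain", "remote"),
    ("tuning", "global"),
    ("tuning", "local"),
    ("tuning", "remote"),
]


@dataclass(frozen=True)
class FeatureSpace:
    """A 1-D stimulus feature space.

    Circular spaces model orientation on [0, pi) with wrap-around distance
    (maximum pi/2); linear spaces are a real interval with absolute distance.
    """

    kind: str  # "circular" | "linear"
    lo: float = 0.0
    hi: float = float(np.pi)
    resolution: int = DEFAULT_RESOLUTION

    def __post_init__(self):
        if self.kind not in ("circular", "linear"):
            raise ValueError(f"unknown feature-space kind {self.kind!r}")
        if self.resolution < 2:
            raise ValueError("resolution must be >= 2")
        if self.kind == "circular" and not (
            np.isclose(self.lo, 0.0) and np.isclose(self.hi, np.pi)
        ):
            raise ValueError("circular feature space must span [0, pi)")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def grid(self) -> np.ndarray:
        if self.kind == "circular":
            return np.linspace(self.lo, self.hi, self.resolution, endpoint=False)
        return np.linspace(self.lo, self.hi, self.resolution)

    def distance(self, x, y) -> np.ndarray:
        """Pairwise-broadcast feature distance between positions."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.kind == "circular":
            d = np.abs(x - y) % np.pi
            return np.minimum(d, np.pi - d)
        return np.abs(x - y)

    @property
    def max_distance(self) -> float:
        return np.pi / 2 if self.kind == "circular" else self.width


@dataclass(frozen=True)
class ModulationModel:
    """One of the six expectation-modulation models.

    ``a`` is the suppression magnitude (a = 1: no modulation, a -> 0: full
    suppression); ``b`` the feature-space distance scale over which the
    modulation falls off (absent for global models).
    """

    op_class: str  # "gain" | "tuning"
    distance: str  # "local" | "remote" | "global"
    a: float
    b: float | None = None

    def __post_init__(self):
        if self.op_class not in ("gain", "tuning"):
            raise ValueError(f"unknown op_class {self.op_class!r}")
        if self.distance not in ("local", "remote", "global"):
            raise ValueError(f"unknown distance function {self.distance!r}")
        if not 0.0 < self.a <= 1.0:
            raise ValueError("a must be in (0, 1]")
        if self.distance == "global":
            if self.b is not None:
                object.__setattr__(self, "b", None)
        elif self.b is None or self.b <= 0:
            raise ValueError("b must be > 0 for local/remote models")

    @property
    def family(self) -> tuple[str, str]:
        return (self.op_class, self.distance)


def suppression_factor(model: ModulationModel, d) -> np.ndarray:
    """Suppression factor c in [a, 1] at feature distance ``d``.

    local:  c = min(1, a + |d/b| (1 - a))   (strongest at d = 0)
    remote: c = max(a, 1 - |d/b| (1 - a))   (strongest far away)
    global: c = a
    """
    d = np.abs(np.asarray(d, dtype=float))
    a = model.a
    if model.distance == "global":
        return np.full_like(d, a)
    ramp = (d / model.b) * (1.0 - a)
    if model.distance == "local":
        return np.minimum(1.0, a + ramp)
    return np.maximum(a, 1.0 - ramp)


def population_curves(
    space: FeatureSpace, mus: np.ndarray, sigma, x: np.ndarray
) -> np.ndarray:
    """Peak-normalized response of each population at positions ``x``.

    ``sigma`` may be scalar or per-(population, position) widths (tuning
    modulation).  Shapes broadcast to (n_populations, len(x)).
    """
    d = space.distance(np.atleast_1d(x)[None, :], np.asarray(mus)[:, None])
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("response width must be > 0")
    if space.kind == "circular":
        # concentration kappa = 1/sigma on the doubled angle; peak = 1 at d = 0
        return np.exp((np.cos(2.0 * d) - 1.0) / sigma)
    return np.exp(-(d**2) / (2.0 * sigma**2))


@dataclass
class ResponseBank:
    """Eight tuned populations and the derived unmodulated response space."""

    space: FeatureSpace
    sigma: float
    mus: np.ndarray
    curves: np.ndarray  # (n_pop, resolution), each peak-normalized to 1
    summed: np.ndarray  # (resolution,) sum over populations
    clip_lo: float
    clip_hi: float
    clip_mask: np.ndarray  # boolean over the grid; all True for circular

    @property
    def norm(self) -> float:
        """Max of the unmodulated summed response within the clipped region."""
        return float(self.summed[self.clip_mask].max())

    @property
    def summed_normalized(self) -> np.ndarray:
        return self.summed / self.norm


def build_bank(
    space: FeatureSpace,
    sigma: float,
    n_populations: int = N_POPULATIONS,
    clip_threshold: float = 0.95,
) -> ResponseBank:
    """Construct the unmodulated neural response space for width ``sigma``.

    Means are evenly spaced: for the circular space, ``n`` points on the
    orientation circle; for linear spaces, spanning the full range inclusive.
    Each population's peak equals 1; linear spaces are clipped to the region
    where the summed response reaches ``clip_threshold`` of its maximum.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if space.kind == "circular":
        mus = space.lo + np.arange(n_populations) * space.width / n_populations
    else:
        mus = np.linspace(space.lo, space.hi, n_populations)
    grid = space.grid
    curves = population_curves(space, mus, sigma, grid)
    summed = curves.sum(axis=0)
    bank = ResponseBank(
        space=space,
        sigma=float(sigma),
        mus=mus,
        curves=curves,
        summed=summed,
        clip_lo=space.lo,
        clip_hi=space.hi,
        clip_mask=np.ones(space.resolution, dtype=bool),
    )
    if space.kind == "linear":
        lo, hi = clip_space(bank, threshold=clip_threshold)
        mask = (grid >= lo) & (grid <= hi)
        bank.clip_lo, bank.clip_hi, bank.clip_mask = lo, hi, mask
    return bank


def clip_space(bank: ResponseBank, threshold: float = 0.95) -> tuple[float, float]:
    """Stimulus-placement bounds of a linear space.

    Returns the outermost positions at which the summed unmodulated response
    reaches ``threshold`` x its maximum.  All stimuli are subsequently placed
    inside these bounds.  No-op for circular spaces.
    """
    if bank.space.kind == "circular":
        return bank.space.lo, bank.space.hi
    s = bank.summed
    ok = s >= threshold * s.max()
    if not ok.any():
        raise ValueError(f"no grid point reaches {threshold:.0%} of the summed maximum")
    idx = np.flatnonzero(ok)
    grid = bank.space.grid
    return float(grid[idx[0]]), float(grid[idx[-1]])


def modulate(
    bank: ResponseBank, model: ModulationModel, expected_position: float
) -> np.ndarray:
    """Modulated response curves (n_pop, resolution) for an expected stimulus.

    Gain models scale each population's curve by c(d(mu_i, x_e)); tuning
    models recompute the curve with width c * sigma (peak unchanged).  The
    modulation applies only when an expected stimulus is actually presented;
    the unmodulated bank describes unexpected trials.
    """
    x_e = float(expected_position)
    if bank.space.kind == "linear" and not (bank.clip_lo <= x_e <= bank.clip_hi):
        raise ValueError(
            f"expected position {x_e:.4f} outside clip bounds "
            f"[{bank.clip_lo:.4f}, {bank.clip_hi:.4f}]"
        )
    c = suppression_factor(model, bank.space.distance(bank.mus, x_e))
    if model.op_class == "gain":
        return c[:, None] * bank.curves
    widths = c * bank.sigma
    return population_curves(bank.space, bank.mus, widths[:, None], bank.space.grid)


def modulated_stimulus_response(
    bank: ResponseBank, model: ModulationModel, positions: np.ndarray
) -> np.ndarray:
    """Population responses (n_pop, n_stim) to *expected* stimuli.

    For a stimulus at x_j, population i responds c(d(mu_i, x_j)) g(x_j) under
    gain modulation or g(x_j; c sigma) under tuning modulation, implementing
    a top-down modulation conditional on the expected stimulus appearing.
    """
    positions = np.atleast_1d(np.asarray(positions, dtype=float))
    d = bank.space.distance(positions[None, :], bank.mus[:, None])
    c = suppression_factor(model, d)
    if model.op_class == "gain":
        g = population_curves(bank.space, bank.mus, bank.sigma, positions)
        return c * g
    widths = c * bank.sigma
    if bank.space.kind == "circular":
        return np.exp((np.cos(2.0 * d) - 1.0) / widths)
    return np.exp(-(d**2) / (2.0 * widths**2))


def unmodulated_stimulus_response(bank: ResponseBank, positions: np.ndarray) -> np.ndarray:
    """Population responses (n_pop, n_stim) to unexpected (unmodulated) stimuli."""
    positions = np.atleast_1d(np.asarray(positions, dtype=float))
    return population_curves(bank.space, bank.mus, bank.sigma, positions)


# ---------------------------------------------------------------------------
# biological-plausibility criteria


@dataclass(frozen=True)
class PlausibilityResult:
    passed: bool
    fail_criterion: int | None = None  # 1, 2 or 3

    def __bool__(self) -> bool:
        return self.passed


def _criterion1(bank: ResponseBank, threshold: float = 0.75) -> bool:
    """Fail if the summed unmodulated response dips below ``threshold`` x its
    maximum anywhere a stimulus can be placed (blind spots)."""
    s = bank.summed[bank.clip_mask]
    return bool(s.min() < threshold * s.max())


def _criterion3(bank: ResponseBank, threshold: float = 0.75) -> bool:
    """Fail if any population still responds above ``threshold`` of its peak
    half pi away from its mean (implausibly untuned)."""
    if bank.space.kind == "circular":
        resp = np.exp(-2.0 / bank.sigma)  # cos(2 * pi/2) - 1 = -2
    else:
        resp = np.exp(-((np.pi / 2) ** 2) / (2.0 * bank.sigma**2))
    return bool(resp > threshold)


def _min_modulated_response(
    bank: ResponseBank,
    model: ModulationModel,
    expected_idx: np.ndarray | None = None,
) -> float:
    """Min over probe positions (within clip) and candidate expected positions
    (full grid) of the modulated summed response.

    For the circular space, candidate expected positions are reduced to one
    lattice period of the population means, which is exact by symmetry.
    """
    space = bank.space
    grid = space.grid
    if expected_idx is None:
        if space.kind == "circular":
            n_per = space.resolution // N_POPULATIONS + 1
            expected_idx = np.arange(n_per)
        else:
            expected_idx = np.arange(space.resolution)
    x_e = grid[expected_idx]
    d_e = space.distance(x_e[None, :], bank.mus[:, None])  # (n_pop, n_e)
    c = suppression_factor(model, d_e)
    probe = bank.clip_mask
    if model.op_class == "gain":
        m = c.T @ bank.curves[:, probe]  # (n_e, n_probe)
        return float(m.min())
    widths = np.maximum(c * bank.sigma, 1e-12)  # (n_pop, n_e)
    d_probe = space.distance(grid[probe][None, :], bank.mus[:, None])  # (n_pop, n_probe)
    if space.kind == "circular":
        m = np.exp((np.cos(2.0 * d_probe[:, None, :]) - 1.0) / widths[:, :, None])
    else:
        m = np.exp(-(d_probe[:, None, :] ** 2) / (2.0 * widths[:, :, None] ** 2))
    return float(m.sum(axis=0).min())


def _criterion2(
    bank: ResponseBank, model: ModulationModel, threshold: float = 0.10
) -> bool:
    """Fail if, for some expected position, the modulated summed response falls
    below ``threshold`` x the maximal unmodulated summed response anywhere a
    stimulus can be placed (de-facto blindness to expected features)."""
    return _min_modulated_response(bank, model) < threshold * bank.norm


def plausibility_check(bank: ResponseBank, model: ModulationModel) -> PlausibilityResult:
    """Apply the three response requirements; report the first failing one.

    1. the unmodulated summed response covers feature space uniformly enough
       (>= 75% of its maximum everywhere stimuli are placed);
    2. the modulated summed response to any expected stimulus stays above 10%
       of the unmodulated maximum;
    3. populations are feature selective (< 75% of peak at distance pi/2).
    """
    for crit, fails in (
        (1, lambda: _criterion1(bank)),
        (2, lambda: _criterion2(bank, model)),
        (3, lambda: _criterion3(bank)),
    ):
        if fails():
            return PlausibilityResult(False, crit)
    return PlausibilityResult(True, None)


# ---------------------------------------------------------------------------
# parameter grid


DEFAULT_SIGMAS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
                  1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0)
DEFAULT_A_VALUES = tuple(np.round(np.arange(1, 21) * 0.05, 2))
DEFAULT_B_VALUES = tuple(np.round(np.arange(1, 24) * 0.1, 1))


@dataclass(frozen=True)
class ParameterGrid:
    """Cartesian parameter grid; ``b`` is dropped for global models."""

    sigmas: tuple = DEFAULT_SIGMAS
    a_values: tuple = DEFAULT_A_VALUES
    b_values: tuple = DEFAULT_B_VALUES

    def __post_init__(self):
        if not (len(self.sigmas) and len(self.a_values) and len(self.b_values)):
            raise ValueError("grid value lists must be non-empty")

    @property
    def size(self) -> int:
        """Grid size for the local/remote families."""
        return len(self.sigmas) * len(self.a_values) * len(self.b_values)

    def family_size(self, distance: str) -> int:
        if distance == "global":
            return len(self.sigmas) * len(self.a_values)
        return self.size

    def top_k(self, fraction: float = 0.02, distance: str = "local") -> int:
        return int(np.floor(fraction * self.family_size(distance)))

    def models(self, op_class: str, distance: str):
        """Iterate ModulationModel instances of one family."""
        if distance == "global":
            for a in self.a_values:
                yield ModulationModel(op_class, distance, a=a)
        else:
            for a, b in itertools.product(self.a_values, self.b_values):
                yield ModulationModel(op_class, distance, a=a, b=b)

    def points(self, op_class: str, distance: str):
        """Iterate (sigma, model) pairs of one family."""
        for sigma in self.sigmas:
            for m in self.models(op_class, distance):
                yield sigma, m


def build_grid(config: dict | None = None) -> ParameterGrid:
    """Build the parameter grid (defaults: 17 sigma x 20 a x 23 b = 7820)."""
    config = config or {}
    return ParameterGrid(
        sigmas=tuple(config.get("sigmas", DEFAULT_SIGMAS)),
        a_values=tuple(config.get("a_values", DEFAULT_A_VALUES)),
        b_values=tuple(config.get("b_values", DEFAULT_B_VALUES)),
    )


# ---------------------------------------------------------------------------
# bulk rejection table


def _first_passing_a(bank, op_class, distance, a_values, b) -> int:
    """Index of the smallest ``a`` passing criterion 2 at fixed (sigma, b).

    The minimum modulated response is nondecreasing in ``a`` (both suppression
    branches increase with a, and curve height increases with width), so the
    criterion-2 failure set is a prefix of the sorted a values and can be
    found by bisection.
    """
    lo, hi = 0, len(a_values)
    while lo < hi:
        mid = (lo + hi) // 2
        m = ModulationModel(op_class, distance, a=a_values[mid], b=b)
        if _criterion2(bank, m):
            lo = mid + 1
        else:
            hi = mid
    return lo


def rejection_table(
    space: FeatureSpace,
    grid: ParameterGrid | None = None,
    families=MODEL_FAMILIES,
    detail: bool = False,
) -> pd.DataFrame:
    """Plausibility rejection rates per model family over the full grid.

    Returns one row per family with columns ``op_class, distance, n_total,
    n_rejected, pct_rejected``.  With ``detail=True`` an additional
    per-combination frame is attached as ``.attrs["detail"]`` listing
    ``plausible`` and the first failing criterion for every grid point.

    Rates are exact: the bulk path exploits monotonicity of the minimum
    modulated response in ``a`` (bisection per (sigma, b)); ``detail`` falls
    back to per-point evaluation of criterion 2 where needed.
    """
    grid = grid or build_grid()
    a_values = sorted(grid.a_values)
    rows = []
    detail_rows = []
    banks = {s: build_bank(space, s) for s in grid.sigmas}
    for op_class, distance in families:
        b_values = [None] if distance == "global" else list(grid.b_values)
        n_tot = n_rej = 0
        for sigma in grid.sigmas:
            bank = banks[sigma]
            fail1 = _criterion1(bank)
            fail3 = _criterion3(bank)
            for b in b_values:
                n_tot += len(a_values)
                if fail1 or fail3:
                    n_rej += len(a_values)
                    if detail:
                        for a in a_values:
                            crit = 1 if fail1 else (
                                2 if _criterion2(
                                    bank, ModulationModel(op_class, distance, a=a, b=b)
                                ) else 3
                            )
                            detail_rows.append(
                                (op_class, distance, sigma, a, b, False, crit)
                            )
                    continue
                k = _first_passing_a(bank, op_class, distance, a_values, b)
                n_rej += k
                if detail:
                    for i, a in enumerate(a_values):
                        detail_rows.append(
                            (op_class, distance, sigma, a, b, i >= k,
                             2 if i < k else None)
                        )
        rows.append(
            {
                "op_class": op_class,
                "distance": distance,
                "n_total": n_tot,
                "n_rejected": n_rej,
                "pct_rejected": 100.0 * n_rej / n_tot,
            }
        )
    table = pd.DataFrame(rows)
    if detail:
        table.attrs["detail"] = pd.DataFrame(
            detail_rows,
            columns=["op_class", "distance", "sigma", "a", "b",
                     "plausible", "fail_criterion"],
        )
    return table
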