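"""Model comparison: sign matching and weighted-MSE grid ranking.

Simulated outcome metrics are compared to an empirical summary in two ways.
Qualitatively, the sign of each simulated metric's slope (when significantly
different from zero across simulated participants) is matched against the
empirical sign, giving a 0-7 match count per parameterization.
Quantitatively, normalized slopes enter a weighted MSE: squared errors per
metric are scaled by their grand median across all model types and plausible
parameterizations (so each metric contributes comparably), then averaged with
weights proportional to the inverse normalized SD (SD/|mean|) of the
empirical metric across participants, discounting unreliable metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import METRIC_NAMES, MetricResult

__all__ = [
    "EmpiricalSummary",
    "normalize_metrics",
    "sign_match",
    "squared_errors",
    "grand_medians",
    "weighted_mse",
    "rank_models",
    "best_parameter_summary",
]

#: ratio metrics are normalized per condition by the metric's unexpected
#: (unmodulated) value; ranked metrics divide suppression by the mean
#: unmodulated response amplitude
RATIO_METRICS = ("MAM", "WC", "BC", "CP")
RANKED_METRICS = ("AMA", "AMS", "IP")


def normalize_metrics(mr: MetricResult) -> np.ndarray:
    """Normalized slope per metric (order: METRIC_NAMES).

    MAM/WC/BC/CP: (expected - unexpected) / unexpected value of the metric
    (for MAM, the suppression relative to the mean unmodulated amplitude);
    AMA/AMS/IP: raw slope divided by the mean unmodulated amplitude.
    Normalization makes slopes scale-invariant: multiplying all responses by
    a constant leaves them unchanged.
    """
    ref_amp = mr.mean_unexpected
    if ref_amp == 0:
        raise ValueError("zero unmodulated reference amplitude")
    out = {}
    out["MAM"] = mr.mam / ref_amp
    for name, vals in (("WC", mr.wc), ("BC", mr.bc), ("CP", mr.cp)):
        ref = vals["unexpected"]
        if ref == 0:
            raise ValueError(f"zero unmodulated reference for {name}")
        out[name] = (vals["expected"] - vals["unexpected"]) / ref
    for name, slope in (("AMA", mr.ama_slope), ("AMS", mr.ams_slope),
                        ("IP", mr.ip_slope)):
        out[name] = slope / ref_amp
    return np.array([out[m] for m in METRIC_NAMES])


@dataclass
class EmpiricalSummary:
    """Per-participant normalized slopes plus raw slope signs of the
    empirical (or pseudo-empirical) result."""

    slopes: pd.DataFrame  # participants x METRIC_NAMES, normalized
    raw_signs: np.ndarray  # (7,) in {-1, 0, +1}

    def __post_init__(self):
        missing = set(METRIC_NAMES) - set(self.slopes.columns)
        if missing:
            raise ValueError(f"missing metrics in empirical summary: {missing}")
        if len(self.slopes) < 2:
            raise ValueError("need at least 2 participants")
        self.slopes = self.slopes[list(METRIC_NAMES)]
        self.raw_signs = np.asarray(self.raw_signs, dtype=int)

    @property
    def mean(self) -> np.ndarray:
        return self.slopes.mean(axis=0).to_numpy()

    @property
    def sd(self) -> np.ndarray:
        return self.slopes.std(axis=0, ddof=1).to_numpy()

    @property
    def weights(self) -> np.ndarray:
        """Inverse normalized SD per metric, normalized to sum to 1."""
        mean, sd = self.mean, self.sd
        with np.errstate(divide="ignore"):
            w = np.abs(mean) / sd
        w[~np.isfinite(w)] = 0.0
        if w.sum() == 0:
            raise ValueError("degenerate empirical summary: all weights zero")
        return w / w.sum()


def sign_match(
    sim_raw_slopes: np.ndarray,
    empirical_signs: np.ndarray,
    alpha: float = 0.05,
) -> tuple[int, np.ndarray]:
    """Count metrics whose simulated slope sign matches the empirical sign.

    A metric matches iff its slope distribution across simulated participants
    differs significantly from zero (two-sided one-sample t-test at
    ``alpha``) and the sign of its mean equals the empirical sign.  Metrics
    with empirical sign 0 are excluded with a warning.
    """
    sim = np.asarray(sim_raw_slopes, dtype=float)
    if sim.ndim != 2 or sim.shape[0] < 2:
        raise ValueError("need slopes for at least 2 simulated participants")
    signs = np.asarray(empirical_signs, dtype=int)
    matched = np.zeros(sim.shape[1], dtype=bool)
    for m in range(sim.shape[1]):
        if signs[m] == 0:
            warnings.warn(
                f"empirical sign of {METRIC_NAMES[m]} is 0; metric excluded",
                stacklevel=2,
            )
            continue
        col = sim[:, m]
        if np.allclose(col, col[0]):
            continue  # degenerate distribution: never significant
        t, p = stats.ttest_1samp(col, 0.0)
        matched[m] = (p < alpha) and (np.sign(col.mean()) == signs[m])
    return int(matched.sum()), matched


def squared_errors(sim_norm_slopes: np.ndarray, empirical_mean: np.ndarray) -> np.ndarray:
    """(metrics,) squared error of the simulated cohort-mean normalized
    slopes against the empirical group mean."""
    sim = np.asarray(sim_norm_slopes, dtype=float)
    return (sim.mean(axis=0) - np.asarray(empirical_mean)) ** 2


def grand_medians(error_table: np.ndarray) -> np.ndarray:
    """Grand median per metric of the squared errors across all model types
    and plausible parameterizations."""
    err = np.asarray(error_table, dtype=float)
    return np.median(err, axis=0)


def weighted_mse(
    sim_norm_slopes: np.ndarray,
    empirical_mean: np.ndarray,
    medians: np.ndarray,
    weights: np.ndarray,
    participant_idx: np.ndarray | None = None,
) -> float:
    """Weighted MSE for one parameterization.

    ``sim_norm_slopes`` is (participants x metrics); the cohort mean slope
    (optionally over a bootstrap resample of participants) is compared to the
    empirical group mean per metric, squared errors are scaled by the grand
    medians and combined with the normalized weights.  Metrics with a zero
    grand median are dropped with a warning.
    """
    sim = np.asarray(sim_norm_slopes, dtype=float)
    if participant_idx is not None:
        sim = sim[participant_idx]
    err = (sim.mean(axis=0) - np.asarray(empirical_mean, dtype=float)) ** 2
    medians = np.asarray(medians, dtype=float)
    weights = np.asarray(weights, dtype=float)
    ok = medians > 0
    if not ok.all():
        dropped = [METRIC_NAMES[i] for i in np.flatnonzero(~ok)]
        warnings.warn(f"zero grand median; dropping metrics {dropped}", stacklevel=2)
    w = np.where(ok, weights, 0.0)
    if w.sum() == 0:
        raise ValueError("no metric left after dropping zero-median metrics")
    w = w / w.sum()
    scaled = np.where(ok, err / np.where(ok, medians, 1.0), 0.0)
    return float((w * scaled).sum())


_SORT_COLS = ["mse", "op_class", "distance", "a", "b", "sigma"]


def _family_key(op_class: str, distance: str) -> str:
    return f"{distance} {op_class}"


def rank_models(
    fit_table: pd.DataFrame,
    sim_slopes: dict | None = None,
    empirical_mean: np.ndarray | None = None,
    medians: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    top_fraction: float = 0.02,
    n_boot: int = 10000,
    rng: np.random.Generator | int | None = 0,
) -> dict:
    """Rank model families by weighted MSE.

    ``fit_table`` holds one row per (family, grid point) with columns
    op_class, distance, a, b, sigma, mse, sign_matches, plausible.  Only
    plausible rows are ranked.  Per family the report gives the best fit, the
    sorted top-``top_fraction`` MSEs and their mean, and (when per-point
    normalized ``sim_slopes`` keyed by fit_table index are provided) 95%
    bootstrap CIs of the best MSE across simulated participants.  The winner
    is the family with the smallest best MSE; ties break deterministically
    by family name and parameters.
    """
    rng = np.random.default_rng(rng)
    report: dict = {"families": {}}
    plausible = fit_table[fit_table["plausible"]].copy()
    best_rows = []
    for (op_class, distance), grp in fit_table.groupby(
        ["op_class", "distance"], sort=True
    ):
        fam = _family_key(op_class, distance)
        g = grp[grp["plausible"]].sort_values(_SORT_COLS, na_position="first")
        if g.empty:
            report["families"][fam] = {"fit": False}
            continue
        k = max(1, int(np.floor(top_fraction * len(grp))))
        top = g.head(k)
        best = g.iloc[0]
        entry = {
            "fit": True,
            "best_mse": float(best["mse"]),
            "best_params": {
                "a": float(best["a"]),
                "b": None if pd.isna(best["b"]) else float(best["b"]),
                "sigma": float(best["sigma"]),
            },
            "top_k": top["mse"].to_list(),
            "top_k_mean": float(top["mse"].mean()),
            "max_sign_matches": int(grp.loc[grp["plausible"], "sign_matches"].max()),
        }
        if sim_slopes is not None and best.name in sim_slopes:
            sl = sim_slopes[best.name]
            n_p = sl.shape[0]
            boots = np.empty(n_boot)
            for i in range(n_boot):
                idx = rng.integers(0, n_p, n_p)
                boots[i] = weighted_mse(
                    sl, empirical_mean, medians, weights, participant_idx=idx
                )
            entry["best_mse_ci95"] = [
                float(np.percentile(boots, 2.5)),
                float(np.percentile(boots, 97.5)),
            ]
        report["families"][fam] = entry
        best_rows.append((float(best["mse"]), fam, entry))
    if not best_rows:
        raise ValueError("no plausible parameterization in any family")
    best_rows.sort(key=lambda r: (r[0], r[1]))
    winner_mse, winner, winner_entry = best_rows[0]
    report["winner"] = winner
    report["winner_mse"] = winner_mse
    # robustness: does the winner's entire top-k beat every competitor's top-k?
    w_top_max = max(winner_entry["top_k"])
    robust = all(
        w_top_max < min(e["top_k"])
        for _, fam, e in best_rows[1:]
        if e.get("fit")
    )
    report["winner_topk_dominates"] = bool(robust)
    report["n_plausible"] = int(len(plausible))
    return report


def best_parameter_summary(
    fit_table: pd.DataFrame, top_fraction: float = 0.02
) -> pd.DataFrame:
    """Distribution of (a, b, sigma) among each family's top-k fits."""
    rows = []
    for (op_class, distance), grp in fit_table.groupby(
        ["op_class", "distance"], sort=True
    ):
        g = grp[grp["plausible"]].sort_values(_SORT_COLS, na_position="first")
        if g.empty:
            continue
        k = max(1, int(np.floor(top_fraction * len(grp))))
        top = g.head(k)
        for param in ("a", "b", "sigma"):
            vals = top[param].dropna()
            if vals.empty:
                rows.append(
                    {"op_class": op_class, "distance": distance, "param": param,
                     "applicable": False}
                )
                continue
            counts = vals.value_counts()
            rows.append(
                {
                    "op_class": op_class,
                    "distance": distance,
                    "param": param,
                    "applicable": True,
                    "mode": float(counts.idxmax()),
                    "min": float(vals.min()),
                    "q25": float(vals.quantile(0.25)),
                    "median": float(vals.median()),
                    "q75": float(vals.quantile(0.75)),
                    "max": float(vals.max()),
                }
            )
    return pd.DataFrame(rows)
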