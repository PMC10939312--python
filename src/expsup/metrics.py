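"""The seven fMRI outcome metrics.

All metrics are computed identically for simulated and empirical trial-wise
pattern data:

* MAM  - mean amplitude modulation: mean(unexpected) - mean(expected), the
         expectation-suppression effect itself.
* WC   - within-class correlation between each stimulus's expectation-free
         localizer pattern and its condition-mean task pattern.
* BC   - between-class correlation: same, against the other stimuli's task
         patterns.
* CP   - classification performance, defined here as BC - WC.
* AMA  - amplitude modulation by amplitude: voxel-wise suppression binned by
         localizer responsiveness (10 bins), summarized by the OLS slope.
* AMS  - amplitude modulation by selectivity: suppression binned by voxel
         selectivity (slope of localizer response over within-voxel stimulus
         amplitude rank), 10 bins + slope.
* IP   - image preference: within-voxel suppression per localizer preference
         rank; slope oriented so that positive means more suppression for
         more preferred images.

Slope sign conventions (used for sign matching): two-condition metrics use
expected minus unexpected (MAM uses unexpected minus expected, i.e. the
suppression difference); AMA/AMS slopes run over increasing bin rank; the IP
slope over increasing preference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .voxel_sim import TrialDataset

__all__ = [
    "METRIC_NAMES",
    "MetricResult",
    "SlopeSet",
    "MetricEngine",
    "compute_metrics",
    "raw_slopes",
]

METRIC_NAMES = ("MAM", "WC", "BC", "CP", "AMA", "AMS", "IP")

CONDITIONS = ("unexpected", "expected")


@dataclass
class MetricResult:
    """Per-participant outcome-metric values."""

    mam: float
    wc: dict
    bc: dict
    cp: dict
    ama_bins: np.ndarray
    ama_slope: float
    ams_bins: np.ndarray
    ams_slope: float
    ip_values: np.ndarray  # index 0 = most preferred image
    ip_slope: float
    mean_unexpected: float  # average unmodulated response amplitude


@dataclass(frozen=True)
class SlopeSet:
    """The seven per-participant slopes, keyed by metric name."""

    values: dict

    def as_array(self) -> np.ndarray:
        return np.array([self.values[m] for m in METRIC_NAMES], dtype=float)

    def __getitem__(self, key):
        return self.values[key]


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    vx = x - x.mean()
    den = (vx**2).sum()
    if den == 0:
        return 0.0
    return float((vx * (y - y.mean())).sum() / den)


def _bin_slices(n: int, n_bins: int) -> list[slice]:
    """Equal-count bins; remainder items go to the lower bins."""
    base, rem = divmod(n, n_bins)
    sizes = [base + (i < rem) for i in range(n_bins)]
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [slice(edges[i], edges[i + 1]) for i in range(n_bins)]


def _zscore_rows(x: np.ndarray, what: str) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    bad = np.flatnonzero(sd[:, 0] == 0)
    if bad.size:
        raise ValueError(f"zero-variance pattern for {what} {bad[0]}")
    return (x - mu) / sd


class MetricEngine:
    """Precomputed trial bookkeeping for repeated metric evaluation.

    The grid search evaluates thousands of simulated datasets that share one
    trial sequence per participant; the engine precomputes the condition /
    stimulus averaging weights once, and splits localizer-derived features
    (rankings, binnings) from the task-dependent computation, because the
    localizer depends only on the unmodulated bank.
    """

    def __init__(self, trailing, expected, n_stimuli: int, n_bins: int = 10,
                 cp_sign: int = 1):
        if cp_sign not in (1, -1):
            raise ValueError("cp_sign must be +1 (BC - WC) or -1 (WC - BC)")
        self.cp_sign = cp_sign
        trailing = np.asarray(trailing)
        expected = np.asarray(expected, dtype=bool)
        self.n_stimuli = int(n_stimuli)
        self.n_bins = n_bins
        self.t = len(trailing)
        if not expected.any() or expected.all():
            raise ValueError("both expectation conditions must be present")
        # per (condition, stimulus) averaging weights, (2, S, T)
        self.w_cs = np.zeros((2, self.n_stimuli, self.t))
        self.valid = np.zeros((2, self.n_stimuli), dtype=bool)
        for c, mask in enumerate((~expected, expected)):
            for s in range(self.n_stimuli):
                sel = mask & (trailing == s)
                if sel.any():
                    self.w_cs[c, s, sel] = 1.0 / sel.sum()
                    self.valid[c, s] = True
        self._w_flat = self.w_cs.reshape(2 * self.n_stimuli, self.t)
        self._bin_edges = {}

    # -- localizer-derived features (independent of the modulation model) ----

    def localizer_summary(self, localizer: np.ndarray) -> dict:
        if localizer.shape[2] < self.n_bins:
            raise ValueError(f"need at least {self.n_bins} voxels for binning")
        lm = localizer.mean(axis=1)  # (S, V)
        lz = _zscore_rows(lm, "localizer stimulus")
        amp = lm.mean(axis=0)  # (V,)
        amp_order = np.argsort(amp, kind="stable")
        # selectivity: OLS slope of localizer response on within-voxel
        # amplitude rank of the images (flat voxels get slope 0)
        ranks = rankdata(lm, axis=0)  # (S, V), ascending
        vr = ranks - ranks.mean(axis=0)
        den = (vr**2).sum(axis=0)
        num = (vr * (lm - lm.mean(axis=0))).sum(axis=0)
        sel = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        sel_order = np.argsort(sel, kind="stable")
        # preference: stimulus index per (voxel, rank), rank 0 = most preferred
        pref_idx = np.argsort(-lm.T, axis=1, kind="stable")  # (V, S)
        return {
            "lz": lz,
            "amp_order": amp_order,
            "sel": sel,
            "sel_order": sel_order,
            "pref_idx": pref_idx,
        }

    # -- task-dependent evaluation -------------------------------------------

    def evaluate(self, task: np.ndarray, loc: dict, n_bins: int | None = None) -> MetricResult:
        n_bins = n_bins or self.n_bins
        n_vox = task.shape[1]
        # condition-mean stimulus patterns, (2, S, V): unexpected, expected
        gm = (self._w_flat @ task).reshape(2, self.n_stimuli, n_vox)
        # stimulus-balanced condition means: average per stimulus first, so
        # the unequal stimulus composition of the two conditions (expected
        # trailing images repeat their pairing more often) cannot masquerade
        # as an amplitude modulation
        both = self.valid.all(axis=0)
        cond_mean = gm[:, both, :].mean(axis=1)  # (2, V)
        mam = float(cond_mean[0].mean() - cond_mean[1].mean())
        mean_unexpected = float(cond_mean[0].mean())
        wc, bc, cp = {}, {}, {}
        lz = loc["lz"]
        for c, name in enumerate(CONDITIONS):
            val = self.valid[c]
            tz = _zscore_rows(gm[c][val], f"{name} stimulus")
            r = lz[val] @ tz.T / n_vox  # (S_valid, S_valid)
            nv = val.sum()
            if nv < 2:
                raise ValueError("need at least 2 stimuli per condition")
            wc[name] = float(np.trace(r) / nv)
            bc[name] = float((r.sum() - np.trace(r)) / (nv * (nv - 1)))
            # default convention BC - WC; cp_sign = -1 gives the
            # accuracy-style WC - BC instead
            cp[name] = self.cp_sign * (bc[name] - wc[name])

        # voxel-wise suppression
        supp_v = cond_mean[0] - cond_mean[1]  # (V,)
        key = (n_vox, n_bins)
        if key not in self._bin_edges:
            sizes = np.array(
                [sl.stop - sl.start for sl in _bin_slices(n_vox, n_bins)]
            )
            self._bin_edges[key] = (
                np.concatenate([[0], np.cumsum(sizes)[:-1]]), sizes
            )
        starts, sizes = self._bin_edges[key]
        xb = np.arange(1, n_bins + 1)

        ama_bins = np.add.reduceat(supp_v[loc["amp_order"]], starts) / sizes
        ama_slope = _ols_slope(xb, ama_bins)

        ams_bins = np.add.reduceat(supp_v[loc["sel_order"]], starts) / sizes
        ams_slope = _ols_slope(xb, ams_bins)

        # image preference: per-(voxel, stimulus) suppression gathered by rank
        supp_vs = (gm[0] - gm[1]).T  # (V, S)
        gathered = np.take_along_axis(supp_vs, loc["pref_idx"], axis=1)  # (V, S)
        if both.all():
            ip_values = gathered.mean(axis=0)
        else:
            supp_vs[:, ~both] = np.nan  # stimuli missing a condition skipped
            gathered = np.take_along_axis(supp_vs, loc["pref_idx"], axis=1)
            with np.errstate(invalid="ignore"):
                ip_values = np.nanmean(gathered, axis=0)
        pref_score = np.arange(self.n_stimuli, 0, -1)  # high = preferred
        ip_slope = _ols_slope(pref_score, ip_values)

        return MetricResult(
            mam=mam,
            wc=wc,
            bc=bc,
            cp=cp,
            ama_bins=ama_bins,
            ama_slope=ama_slope,
            ams_bins=ams_bins,
            ams_slope=ams_slope,
            ip_values=ip_values,
            ip_slope=ip_slope,
            mean_unexpected=mean_unexpected,
        )


def compute_metrics(ds: TrialDataset, n_bins: int = 10,
                    cp_sign: int = 1) -> MetricResult:
    """Compute all seven outcome metrics for one dataset.

    ``cp_sign`` selects the classification-performance convention:
    +1 for BC - WC (default), -1 for the accuracy-style WC - BC.
    """
    eng = MetricEngine(ds.trailing, ds.expected, ds.n_stimuli, n_bins=n_bins,
                       cp_sign=cp_sign)
    return eng.evaluate(ds.responses, eng.localizer_summary(ds.localizer))


def raw_slopes(mr: MetricResult) -> SlopeSet:
    """Reduce a MetricResult to the seven per-participant slopes."""
    return SlopeSet(
        values={
            "MAM": mr.mam,
            "WC": mr.wc["expected"] - mr.wc["unexpected"],
            "BC": mr.bc["expected"] - mr.bc["unexpected"],
            "CP": mr.cp["expected"] - mr.cp["unexpected"],
            "AMA": mr.ama_slope,
            "AMS": mr.ams_slope,
            "IP": mr.ip_slope,
        }
    )
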