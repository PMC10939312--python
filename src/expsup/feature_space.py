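"""ROI feature spaces: construction from stimuli and RSA validation.

Three 1-D stimulus descriptors are supported: predominant orientation from a
Gabor energy bank (circular, for early visual cortex), shape complexity from
six silhouette metrics reduced by PCA (linear, object-selective cortex), and
a similarity axis extracted from a dissimilarity matrix by 1-D classical MDS
(linear, higher ventral regions).  RDM machinery (model and neural RDMs,
partial-Spearman RSA with controls, bootstrap/Mantel feature-space
comparison) validates the spaces.

Orientation convention: 0 is horizontal, angles increase counter-clockwise,
period pi.  Energy ties break toward the smallest angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import MultiPoint
from shapely import minimum_bounding_radius
from scipy.signal import fftconvolve
from skimage import measure
from skimage.filters import gabor_kernel
from skimage.morphology import convex_hull_image
from sklearn.decomposition import PCA

from .forward_model import FeatureSpace

__all__ = [
    "ShapeMetrics",
    "gabor_orientation_energy",
    "shape_complexity",
    "pca_first_component",
    "mds_1d",
    "model_rdm",
    "neural_rdm",
    "rsa_validate",
    "compare_feature_spaces",
]


# ---------------------------------------------------------------------------
# orientation feature space


def gabor_orientation_energy(
    image: np.ndarray,
    orientation_step_deg: float = 20.0,
    wavelength_short: float | None = None,
    wavelength_long: float | None = None,
    n_frequencies: int = 8,
) -> float:
    """Predominant orientation of an image in radians, in [0, pi).

    Quadrature-pair Gabor energy is summed over the image for each candidate
    orientation (multiples of ``orientation_step_deg``) and averaged over a
    geometric ladder of ``n_frequencies`` spatial scales with wavelengths
    between ``wavelength_short`` (default 4/sqrt(2) pixels, just above the
    Nyquist period) and ``wavelength_long`` (default the image diagonal in
    pixels).  Returns the energy-argmax orientation; exact ties break toward
    the smallest angle.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if np.ptp(image) == 0:
        raise ValueError("constant image: orientation undefined")
    if wavelength_short is None:
        wavelength_short = 4.0 / np.sqrt(2.0)
    if wavelength_long is None:
        wavelength_long = float(np.hypot(*image.shape))
    freqs = 1.0 / np.geomspace(wavelength_short, wavelength_long, n_frequencies)
    thetas = np.deg2rad(np.arange(0.0, 180.0, orientation_step_deg))
    img = image - image.mean()
    energies = np.zeros(len(thetas))
    for i, theta in enumerate(thetas):
        e = 0.0
        for f in freqs:
            kern = gabor_kernel(frequency=f, theta=theta)
            resp = fftconvolve(img, kern, mode="same")
            e += np.abs(resp).sum()  # quadrature-pair energy
        energies[i] = e / len(freqs)
    return float(thetas[int(np.argmax(energies))])  # argmax: first max wins


# ---------------------------------------------------------------------------
# shape-complexity feature space


@dataclass(frozen=True)
class ShapeMetrics:
    """Six complexity descriptors of one silhouette."""

    n_concavities: int
    concavity_area: float
    hull_area: float
    hull_perimeter: float
    min_circle_area: float
    silhouette_to_circle_ratio: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.n_concavities,
                self.concavity_area,
                self.hull_area,
                self.hull_perimeter,
                self.min_circle_area,
                self.silhouette_to_circle_ratio,
            ],
            dtype=float,
        )


METRIC_COLUMNS = (
    "n_concavities",
    "concavity_area",
    "hull_area",
    "hull_perimeter",
    "min_circle_area",
    "silhouette_to_circle_ratio",
)

#: rasterization specks below this area do not count as concavities
MIN_CONCAVITY_AREA = 5


def shape_complexity(silhouette: np.ndarray) -> ShapeMetrics:
    """Complexity metrics of a binary silhouette (one foreground component).

    Concavities are connected components of (convex hull minus silhouette)
    of at least MIN_CONCAVITY_AREA pixels; the enclosing circle is the
    minimum bounding circle of the foreground pixels.
    """
    sil = np.asarray(silhouette).astype(bool)
    if not sil.any():
        raise ValueError("empty silhouette")
    n_comp = measure.label(sil, connectivity=2).max()
    if n_comp != 1:
        raise ValueError(f"silhouette must have one connected component, got {n_comp}")
    hull = convex_hull_image(sil)
    diff = measure.label(hull & ~sil, connectivity=2)
    concavity_areas = np.bincount(diff.ravel())[1:]
    big = concavity_areas[concavity_areas >= MIN_CONCAVITY_AREA]
    ys, xs = np.nonzero(sil)
    radius = minimum_bounding_radius(MultiPoint(np.column_stack([xs, ys])))
    # pixel centers: pad by half a pixel so a single pixel has positive radius
    circle_area = float(np.pi * (radius + 0.5) ** 2)
    return ShapeMetrics(
        n_concavities=int(len(big)),
        concavity_area=float(big.sum()),
        hull_area=float(hull.sum()),
        hull_perimeter=float(measure.perimeter(hull)),
        min_circle_area=circle_area,
        silhouette_to_circle_ratio=float(min(sil.sum() / circle_area, 1.0)),
    )


def pca_first_component(metrics: pd.DataFrame | np.ndarray) -> np.ndarray:
    """First principal component of column-standardized shape metrics.

    The sign is fixed so that higher scores mean more complex shapes
    (positive loading on the concavity count).
    """
    if isinstance(metrics, pd.DataFrame):
        x = metrics[list(METRIC_COLUMNS)].to_numpy(float)
    else:
        x = np.asarray(metrics, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 stimuli for PCA")
    sd = x.std(axis=0)
    z = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=1)
    scores = pca.fit_transform(z)[:, 0]
    if pca.components_[0, 0] < 0:  # loading of n_concavities
        scores = -scores
    return scores


# ---------------------------------------------------------------------------
# similarity feature space (classical MDS)


def mds_1d(rdm: np.ndarray) -> np.ndarray:
    """First classical (Torgerson) MDS coordinate of a dissimilarity matrix.

    Deterministic: double-centering followed by an eigendecomposition;
    positions are centered and their orientation/origin is arbitrary.
    """
    d = _check_rdm(rdm)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    top = np.argmax(vals)
    lam = max(vals[top], 0.0)
    pos = vecs[:, top] * np.sqrt(lam)
    return pos - pos.mean()


# ---------------------------------------------------------------------------
# RDMs and RSA


def _check_rdm(rdm: np.ndarray) -> np.ndarray:
    r = np.asarray(rdm, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("RDM must be square")
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("RDM must be symmetric")
    return r


def _lower_triangle(rdm: np.ndarray) -> np.ndarray:
    r = _check_rdm(rdm)
    return r[np.tril_indices_from(r, k=-1)]


def model_rdm(positions: np.ndarray, space: FeatureSpace) -> np.ndarray:
    """Pairwise feature-distance RDM: wrap-around distance (max pi/2) for the
    circular space, absolute difference for linear spaces."""
    p = np.asarray(positions, dtype=float)
    return space.distance(p[None, :], p[:, None])


def neural_rdm(patterns: np.ndarray) -> np.ndarray:
    """Correlation-distance RDM (1 - Pearson r) of z-scored localizer
    patterns (stimuli x voxels)."""
    x = np.asarray(patterns, dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 3:
        raise ValueError("need >= 2 stimuli and >= 3 voxels")
    sd = x.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance pattern for stimulus {bad[0]}")
    return 1.0 - np.corrcoef(x)


def _partial_spearman(x: np.ndarray, y: np.ndarray, controls: np.ndarray | None):
    """Partial Spearman: Pearson on ranked, control-residualized vectors."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if controls is not None and controls.size:
        rc = np.column_stack([stats.rankdata(c) for c in controls])
        design = np.column_stack([np.ones(len(rx)), rc])
        rx = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
        ry = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("constant lower triangle: correlation undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def rsa_validate(
    model: np.ndarray,
    neural_rdms: list[np.ndarray],
    control_rdms: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-participant partial Spearman rho of a model RDM against neural
    RDMs, controlling for competing model RDMs; Fisher-z values and a
    two-sided one-sample group t-test against zero.

    Returns a tidy frame (participant, rho, z) with t/p in ``.attrs``.
    """
    mv = _lower_triangle(model)
    cv = (
        np.array([_lower_triangle(c) for c in control_rdms])
        if control_rdms
        else None
    )
    rows = []
    for i, nr in enumerate(neural_rdms):
        nv = _lower_triangle(nr)
        if nv.shape != mv.shape:
            raise ValueError("RDM sizes differ")
        rho = _partial_spearman(mv, nv, cv)
        rows.append({"participant": i, "rho": rho, "z": np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))})
    out = pd.DataFrame(rows)
    if len(out) >= 2:
        t, p = stats.ttest_1samp(out["z"], 0.0)
        out.attrs["t"] = float(t)
        out.attrs["p"] = float(p)
    return out


def compare_feature_spaces(
    rdms: dict[str, np.ndarray],
    n_boot: int = 10000,
    n_perm: int = 10000,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Pairwise Spearman rho between feature-space RDMs with joint-bootstrap
    95% CIs (resampling stimuli) and Mantel permutation p values."""
    rng = np.random.default_rng(rng)
    names = list(rdms)
    mats = {k: _check_rdm(v) for k, v in rdms.items()}
    n = next(iter(mats.values())).shape[0]
    if any(m.shape[0] != n for m in mats.values()):
        raise ValueError("RDM sizes differ")
    tril = np.tril_indices(n, k=-1)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = mats[names[i]], mats[names[j]]
            rho = stats.spearmanr(a[tril], b[tril]).statistic
            boots = np.empty(n_boot)
            for k in range(n_boot):
                idx = rng.integers(0, n, n)
                sa = a[np.ix_(idx, idx)][tril]
                sb = b[np.ix_(idx, idx)][tril]
                if np.ptp(sa) == 0 or np.ptp(sb) == 0:
                    boots[k] = np.nan
                    continue
                boots[k] = stats.spearmanr(sa, sb).statistic
            # Mantel: permute rows/columns of one RDM jointly
            count = 0
            for k in range(n_perm):
                perm = rng.permutation(n)
                r = stats.spearmanr(a[np.ix_(perm, perm)][tril], b[tril]).statistic
                if abs(r) >= abs(rho):
                    count += 1
            rows.append(
                {
                    "space_a": names[i],
                    "space_b": names[j],
                    "rho": float(rho),
                    "ci_low": float(np.nanpercentile(boots, 2.5)),
                    "ci_high": float(np.nanpercentile(boots, 97.5)),
                    "mantel_p": (count + 1) / (n_perm + 1),
                }
            )
    return pd.DataFrame(rows)
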