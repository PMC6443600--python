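"""CT texture feature bank: first-order, GLCM, GLRLM and Gabor features.

The bank mirrors a high-throughput phenotype matrix of 356 three-dimensional
plus 236 two-dimensional features per tumor region of interest:

* 12 first-order intensity statistics;
* 9 gray-level co-occurrence (GLCM) features on a grid of quantization
  levels {8,16,32,64} x offsets (distances {1,2,3,4} in 3-D over 13
  directions, {1,2} in 2-D over 4 in-plane directions), aggregated as the
  mean and range over directions;
* 7 gray-level run-length (GLRLM) features per level setting, mean and
  range over the same direction sets;
* Gabor response-magnitude variance and histogram entropy per
  (frequency, orientation), per axial slice (2-D only).

2-D features are computed on every mask-intersecting axial slice and
aggregated by unweighted mean.  GLCM and GLRLM accumulation is mask-aware:
only voxel pairs / runs lying entirely inside the mask contribute, which is
why the matrices are built here rather than with ``skimage``'s unmasked
``graycomatrix``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache as _lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FeatureBankConfig",
    "QuantizedVolume",
    "quantize",
    "first_order_features",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "gabor_features",
    "extract_feature_bank",
    "feature_manifest",
    "TextureFeatureBank",
]

FIRST_ORDER_NAMES = [
    "mean", "sd", "variance", "skewness", "kurtosis", "energy", "entropy",
    "min", "max", "range", "median", "mad",
]
GLCM_NAMES = [
    "contrast", "dissimilarity", "homogeneity", "energy", "entropy",
    "correlation", "cluster_shade", "cluster_prominence", "max_probability",
]
GLRLM_NAMES = ["sre", "lre", "gln", "rln", "rp", "lgre", "hgre"]
GABOR_NAMES = ["variance", "entropy"]

#: 13 unique 3-D co-occurrence directions (up to sign)
DIRECTIONS_3D = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]
#: 4 in-plane directions (rows, cols)
DIRECTIONS_2D = [(0, 1), (1, 0), (1, 1), (1, -1)]


@dataclass(frozen=True)
class FeatureBankConfig:
    """Parameter grid of the feature bank.

    The grid is sized so that the bank emits exactly 356 3-D and 236 2-D
    features: 12 + 2*4*(9*4+7) = 356 and 12 + 2*4*(9*2+7) + 24 = 236.
    """

    quantization_levels: tuple[int, ...] = (8, 16, 32, 64)
    glcm_distances_3d: tuple[int, ...] = (1, 2, 3, 4)
    glcm_distances_2d: tuple[int, ...] = (1, 2)
    gabor_frequencies: tuple[float, ...] = (0.1, 0.2, 0.4)
    gabor_orientations_deg: tuple[int, ...] = (0, 45, 90, 135)
    histogram_bins: int = 64

    def __post_init__(self):
        if any(g < 2 for g in self.quantization_levels):
            raise ValueError("quantization levels must be >= 2")
        if any(d < 1 for d in self.glcm_distances_3d + self.glcm_distances_2d):
            raise ValueError("GLCM distances must be >= 1")
        if any(not 0 < f <= 0.5 for f in self.gabor_frequencies):
            raise ValueError("gabor frequencies must lie in (0, 0.5]")

    @property
    def n_features_3d(self) -> int:
        nG = len(self.quantization_levels)
        return (len(FIRST_ORDER_NAMES)
                + 2 * nG * (len(GLCM_NAMES) * len(self.glcm_distances_3d)
                            + len(GLRLM_NAMES)))

    @property
    def n_features_2d(self) -> int:
        nG = len(self.quantization_levels)
        return (len(FIRST_ORDER_NAMES)
                + 2 * nG * (len(GLCM_NAMES) * len(self.glcm_distances_2d)
                            + len(GLRLM_NAMES))
                + len(GABOR_NAMES) * len(self.gabor_frequencies)
                * len(self.gabor_orientations_deg))

    def feature_ids(self) -> list[str]:
        """Deterministic id list; a pure function of the config."""
        ids: list[str] = []
        for dim, dists in (("3d", self.glcm_distances_3d),
                           ("2d", self.glcm_distances_2d)):
            ids += [f"{dim}_firstorder_{n}" for n in FIRST_ORDER_NAMES]
            for G in self.quantization_levels:
                for d in dists:
                    for agg in ("mean", "range"):
                        ids += [f"{dim}_glcm_{n}_G{G}_d{d}_{agg}"
                                for n in GLCM_NAMES]
                for agg in ("mean", "range"):
                    ids += [f"{dim}_glrlm_{n}_G{G}_{agg}" for n in GLRLM_NAMES]
        for f in self.gabor_frequencies:
            for th in self.gabor_orientations_deg:
                ids += [f"2d_gabor_{n}_f{f:g}_th{th}" for n in GABOR_NAMES]
        return ids

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FeatureBankConfig":
        d = json.loads(text)
        return cls(**{k: tuple(v) if isinstance(v, list) else v
                      for k, v in d.items()})


@dataclass
class QuantizedVolume:
    grid: np.ndarray   # integer levels in [1, G]; 0 outside mask
    G: int
    mask: np.ndarray


def quantize(volume: np.ndarray, mask: np.ndarray, G: int) -> QuantizedVolume:
    """Equal-width quantization of the masked intensities into [1, G].

    A constant region has zero range and maps wholly to level 1.
    """
    if G < 2:
        raise ValueError("G must be >= 2")
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = np.asarray(volume, float)
    lo, hi = vals[mask].min(), vals[mask].max()
    grid = np.zeros(vals.shape, dtype=np.int64)
    if hi > lo:
        lev = np.floor((vals - lo) / (hi - lo) * G).astype(np.int64) + 1
        grid[mask] = np.clip(lev[mask], 1, G)
    else:
        grid[mask] = 1
    return QuantizedVolume(grid=grid, G=G, mask=mask)


# ---------------------------------------------------------------------------
# first order

def first_order_features(volume: np.ndarray, mask: np.ndarray,
                         bins: int = 64) -> dict[str, float]:
    """Intensity statistics over masked voxels (population moments).

    Skewness and kurtosis are undefined (NaN) when the region is constant
    or a single voxel; entropy is the Shannon entropy (bits) of a
    ``bins``-bin histogram of the masked intensities.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    x = np.asarray(volume, float)[mask]
    n = x.size
    mu = x.mean()
    var = float(((x - mu) ** 2).mean())
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(((x - mu) ** 3).mean() / sd**3)
        kurt = float(((x - mu) ** 4).mean() / sd**4)
    else:
        skew = kurt = np.nan
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / n
    ent = float(-(p * np.log2(p)).sum())
    return {
        "mean": float(mu), "sd": float(sd), "variance": var,
        "skewness": skew, "kurtosis": kurt,
        "energy": float((x ** 2).sum()), "entropy": ent,
        "min": float(x.min()), "max": float(x.max()),
        "range": float(x.max() - x.min()),
        "median": float(np.median(x)),
        "mad": float(np.median(np.abs(x - np.median(x)))),
    }


# ---------------------------------------------------------------------------
# GLCM

def _offset_views(shape: tuple[int, ...], offset: tuple[int, ...]):
    a, b = [], []
    for o, s in zip(offset, shape):
        if abs(o) >= s:
            return None
        if o >= 0:
            a.append(slice(0, s - o)); b.append(slice(o, s))
        else:
            a.append(slice(-o, s)); b.append(slice(0, s + o))
    return tuple(a), tuple(b)


def glcm_matrix(q: QuantizedVolume, offset: tuple[int, ...],
                symmetric: bool = True) -> np.ndarray | None:
    """Normalized co-occurrence matrix for one offset; ``None`` when no
    voxel pair at the offset lies entirely inside the mask."""
    views = _offset_views(q.grid.shape, tuple(offset))
    if views is None:
        return None
    va, vb = views
    ga, gb = q.grid[va], q.grid[vb]
    valid = (ga > 0) & (gb > 0)
    if not valid.any():
        return None
    i = ga[valid] - 1
    j = gb[valid] - 1
    counts = np.bincount(i * q.G + j, minlength=q.G * q.G).reshape(q.G, q.G)
    counts = counts.astype(float)
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


@_lru_cache(maxsize=16)
def _level_grids(G: int):
    lev = np.arange(1, G + 1, dtype=float)
    ii, jj = np.meshgrid(lev, lev, indexing="ij")
    return lev, ii, jj


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """Haralick-style statistics of a normalized co-occurrence matrix.

    Correlation is undefined (NaN) when a marginal is degenerate.  Entropy
    uses log2.  Cluster shade is the third joint moment
    sum_ij (i + j - mu_x - mu_y)^3 P(i,j) on 1-based levels.
    """
    G = P.shape[0]
    lev, ii, jj = _level_grids(G)
    px, py = P.sum(axis=1), P.sum(axis=0)
    mu_x, mu_y = (lev * px).sum(), (lev * py).sum()
    sd_x = np.sqrt(((lev - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((lev - mu_y) ** 2 * py).sum())
    diff = ii - jj
    nz = P > 0
    corr = (float((((ii - mu_x) * (jj - mu_y) * P).sum()) / (sd_x * sd_y))
            if sd_x > 0 and sd_y > 0 else np.nan)
    return {
        "contrast": float((diff ** 2 * P).sum()),
        "dissimilarity": float((np.abs(diff) * P).sum()),
        "homogeneity": float((P / (1.0 + diff ** 2)).sum()),
        "energy": float((P ** 2).sum()),
        "entropy": float(-(P[nz] * np.log2(P[nz])).sum()),
        "correlation": corr,
        "cluster_shade": float(((ii + jj - mu_x - mu_y) ** 3 * P).sum()),
        "cluster_prominence": float(((ii + jj - mu_x - mu_y) ** 4 * P).sum()),
        "max_probability": float(P.max()),
    }


# ---------------------------------------------------------------------------
# GLRLM

def _shift(arr: np.ndarray, direction: tuple[int, ...], fill=0) -> np.ndarray:
    """Value of ``arr`` at v - direction (out-of-bounds -> fill)."""
    out = np.full_like(arr, fill)
    views = _offset_views(arr.shape, tuple(direction))
    if views is None:
        return out
    va, vb = views
    out[vb] = arr[va]
    return out


def glrlm_matrix(q: QuantizedVolume, direction: tuple[int, ...]) -> np.ndarray:
    """Run-length count matrix R[level-1, length-1] along one direction.

    Runs are maximal segments of consecutive in-mask voxels sharing a
    level; the mask breaks runs.  Computed by propagating run lengths
    along the direction with vectorized shifts.
    """
    grid, mask, G = q.grid, q.mask, q.G
    prev = _shift(grid, direction, fill=0)
    same = mask & (prev == grid) & (prev > 0)
    rl = mask.astype(np.int64)
    max_len = int(max(grid.shape))
    for _ in range(max_len):
        prop = _shift(rl, direction, fill=0)
        new = np.where(same, prop + 1, mask.astype(np.int64))
        if np.array_equal(new, rl):
            break
        rl = new
    # a run ends at v when v+direction does not continue it
    cont_next = _shift(same.astype(np.int64), tuple(-d for d in direction),
                       fill=0).astype(bool)
    ends = mask & ~cont_next
    levels = grid[ends] - 1
    lengths = rl[ends] - 1
    R = np.zeros((G, max_len), dtype=np.int64)
    np.add.at(R, (levels, lengths), 1)
    return R


def glrlm_features(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    """Galloway run-length statistics of a run count matrix."""
    Nr = R.sum()
    if Nr == 0:
        return {n: np.nan for n in GLRLM_NAMES}
    G, L = R.shape
    i = np.arange(1, G + 1, dtype=float)[:, None]
    j = np.arange(1, L + 1, dtype=float)[None, :]
    Rf = R.astype(float)
    return {
        "sre": float((Rf / j ** 2).sum() / Nr),
        "lre": float((Rf * j ** 2).sum() / Nr),
        "gln": float((Rf.sum(axis=1) ** 2).sum() / Nr),
        "rln": float((Rf.sum(axis=0) ** 2).sum() / Nr),
        "rp": float(Nr / n_voxels),
        "lgre": float((Rf / i ** 2).sum() / Nr),
        "hgre": float((Rf * i ** 2).sum() / Nr),
    }


# ---------------------------------------------------------------------------
# Gabor

@_lru_cache(maxsize=64)
def _gabor_kernel_cached(frequency: float, theta: float) -> np.ndarray:
    from skimage.filters import gabor_kernel

    kern = np.asarray(gabor_kernel(frequency, theta=theta))
    # enforce a zero-DC even component so constant inputs give ~0 response
    return (kern.real - kern.real.mean()) + 1j * kern.imag


def _gabor_magnitude(img: np.ndarray, frequency: float, theta: float) -> np.ndarray:
    from scipy.signal import fftconvolve

    kern = _gabor_kernel_cached(float(frequency), float(theta))
    if kern.shape[0] > img.shape[0] or kern.shape[1] > img.shape[1]:
        warnings.warn("Gabor kernel larger than slice; reflect-padding",
                      stacklevel=2)
    py, px = kern.shape[0] // 2, kern.shape[1] // 2
    padded = np.pad(img, ((py, py), (px, px)), mode="symmetric")
    resp = fftconvolve(padded, kern[::-1, ::-1], mode="valid")
    resp = resp[:img.shape[0], :img.shape[1]]
    return np.abs(resp)


def gabor_features(volume_slice: np.ndarray, mask_slice: np.ndarray,
                   frequency: float, orientation: float,
                   bins: int = 64) -> dict[str, float]:
    """Variance and histogram entropy of the Gabor response magnitude
    inside the mask, for one 2-D slice.

    ``orientation`` is in radians.  A constant slice gives ~0 response
    (the even kernel component is DC-free) and zero entropy.
    """
    if not 0 < frequency <= 0.5:
        raise ValueError("frequency must lie in (0, 0.5]")
    mag = _gabor_magnitude(np.asarray(volume_slice, float), frequency,
                           orientation)
    m = np.asarray(mask_slice, bool)
    x = mag[m]
    if x.size == 0:
        return {n: np.nan for n in GABOR_NAMES}
    var = float(((x - x.mean()) ** 2).mean())
    scale = max(1.0, float(np.abs(np.asarray(volume_slice, float)[m]).max()))
    if np.ptp(x) <= 1e-9 * scale:   # numerically constant response
        return {"variance": var, "entropy": 0.0}
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    ent = float(-(p * np.log2(p)).sum())
    return {"variance": var, "entropy": ent}


# ---------------------------------------------------------------------------
# bank assembly

def _directional_aggregate(per_dir: list[dict[str, float]],
                           names: list[str]) -> dict[str, float]:
    """Mean and range over directions, ignoring missing directions; all
    directions missing -> NaN (explicit missing, never silent zero)."""
    out = {}
    for n in names:
        vals = np.array([d[n] for d in per_dir if d is not None], float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            out[f"{n}_mean"] = np.nan
            out[f"{n}_range"] = np.nan
        else:
            out[f"{n}_mean"] = float(vals.mean())
            out[f"{n}_range"] = float(vals.max() - vals.min())
    return out


def _texture_block(vol: np.ndarray, mask: np.ndarray, dim: str,
                   directions: list[tuple[int, ...]],
                   distances: tuple[int, ...],
                   config: FeatureBankConfig) -> dict[str, float]:
    """GLCM + GLRLM features of one array (a volume or a single slice)."""
    feats: dict[str, float] = {}
    n_vox = int(mask.sum())
    for G in config.quantization_levels:
        q = quantize(vol, mask, G)
        for d in distances:
            per_dir = []
            for direc in directions:
                off = tuple(d * c for c in direc)
                P = glcm_matrix(q, off)
                per_dir.append(None if P is None else glcm_features(P))
            agg = _directional_aggregate(per_dir, GLCM_NAMES)
            for n in GLCM_NAMES:
                for a in ("mean", "range"):
                    feats[f"{dim}_glcm_{n}_G{G}_d{d}_{a}"] = agg[f"{n}_{a}"]
        per_dir = [glrlm_features(glrlm_matrix(q, direc), n_vox)
                   for direc in directions]
        agg = _directional_aggregate(per_dir, GLRLM_NAMES)
        for n in GLRLM_NAMES:
            for a in ("mean", "range"):
                feats[f"{dim}_glrlm_{n}_G{G}_{a}"] = agg[f"{n}_{a}"]
    return feats


def extract_feature_bank(phantom, config: FeatureBankConfig | None = None
                         ) -> pd.Series:
    """Full 3-D + 2-D feature vector for one masked volume.

    3-D features use direction-averaged GLCM/GLRLM on the whole volume;
    2-D features are computed on each mask-intersecting axial slice and
    averaged (unweighted); Gabor features are 2-D only.  The id set is a
    pure function of the config; non-finite values are recorded as NaN.
    """
    config = config or FeatureBankConfig()
    vol = np.asarray(phantom.volume, float)
    mask = np.asarray(phantom.mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    feats: dict[str, float] = {}

    for name, val in first_order_features(vol, mask, config.histogram_bins).items():
        feats[f"3d_firstorder_{name}"] = val
    feats.update(_texture_block(vol, mask, "3d", DIRECTIONS_3D,
                                config.glcm_distances_3d, config))

    slice_ids = np.where(mask.any(axis=(1, 2)))[0]
    per_slice: list[dict[str, float]] = []
    for k in slice_ids:
        sl_feats: dict[str, float] = {}
        v2, m2 = vol[k], mask[k]
        for name, val in first_order_features(v2, m2, config.histogram_bins).items():
            sl_feats[f"2d_firstorder_{name}"] = val
        sl_feats.update(_texture_block(v2, m2, "2d", DIRECTIONS_2D,
                                       config.glcm_distances_2d, config))
        for f in config.gabor_frequencies:
            for th in config.gabor_orientations_deg:
                g = gabor_features(v2, m2, f, np.deg2rad(th),
                                   config.histogram_bins)
                for n in GABOR_NAMES:
                    sl_feats[f"2d_gabor_{n}_f{f:g}_th{th}"] = g[n]
        per_slice.append(sl_feats)

    df2 = pd.DataFrame(per_slice)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        feats.update(df2.mean(axis=0, skipna=True).to_dict())

    ids = config.feature_ids()
    return pd.Series({fid: feats.get(fid, np.nan) for fid in ids},
                     index=ids, dtype=float)


def feature_manifest(config: FeatureBankConfig | None = None) -> dict:
    """id -> {family, dim, params} audit map of the bank."""
    config = config or FeatureBankConfig()
    manifest = {}
    for fid in config.feature_ids():
        parts = fid.split("_")
        dim, family = parts[0], parts[1]
        manifest[fid] = {"dim": dim.upper(), "family": family,
                         "params": "_".join(parts[2:])}
    return manifest


class TextureFeatureBank(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer: phantoms -> feature matrix.

    ``transform`` accepts a sequence of phantom-like objects (``volume``,
    ``mask`` attributes) and returns a DataFrame with one row per phantom
    and one column per feature id.
    """

    def __init__(self, config: FeatureBankConfig | None = None):
        self.config = config

    def fit(self, X=None, y=None):
        self.config_ = self.config or FeatureBankConfig()
        self.feature_names_out_ = self.config_.feature_ids()
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "config_"):
            self.fit()
        rows = [extract_feature_bank(ph, self.config_) for ph in X]
        idx = [getattr(ph, "id", i) for i, ph in enumerate(X)]
        return pd.DataFrame(rows, index=idx)

    def get_feature_names_out(self, input_features=None):
        if not hasattr(self, "config_"):
            self.fit()
        return np.asarray(self.feature_names_out_, dtype=object)
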