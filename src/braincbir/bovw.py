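"""Dense raw-patch bag-of-visual-words: dictionary, coding, pooling.

Local descriptors are raw w×w intensity patches (row-major flattened, no mean
subtraction) sampled densely inside the ROI on a stride grid.  A dictionary of
V visual words is learned by k-means; patches are coded either hard (one-hot
at the nearest word) or soft (Gaussian kernel weights over the K nearest
words, renormalized).  Codes are aggregated per spatial region by p-norm
pooling, f = ((1/n) Σ c^p)^(1/p), whose p = 1 and p → ∞ limits are average and
max pooling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .errors import ConfigurationError


@dataclass
class PatchSet:
    """Dense patch descriptors plus their ROI-local center coordinates."""

    descriptors: np.ndarray  # (n, w*w)
    centers: np.ndarray  # (n, 2) as (row, col), 0-based within the ROI
    w: int


@dataclass
class Dictionary:
    """V visual words over w×w raw patches (rows of ``words`` are cluster centers)."""

    words: np.ndarray  # (V, w*w)
    w: int
    seed: int | None = None

    @property
    def V(self) -> int:
        return self.words.shape[0]

    def save(self, path: str | Path) -> None:
        payload = {
            "V": int(self.V),
            "w": int(self.w),
            "seed": self.seed,
            "checksum": float(np.sum(self.words)),
            # row-major flattened word matrix
            "words": np.asarray(self.words, dtype=float).ravel().tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "Dictionary":
        payload = json.loads(Path(path).read_text())
        words = np.asarray(payload["words"], dtype=float).reshape(
            payload["V"], payload["w"] ** 2
        )
        return cls(words=words, w=payload["w"], seed=payload["seed"])


def sample_patches_dense(
    image: np.ndarray, roi: tuple[int, int, int, int], w: int, stride: int = 1
) -> PatchSet:
    """All w×w patches on the stride grid whose footprint lies inside the ROI.

    The count is ``ceil((H-w+1)/stride) * ceil((W-w+1)/stride)`` for an H×W ROI.
    """
    if w % 2 == 0 or w < 1:
        raise ValueError("patch side w must be odd and positive")
    if stride < 1:
        raise ValueError("stride must be positive")
    r0, c0, H, W = roi
    if H < w or W < w:
        raise ValueError(f"ROI {H}x{W} smaller than patch size {w}")
    if r0 < 0 or c0 < 0 or r0 + H > image.shape[0] or c0 + W > image.shape[1]:
        raise ValueError("ROI does not fit inside the image")
    sub = np.asarray(image, dtype=float)[r0 : r0 + H, c0 : c0 + W]
    windows = sliding_window_view(sub, (w, w))[::stride, ::stride]
    n0, n1 = windows.shape[:2]
    descriptors = windows.reshape(n0 * n1, w * w).copy()
    rows = np.arange(n0) * stride + w // 2
    cols = np.arange(n1) * stride + w // 2
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    centers = np.stack([rr.ravel(), cc.ravel()], axis=1)
    return PatchSet(descriptors=descriptors, centers=centers, w=w)


def learn_dictionary(
    descriptors: np.ndarray,
    V: int,
    seed: int = 0,
    w: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> Dictionary:
    """k-means dictionary (k-means++ init, single run, seeded → deterministic)."""
    descriptors = np.asarray(descriptors, dtype=float)
    if V < 2:
        raise ValueError("dictionary size V must be >= 2")
    if descriptors.shape[0] < V:
        raise ValueError(
            f"need at least V={V} patches, got {descriptors.shape[0]}"
        )
    km = KMeans(
        n_clusters=V,
        init="k-means++",
        n_init=1,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(descriptors)
    if w is None:
        side = int(round(np.sqrt(descriptors.shape[1])))
        w = side
    return Dictionary(words=km.cluster_centers_.copy(), w=w, seed=seed)


def _as_batch(descriptors: np.ndarray) -> tuple[np.ndarray, bool]:
    d = np.asarray(descriptors, dtype=float)
    if d.ndim == 1:
        return d[None, :], True
    return d, False


def encode_hard(descriptors: np.ndarray, dictionary: Dictionary) -> np.ndarray:
    """One-hot code at the nearest word (Euclidean; ties go to the lowest index)."""
    d, single = _as_batch(descriptors)
    dist = cdist(d, dictionary.words, "sqeuclidean")
    idx = np.argmin(dist, axis=1)  # argmin returns the first minimum
    codes = np.zeros((d.shape[0], dictionary.V))
    codes[np.arange(d.shape[0]), idx] = 1.0
    return codes[0] if single else codes


def median_nn_sigma(dictionary: Dictionary) -> float:
    """Default soft-assignment kernel width: median nearest-neighbor distance
    among the dictionary words."""
    dist = cdist(dictionary.words, dictionary.words)
    np.fill_diagonal(dist, np.inf)
    return float(np.median(dist.min(axis=1)))


def encode_soft(
    descriptors: np.ndarray,
    dictionary: Dictionary,
    sigma: float | None = None,
    K: int = 5,
) -> np.ndarray:
    """Kernel codebook soft assignment over the K nearest words.

    Weights ∝ exp(-‖x - word‖² / (2σ²)) on the K nearest words (stable sort,
    so distance ties resolve to lower indices), zero elsewhere, renormalized to
    sum to 1.  Computed with a max-shift so the σ → 0 limit reproduces hard
    assignment exactly.
    """
    if sigma is None:
        sigma = median_nn_sigma(dictionary)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    K = min(K, dictionary.V)
    d, single = _as_batch(descriptors)
    dist = cdist(d, dictionary.words, "sqeuclidean")
    order = np.argsort(dist, axis=1, kind="stable")[:, :K]
    dk = np.take_along_axis(dist, order, axis=1)
    z = np.exp(-(dk - dk[:, :1]) / (2.0 * sigma**2))
    z /= z.sum(axis=1, keepdims=True)
    codes = np.zeros((d.shape[0], dictionary.V))
    np.put_along_axis(codes, order, z, axis=1)
    return codes[0] if single else codes


def pool(
    codes: np.ndarray,
    region_labels: np.ndarray,
    m: int,
    p: float | str = "inf",
) -> np.ndarray:
    """p-norm pooling of codes per region, concatenated in region-index order.

    ``p=1`` is average pooling, ``p='inf'`` (or ``numpy.inf``) max pooling;
    regions with no codes contribute an all-zero block.
    """
    codes = np.atleast_2d(np.asarray(codes, dtype=float))
    region_labels = np.asarray(region_labels)
    if codes.shape[0] != region_labels.shape[0]:
        raise ValueError("one region label per code required")
    if region_labels.size and (region_labels.min() < 0 or region_labels.max() >= m):
        raise ValueError("region labels must lie in [0, m)")
    if p == "inf" or p == np.inf:
        reduce = lambda c: c.max(axis=0)
    elif p == 1:
        reduce = lambda c: c.mean(axis=0)
    else:
        raise ConfigurationError("pooling order p must be 1 or 'inf'")
    V = codes.shape[1]
    out = np.zeros(m * V)
    for i in range(m):
        block = codes[region_labels == i]
        if block.shape[0]:
            out[i * V : (i + 1) * V] = reduce(block)
    return out


@dataclass
class EncodedROI:
    """Soft codes of one ROI plus unit-square patch-center coordinates.

    ``points[:, 0]`` is x = (col+0.5)/W and ``points[:, 1]`` is y =
    (row+0.5)/H, so one learned partition of [0,1]² transfers across ROIs of
    different pixel sizes.
    """

    points: np.ndarray  # (n, 2) in [0, 1]^2
    codes: np.ndarray  # (n, V)


def encode_roi(
    image: np.ndarray,
    roi: tuple[int, int, int, int],
    dictionary: Dictionary,
    stride: int = 1,
    sigma: float | None = None,
    K: int = 5,
    coding: str = "soft",
) -> EncodedROI:
    """Sample, code, and map an ROI's patches into the unit-square frame."""
    ps = sample_patches_dense(image, roi, dictionary.w, stride)
    if coding == "soft":
        codes = encode_soft(ps.descriptors, dictionary, sigma=sigma, K=K)
    elif coding == "hard":
        codes = encode_hard(ps.descriptors, dictionary)
    else:
        raise ConfigurationError(f"unknown coding method {coding!r}")
    _, _, H, W = roi
    x = (ps.centers[:, 1] + 0.5) / W
    y = (ps.centers[:, 0] + 0.5) / H
    return EncodedROI(points=np.stack([x, y], axis=1), codes=codes)
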