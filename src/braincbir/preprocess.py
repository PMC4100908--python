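"""Intensity normalization for MR slices.

MR intensities carry no fixed physical meaning, so before raw-patch features
are extracted every slice is rescaled to [0, 1] by a robust quantile min–max
map: the 1% and 99% intensity quantiles (of the brain mask when one is given,
else of the whole image) are mapped to 0 and 1 and values outside saturate.
Bias-field correction (e.g. N3/N4) is an external preprocessing step; the
pipeline accepts pre-corrected images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError


@dataclass(frozen=True)
class NormalizationParams:
    q_low: float = 0.01
    q_high: float = 0.99

    def __post_init__(self):
        if not (0.0 <= self.q_low < self.q_high <= 1.0):
            raise ValueError("need 0 <= q_low < q_high <= 1")


def normalize_intensity(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    params: NormalizationParams = NormalizationParams(),
) -> np.ndarray:
    """Quantile min–max rescaling to [0, 1].

    Quantiles use linear interpolation between order statistics.  Raises
    :class:`DegenerateInputError` when the two quantiles coincide (constant
    region), since no affine map is defined there.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != image.shape:
            raise ValueError("mask shape must match image shape")
        values = image[mask]
        if values.size == 0:
            raise ValueError("mask has empty foreground")
    else:
        values = image.reshape(-1)
    q1, q99 = np.quantile(values, [params.q_low, params.q_high])
    if q99 <= q1:
        raise DegenerateInputError("quantiles coincide: constant region")
    return np.clip((image - q1) / (q99 - q1), 0.0, 1.0)
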