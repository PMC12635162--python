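"""Construction of the binarized pNMS mask and overlap statistics.

The personalized neurometabolic signature (pNMS) is the set of voxels
whose PET asymmetry index falls at or below a prognostic threshold
(default -0.06, the hypometabolic direction), restricted to the
hemisphere ipsilateral to the epileptogenic zone. This module builds
that mask and quantifies its relationship to the ablation cavity:
the ablative rate (fraction of the in-ROI signature that was ablated)
and the Dice overlap coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .volume import AIMap, Volume

__all__ = [
    "PNMSMask",
    "OverlapReport",
    "binarize_pnms",
    "ablative_rate",
    "dice",
    "mean_ai_within_mask",
    "hemisphere_mask",
]

DEFAULT_AI_THRESHOLD = -0.06


@dataclass
class PNMSMask:
    """Binarized pNMS: voxels with AI <= threshold within one hemisphere."""

    mask: np.ndarray
    threshold: float = DEFAULT_AI_THRESHOLD
    hemisphere: str = "left"
    source_modality: str = "PET"

    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class OverlapReport:
    """Per-ROI overlap between a pNMS and the ablation cavity."""

    roi_name: str
    pnms_volume_vox: int
    intersection_vox: int
    ablative_rate: float | None  # None when pNMS ∩ ROI is empty (undefined)
    dice: float | None = None
    extra: dict = field(default_factory=dict)


def hemisphere_mask(shape: tuple[int, int, int], side: str) -> np.ndarray:
    """Binary mask of one hemisphere of an even-x lattice.

    ``side='left'`` selects columns ``0 .. Nx/2 - 1`` (lower x indices).
    """
    nx = shape[0]
    if nx % 2:
        raise ValueError("asymmetric grid: x-dimension must be even")
    m = np.zeros(shape, dtype=bool)
    if side == "left":
        m[: nx // 2] = True
    elif side == "right":
        m[nx // 2 :] = True
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return m


def _mask_array(m: Volume | np.ndarray) -> np.ndarray:
    arr = m.values if isinstance(m, Volume) else m
    return np.asarray(arr).astype(bool)


def binarize_pnms(
    ai: AIMap,
    threshold: float = DEFAULT_AI_THRESHOLD,
    hemisphere_mask_: Volume | np.ndarray | None = None,
    hemisphere: str = "left",
    source_modality: str = "PET",
) -> PNMSMask:
    """Threshold an AI map into a binary pNMS.

    The mask comprises voxels in the chosen hemisphere that are valid in
    the AI map and satisfy ``AI <= threshold`` (the hypometabolic
    direction: intensity lower than the contralateral homologue). An
    empty result is allowed and warned about, not an error.
    """
    if hemisphere_mask_ is None:
        hm = hemisphere_mask(ai.shape, hemisphere)
    else:
        hm = _mask_array(hemisphere_mask_)
        nx = ai.shape[0]
        left, right = hm[: nx // 2].any(), hm[nx // 2 :].any()
        if left and right:
            raise ValueError("hemisphere mask straddles the midsagittal plane")
        hemisphere = "left" if left else "right"
    sel = hm & ai.valid_mask
    mask = np.zeros(ai.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        mask[sel] = ai.values[sel] <= threshold
    if not mask.any():
        warnings.warn(
            f"pNMS empty at threshold {threshold}: no voxel below it", stacklevel=2
        )
    return PNMSMask(mask, threshold, hemisphere, source_modality)


def ablative_rate(
    pnms: PNMSMask | np.ndarray,
    ablation: Volume | np.ndarray,
    roi: Volume | np.ndarray | None = None,
) -> float | None:
    """Fraction of the (in-ROI) pNMS that falls inside the ablation cavity.

    Returns ``|pnms ∩ roi ∩ ablation| / |pnms ∩ roi|``; with ``roi=None``
    the whole signature is the denominator. An empty denominator makes
    the rate undefined and returns None (propagated as missing, never
    coerced to zero).
    """
    p = pnms.mask if isinstance(pnms, PNMSMask) else _mask_array(pnms)
    a = _mask_array(ablation)
    if p.shape != a.shape:
        raise ValueError("pNMS and ablation mask are on different lattices")
    sel = p if roi is None else (p & _mask_array(roi))
    denom = int(sel.sum())
    if denom == 0:
        return None
    return float((sel & a).sum() / denom)


def dice(a: Volume | np.ndarray, b: Volume | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) between two binary masks."""
    aa, bb = _mask_array(a), _mask_array(b)
    if aa.shape != bb.shape:
        raise ValueError("masks are on different lattices")
    total = int(aa.sum()) + int(bb.sum())
    if total == 0:
        raise ValueError("Dice undefined: both masks empty")
    return float(2.0 * (aa & bb).sum() / total)


def mean_ai_within_mask(
    ai: AIMap, mask: Volume | np.ndarray, aggregator: str = "mean"
) -> float | None:
    """Aggregate AI over a mask; the per-patient modality feature.

    The arithmetic mean over ``mask ∩ valid_mask`` is the default
    per-patient scalar entering all regressions; ``aggregator='median'``
    is available. An empty intersection yields None (missing).
    """
    m = _mask_array(mask) & ai.valid_mask
    if not m.any():
        return None
    vals = ai.values[m]
    if aggregator == "mean":
        return float(vals.mean())
    if aggregator == "median":
        return float(np.median(vals))
    raise ValueError(f"unknown aggregator {aggregator!r}")
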