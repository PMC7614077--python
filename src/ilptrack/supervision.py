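"""Training-target and loss math for sparse point supervision.

These are the array operations a detection network would be trained with:
Gaussian cell-indicator targets peaking at annotated centers, movement-vector
targets pointing to the parent position at the previous frame, training masks
around each annotation (nothing outside any mask ever enters a loss, since
unannotated regions may contain cells), masked mean squared error, and the
two-term movement loss with its sigmoidal iteration schedule.  No network or
GPU is involved; the operations are exposed for testing and for building
supervision targets from annotation tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "SupervisionConfig",
    "cell_indicator_target",
    "movement_target",
    "masked_mse",
    "alpha_schedule",
    "movement_loss",
]


@dataclass
class SupervisionConfig:
    """Per-axis supervision geometry and the loss schedule.

    ``sigma`` (z, y, x, voxels) shapes the indicator Gaussian; ``mask_radius``
    (z, y, x, voxels) is the semi-axis of the ellipsoidal training mask around
    each annotation -- the caller must keep it small enough not to overlap
    neighboring nuclei.  ``alpha_midpoint``/``alpha_rate`` parametrize the
    schedule alpha(i) = sigmoid(rate * (i - midpoint)) that blends the two
    movement-loss terms over training iterations.
    """

    sigma: tuple[float, float, float] = (1.5, 2.5, 2.5)
    mask_radius: tuple[float, float, float] = (3.0, 5.0, 5.0)
    alpha_midpoint: float = 20000.0
    alpha_rate: float = 0.01

    def __post_init__(self) -> None:
        if min(self.sigma) <= 0:
            raise ValueError("sigma must be positive")
        if min(self.mask_radius) <= 0:
            raise ValueError("mask_radius must be positive")


def _frame_annotations(annotations, frame: int, extent) -> list[dict]:
    """Annotations of one frame as dicts; error on out-of-extent positions."""
    rows = []
    bad = []
    for a in annotations:
        if int(a["t"]) != frame:
            continue
        pos = np.asarray(a["position"], dtype=float)
        if np.any(pos < 0) or np.any(pos >= np.asarray(extent, dtype=float)):
            bad.append(a["id"])
        rows.append({"id": a["id"], "position": pos, "parent_id": a.get("parent_id")})
    if bad:
        raise ValueError(f"annotations outside extent: {bad}")
    return rows


def _ellipsoid_patch(center, radii, extent):
    """Bounding slices and inside-mask of an axis-aligned ellipsoid."""
    lo = np.maximum(np.ceil(center - radii).astype(int), 0)
    hi = np.minimum(np.floor(center + radii).astype(int) + 1, extent)
    if np.any(hi <= lo):
        return None, None
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return tuple(slice(l, h) for l, h in zip(lo, hi)), q <= 1.0


def cell_indicator_target(
    annotations, frame: int, extent, config: SupervisionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian indicator target and binary training mask for one frame.

    The target is 1.0 at each annotated center and decays with the configured
    per-axis sigma; overlapping contributions combine by maximum so the target
    never exceeds 1.  The mask is 1 exactly within the ellipsoidal
    ``mask_radius`` of any annotation.

    ``annotations`` is an iterable of dicts with keys ``id``, ``t``,
    ``position`` (z, y, x) and optional ``parent_id``.
    """
    extent = tuple(int(e) for e in extent)
    target = np.zeros(extent, dtype=np.float32)
    mask = np.zeros(extent, dtype=np.uint8)
    sigma = np.asarray(config.sigma, dtype=float)
    radii = np.asarray(config.mask_radius, dtype=float)
    for a in _frame_annotations(annotations, frame, extent):
        c = a["position"]
        # paint the Gaussian out to 4 sigma; beyond that it is < 3.4e-4
        glo = np.maximum(np.ceil(c - 4 * sigma).astype(int), 0)
        ghi = np.minimum(np.floor(c + 4 * sigma).astype(int) + 1, extent)
        if np.all(ghi > glo):
            grids = np.ogrid[glo[0]:ghi[0], glo[1]:ghi[1], glo[2]:ghi[2]]
            q = sum(((g - cc) / s) ** 2 for g, cc, s in zip(grids, c, sigma))
            sl = tuple(slice(l, h) for l, h in zip(glo, ghi))
            np.maximum(target[sl], np.exp(-0.5 * q).astype(np.float32), out=target[sl])
        sl, inside = _ellipsoid_patch(c, radii, extent)
        if sl is not None:
            mask[sl] |= inside.astype(np.uint8)
    return target, mask


def movement_target(
    annotations, frame: int, extent, config: SupervisionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Movement-vector target (z, y, x channels last) plus validity mask.

    Within each annotation's mask region the target is the offset from the
    annotation to its parent's position at frame-1 (the zero vector for
    annotations without a parent, e.g. track starts or frame 0).  Voxels
    outside every mask are undefined: the returned binary mask, not a
    sentinel value, marks where the target participates in losses.  Both
    daughters of a division carry offsets to the same mother position.
    """
    extent = tuple(int(e) for e in extent)
    offsets = np.zeros(extent + (3,), dtype=np.float32)
    mask = np.zeros(extent, dtype=np.uint8)
    radii = np.asarray(config.mask_radius, dtype=float)
    by_id = {a["id"]: np.asarray(a["position"], dtype=float) for a in annotations}
    parent_of = {a["id"]: a.get("parent_id") for a in annotations}
    for a in _frame_annotations(annotations, frame, extent):
        c = a["position"]
        pid = parent_of.get(a["id"])
        if pid is not None and pid in by_id:
            vec = by_id[pid] - c
        else:
            vec = np.zeros(3)
        sl, inside = _ellipsoid_patch(c, radii, extent)
        if sl is None:
            continue
        for k in range(3):
            offsets[sl + (k,)] = np.where(inside, vec[k], offsets[sl + (k,)])
        mask[sl] |= inside.astype(np.uint8)
    return offsets, mask


def masked_mse(prediction: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared error over voxels where mask is nonzero (0 if mask empty).

    For vector-valued fields (trailing channel axis) the mean runs over all
    channels of the masked voxels.
    """
    prediction = np.asarray(prediction, dtype=float)
    target = np.asarray(target, dtype=float)
    if prediction.shape != target.shape:
        raise ValueError(f"shape mismatch {prediction.shape} vs {target.shape}")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != prediction.shape[: mask.ndim]:
        raise ValueError(f"mask shape {mask.shape} incompatible with {prediction.shape}")
    if not mask.any():
        return 0.0
    diff2 = (prediction - target) ** 2
    return float(diff2[mask].mean())


def alpha_schedule(
    iteration, midpoint: float = 20000.0, rate: float = 0.01
) -> np.ndarray | float:
    """Blending weight alpha(i) = 1 / (1 + exp(rate * (midpoint - i))).

    Strictly increasing in i, bounded in (0, 1), exactly 0.5 at the midpoint.
    With the default midpoint of 20000 iterations, the movement loss is
    dominated early by its peak-restricted term and late by the full-mask
    term (this is the schedule formula as printed; see ``movement_loss`` for
    the option to swap the two weights).
    """
    i = np.asarray(iteration, dtype=float)
    if np.any(i < 0):
        raise ValueError("iteration must be non-negative")
    out = expit(rate * (i - midpoint))
    return float(out) if out.ndim == 0 else out


def movement_loss(
    pred_offsets: np.ndarray,
    target_offsets: np.ndarray,
    mask: np.ndarray,
    nms_peaks: np.ndarray,
    iteration: int,
    config: SupervisionConfig | None = None,
    favor_full_mask_early: bool = False,
) -> float:
    """Scheduled movement-vector loss alpha * L_A + (1 - alpha) * L_B.

    L_A is the masked MSE over the full training mask; L_B restricts the
    error to NMS-maximal voxels (``nms_peaks``, binary) that are also inside
    the training mask.  ``favor_full_mask_early`` swaps the two weights so
    that L_A dominates at low iteration counts instead of L_B; the default
    follows the printed schedule, under which alpha (the L_A weight) starts
    near 0 and rises to 1.
    """
    if iteration < 0:
        raise ValueError("iteration must be non-negative")
    cfg = config or SupervisionConfig()
    a = alpha_schedule(iteration, cfg.alpha_midpoint, cfg.alpha_rate)
    if favor_full_mask_early:
        a = 1.0 - a
    mask = np.asarray(mask).astype(bool)
    peaks = np.asarray(nms_peaks).astype(bool)
    loss_a = masked_mse(pred_offsets, target_offsets, mask)
    loss_b = masked_mse(pred_offsets, target_offsets, mask & peaks)
    return a * loss_a + (1.0 - a) * loss_b
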