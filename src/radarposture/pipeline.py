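"""Glue between the stages: samples -> view stacks -> model-ready arrays."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .geometry import GridSpec, default_placement
from .labels import COARSE_LABELS, FINE_LABELS, coarse_map
from .srem import build_view_stack

__all__ = ["resize_map", "encode_labels", "views_from_samples"]


def resize_map(values: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resample of a 2D map to (size, size).

    Uses explicit coordinate mapping so the output shape is exact
    regardless of the input aspect ratio (the bed grid is 139 x 304).
    """
    nx, ny = values.shape
    xi = (np.arange(size) + 0.5) * nx / size - 0.5
    yi = (np.arange(size) + 0.5) * ny / size - 0.5
    X, Y = np.meshgrid(xi, yi, indexing="ij")
    return ndimage.map_coordinates(values, [X, Y], order=1, mode="nearest")


def encode_labels(postures, scheme: str = "coarse") -> np.ndarray:
    """Posture label strings -> integer class indices for one scheme."""
    if scheme == "coarse":
        lut = {lab: i for i, lab in enumerate(COARSE_LABELS)}
        return np.array([lut[coarse_map(p)] for p in postures], dtype=np.int64)
    if scheme == "fine":
        lut = {lab: i for i, lab in enumerate(FINE_LABELS)}
        return np.array([lut[p] for p in postures], dtype=np.int64)
    raise ValueError(f"unknown label scheme {scheme!r}")


def views_from_samples(samples, placement=None, grid: GridSpec | None = None,
                       mask=None, input_size: int = 32, **stack_kwargs):
    """Run the preprocessing chain on an iterable of SampleRecords.

    Returns (x, postures, subjects, sample_ids) where x is a float32
    array (n_samples, n_views, input_size, input_size).  ``stack_kwargs``
    pass through to build_view_stack (interp, masked, profile_method,
    normalization, suppress_clutter).
    """
    placement = placement if placement is not None else default_placement()
    grid = grid if grid is not None else GridSpec()
    xs, postures, subjects, ids = [], [], [], []
    for rec in samples:
        stack = build_view_stack(rec, placement, grid, mask=mask, **stack_kwargs)
        views = np.stack([resize_map(v.values, input_size) for v in stack.views])
        xs.append(views.astype(np.float32))
        postures.append(rec.posture)
        subjects.append(rec.subject_id)
        ids.append(rec.sample_id)
    return np.stack(xs), postures, subjects, ids
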