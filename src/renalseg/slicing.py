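"""2.5D sample construction and reassembly.

A sample is a stack of ``k`` adjacent axial slices (k odd) used as input
channels; the supervision target is the middle slice's mask.  Per-slice
predictions are reassembled into a 3D label volume, one prediction per slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import LabelVolume, Volume

EDGE_POLICIES = ("replicate", "zero")


@dataclass
class SliceStack:
    channels: np.ndarray  # (k, H, W)
    center_index: int
    case_id: str = ""

    def __post_init__(self):
        k = self.channels.shape[0]
        if k % 2 == 0 or k < 1:
            raise ValueError(f"stack depth k must be odd and >= 1, got {k}")

    @property
    def k(self) -> int:
        return self.channels.shape[0]


@dataclass
class SliceTarget:
    mask: np.ndarray  # (H, W) int
    center_index: int


def make_stacks(volume: Volume, label: LabelVolume | None = None, k: int = 3,
                edge_policy: str = "replicate"):
    """Build one (SliceStack, SliceTarget|None) pair per axial slice.

    Neighbour indices falling outside the volume are handled by
    ``edge_policy``: ``"replicate"`` repeats the boundary slice, ``"zero"``
    substitutes a zero slice.
    """
    if k % 2 == 0 or k <= 0:
        raise ValueError(f"k must be a positive odd integer, got {k}")
    ns = volume.num_slices
    if k > 2 * ns - 1:
        raise ValueError(f"k={k} too large for a volume with {ns} slices")
    if edge_policy not in EDGE_POLICIES:
        raise ValueError(f"unknown edge policy {edge_policy!r}; use one of {EDGE_POLICIES}")
    if label is not None and label.data.shape != volume.data.shape:
        raise ValueError("volume/label shape mismatch")
    half = (k - 1) // 2
    out = []
    for center in range(ns):
        idx = np.arange(center - half, center + half + 1)
        if edge_policy == "replicate":
            chans = volume.data[np.clip(idx, 0, ns - 1)]
        else:
            chans = np.zeros((k,) + volume.data.shape[1:], dtype=volume.data.dtype)
            valid = (idx >= 0) & (idx < ns)
            chans[valid] = volume.data[idx[valid]]
        stack = SliceStack(np.ascontiguousarray(chans), center_index=center,
                           case_id=volume.case_id)
        target = None
        if label is not None:
            target = SliceTarget(mask=label.data[center].copy(), center_index=center)
        out.append((stack, target))
    return out


def reassemble(predictions, num_slices: int, vocabulary: str = "kits21",
               spacing=(1.0, 1.0, 1.0), affine=None, case_id: str = "") -> LabelVolume:
    """Stack per-slice predictions ``(center_index, HxW grid)`` into a volume.

    Every center index in ``0..num_slices-1`` must appear exactly once.
    """
    preds = list(predictions)
    slots: dict[int, np.ndarray] = {}
    for center, grid in preds:
        center = int(center)
        if center in slots:
            raise ValueError(f"duplicate prediction for slice index {center}")
        slots[center] = np.asarray(grid)
    missing = sorted(set(range(num_slices)) - set(slots))
    if missing:
        raise ValueError(f"missing predictions for slice indices {missing}")
    extra = sorted(set(slots) - set(range(num_slices)))
    if extra:
        raise ValueError(f"prediction indices out of range: {extra}")
    shapes = {s.shape for s in slots.values()}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent prediction shapes: {sorted(shapes)}")
    data = np.stack([slots[i] for i in range(num_slices)], axis=0)
    if affine is None:
        affine = np.diag(list(spacing) + [1.0])
    return LabelVolume(data, vocabulary=vocabulary, spacing=spacing,
                       affine=affine, case_id=case_id)
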