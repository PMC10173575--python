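"""Two-stage coarse-to-fine segmentation.

Stage 1 segments kidney-vs-background on whole slices; the foreground's
bounding box (plus margin) defines a region of interest; stage 2 segments
tumor (and cyst) inside the cropped ROI; fine labels are pasted back into
full-volume coordinates.  Where the fine network predicts background on a
voxel the coarse stage called kidney, the kidney label is kept (toggleable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .slicing import make_stacks, reassemble
from .volume_io import KIDNEY, LabelVolume, NormalizationStats, Volume, normalize

DEFAULT_MARGIN = (4, 16, 16)  # slices, rows, cols


class NoKidneyFoundError(ValueError):
    """Raised when a coarse mask has no foreground to build an ROI from."""


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned half-open sub-volume bounds ``[lo, hi)`` with provenance."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    margin: tuple[int, int, int]
    source_shape: tuple[int, int, int]

    def __post_init__(self):
        for axis in range(3):
            if not (0 <= self.lo[axis] < self.hi[axis] <= self.source_shape[axis]):
                raise ValueError(
                    f"invalid box on axis {axis}: lo={self.lo}, hi={self.hi}, "
                    f"shape={self.source_shape}")

    @property
    def extent(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))


def extract_roi(coarse_mask, margin=DEFAULT_MARGIN) -> RoiBox:
    """Tight foreground bounding box expanded by ``margin``, clamped to bounds."""
    arr = coarse_mask.data if isinstance(coarse_mask, LabelVolume) else np.asarray(coarse_mask)
    if arr.ndim != 3:
        raise ValueError("coarse mask must be 3D")
    margin = tuple(int(m) for m in (margin if np.ndim(margin) else (margin,) * 3))
    if any(m < 0 for m in margin):
        raise ValueError("margin must be non-negative")
    fg = np.nonzero(arr)
    if fg[0].size == 0:
        raise NoKidneyFoundError("coarse mask contains no foreground voxels")
    lo = tuple(max(int(idx.min()) - m, 0) for idx, m in zip(fg, margin))
    hi = tuple(min(int(idx.max()) + 1 + m, s)
               for idx, m, s in zip(fg, margin, arr.shape))
    return RoiBox(lo=lo, hi=hi, margin=margin, source_shape=arr.shape)


def crop(obj, box: RoiBox):
    """Crop a Volume or LabelVolume to the box; the affine is translated."""
    if obj.data.shape != box.source_shape:
        raise ValueError(
            f"box built for shape {box.source_shape}, got {obj.data.shape}")
    affine = obj.affine.copy()
    affine[:3, 3] = affine[:3, 3] + affine[:3, :3] @ np.asarray(box.lo, dtype=float)
    return replace(obj, data=obj.data[box.slices].copy(), affine=affine)


def paste_back(fine_mask, box: RoiBox, vocabulary: str | None = None) -> LabelVolume:
    """Full-shape label volume: fine labels inside the box, background outside."""
    arr = fine_mask.data if isinstance(fine_mask, LabelVolume) else np.asarray(fine_mask)
    if arr.shape != box.extent:
        raise ValueError(f"fine mask shape {arr.shape} != box extent {box.extent}")
    if vocabulary is None:
        vocabulary = fine_mask.vocabulary if isinstance(fine_mask, LabelVolume) else "kits21"
    canvas = np.zeros(box.source_shape, dtype=np.int16)
    canvas[box.slices] = arr
    if isinstance(fine_mask, LabelVolume):
        affine = fine_mask.affine.copy()
        affine[:3, 3] = affine[:3, 3] - affine[:3, :3] @ np.asarray(box.lo, dtype=float)
        return LabelVolume(canvas, vocabulary=vocabulary, spacing=fine_mask.spacing,
                           affine=affine, case_id=fine_mask.case_id)
    return LabelVolume(canvas, vocabulary=vocabulary)


# ---------------------------------------------------------------------------
# slice predictors

class SlicePredictor:
    """Anything that maps a Volume to a LabelVolume slice by slice."""

    vocabulary: str = "kits21"

    def predict_volume(self, volume: Volume) -> LabelVolume:
        raise NotImplementedError


class NetworkPredictor(SlicePredictor):
    """Runs a trained network over 2.5D stacks of a (raw HU) volume.

    Handles normalization, edge policy, padding of extents not divisible by
    the network's downsampling factor, and batching.
    """

    def __init__(self, model, stats: NormalizationStats, k: int = 3,
                 vocabulary: str = "kits21", edge_policy: str = "replicate",
                 batch_size: int = 8):
        self.model = model
        self.stats = stats
        self.k = int(k)
        self.vocabulary = vocabulary
        self.edge_policy = edge_policy
        self.batch_size = int(batch_size)

    def predict_volume(self, volume: Volume) -> LabelVolume:
        vol = normalize(volume, self.stats)
        div = self.model.config.divisor
        ns, h, w = vol.data.shape
        ph = (-h) % div
        pw = (-w) % div
        data = vol.data
        if ph or pw:
            data = np.pad(data, ((0, 0), (0, ph), (0, pw)), mode="edge")
        padded = replace(vol, data=data)
        stacks = [s for s, _ in make_stacks(padded, None, k=self.k,
                                            edge_policy=self.edge_policy)]
        preds = []
        for i in range(0, len(stacks), self.batch_size):
            chunk = stacks[i:i + self.batch_size]
            batch = np.stack([s.channels for s in chunk])
            masks = self.model.predict_batch(batch)
            preds.extend((s.center_index, m[:h, :w]) for s, m in zip(chunk, masks))
        return reassemble(preds, num_slices=ns, vocabulary=self.vocabulary,
                          spacing=volume.spacing, affine=volume.affine,
                          case_id=volume.case_id)


class GroundTruthPredictor(SlicePredictor):
    """Oracle predictor backed by a reference label volume.

    Locates any (possibly cropped) sub-volume of its reference through the
    affine offset, so it can stand in for either cascade stage; ``label_map``
    optionally remaps labels (e.g. all foreground -> kidney for the coarse
    stage).
    """

    def __init__(self, reference: LabelVolume, label_map: dict[int, int] | None = None,
                 vocabulary: str | None = None):
        self.reference = reference
        self.label_map = label_map
        self.vocabulary = vocabulary or reference.vocabulary

    def predict_volume(self, volume: Volume) -> LabelVolume:
        ref = self.reference
        offset_world = volume.affine[:3, 3] - ref.affine[:3, 3]
        offset = np.linalg.solve(ref.affine[:3, :3], offset_world)
        lo = np.rint(offset).astype(int)
        if not np.allclose(offset, lo, atol=1e-6):
            raise ValueError("volume is not voxel-aligned with the reference labels")
        hi = lo + np.asarray(volume.data.shape)
        if (lo < 0).any() or (hi > np.asarray(ref.data.shape)).any():
            raise ValueError("volume extends outside the reference labels")
        out = ref.data[tuple(slice(l, h) for l, h in zip(lo, hi))].copy()
        if self.label_map is not None:
            mapped = np.zeros_like(out)
            for src, dst in self.label_map.items():
                mapped[out == src] = dst
            out = mapped
        return LabelVolume(out, vocabulary=self.vocabulary, spacing=volume.spacing,
                           affine=volume.affine, case_id=volume.case_id)


def coarse_label_map(vocabulary: str) -> dict[int, int]:
    """All foreground labels -> kidney (binary coarse-stage target)."""
    from .volume_io import VOCABULARIES
    return {v: (KIDNEY if v else 0) for v in sorted(VOCABULARIES[vocabulary])}


# ---------------------------------------------------------------------------

def run_cascade(volume: Volume, coarse: SlicePredictor, fine: SlicePredictor,
                margin=DEFAULT_MARGIN, keep_coarse_kidney: bool = True
                ) -> tuple[LabelVolume, dict]:
    """Full coarse-to-fine inference on one volume.

    Returns the fused label volume and an info dict with the ROI box and a
    ``no_kidney_found`` flag (set when the coarse stage finds nothing, in
    which case the output is all background).
    """
    info: dict = {"no_kidney_found": False, "roi": None}
    coarse_mask = coarse.predict_volume(volume)
    try:
        box = extract_roi(coarse_mask, margin=margin)
    except NoKidneyFoundError:
        warnings.warn("coarse stage found no kidney; returning all background")
        info["no_kidney_found"] = True
        empty = LabelVolume(np.zeros(volume.data.shape, dtype=np.int16),
                            vocabulary=fine.vocabulary, spacing=volume.spacing,
                            affine=volume.affine, case_id=volume.case_id)
        return empty, info
    info["roi"] = box
    fine_mask = fine.predict_volume(crop(volume, box))
    out = paste_back(fine_mask, box, vocabulary=fine.vocabulary)
    if keep_coarse_kidney:
        fill = (out.data == 0) & (coarse_mask.data > 0)
        data = out.data.copy()
        data[fill] = KIDNEY
        out = replace(out, data=data)
    out = replace(out, spacing=volume.spacing, affine=volume.affine,
                  case_id=volume.case_id)
    return out, info
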