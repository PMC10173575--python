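"""NIfTI volume and label I/O in the KiTS case layout, plus intensity
preprocessing.

Axis convention throughout the package: axis 0 is the axial (slice) axis, so
arrays have shape ``(num_slices, height, width)``.  Indexing is 0-based.

Normalization follows the usual CT recipe: clip to a Hounsfield window
(default [-200, 500], a soft-tissue/kidney range), then standardize with the
mean and standard deviation of the labelled foreground of the *training*
cases.  The standard deviation uses the population convention (divide by N)
and is floored at 1e-6.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from skimage.transform import resize

VOCABULARIES: dict[str, frozenset[int]] = {
    "kits19": frozenset({0, 1, 2}),
    "kits21": frozenset({0, 1, 2, 3}),
}

#: label meanings shared by both vocabularies (kits21 adds the cyst)
BACKGROUND, KIDNEY, TUMOR, CYST = 0, 1, 2, 3

DEFAULT_WINDOW = (-200.0, 500.0)
STD_EPS = 1e-6


@dataclass
class Volume:
    """A 3D intensity grid (HU) with voxel spacing and NIfTI affine."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    case_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with positive extents, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def num_slices(self) -> int:
        return self.data.shape[0]


@dataclass
class LabelVolume:
    """A 3D integer grid over a declared label vocabulary."""

    data: np.ndarray
    vocabulary: str = "kits21"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    case_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("label volume has non-integer values")
            self.data = rounded.astype(np.int16)
        else:
            self.data = self.data.astype(np.int16)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {self.data.shape}")
        if self.vocabulary not in VOCABULARIES:
            raise ValueError(f"unknown vocabulary {self.vocabulary!r}")
        allowed = VOCABULARIES[self.vocabulary]
        present = set(np.unique(self.data).tolist())
        bad = present - allowed
        if bad:
            raise ValueError(
                f"label value(s) {sorted(bad)} outside vocabulary "
                f"{self.vocabulary!r} (allowed: {sorted(allowed)})")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class NormalizationStats:
    mean: float
    std: float
    clip_low: float = DEFAULT_WINDOW[0]
    clip_high: float = DEFAULT_WINDOW[1]

    def __post_init__(self):
        if self.std <= 0:
            raise ValueError("std must be > 0")
        if self.clip_low >= self.clip_high:
            raise ValueError("clip_low must be < clip_high")


def _spacing_from(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_case(image_path: str | os.PathLike,
              label_path: str | os.PathLike | None = None,
              vocabulary: str = "kits21") -> tuple[Volume, LabelVolume | None]:
    """Load an imaging NIfTI and (optionally) its segmentation.

    Raises ``FileNotFoundError``/``nibabel`` I/O errors for unreadable files,
    ``ValueError`` on image/label shape mismatch or out-of-vocabulary labels.
    """
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    case_id = os.path.basename(os.path.dirname(str(image_path))) or "case"
    volume = Volume(data, spacing=_spacing_from(img), affine=img.affine, case_id=case_id)
    label = None
    if label_path is not None:
        seg = nib.load(str(label_path))
        seg_data = np.asanyarray(seg.dataobj)
        if seg_data.shape != data.shape:
            raise ValueError(
                f"image/label shape mismatch: {data.shape} vs {seg_data.shape}")
        label = LabelVolume(seg_data, vocabulary=vocabulary,
                            spacing=_spacing_from(seg), affine=seg.affine,
                            case_id=case_id)
    return volume, label


def write_image(volume: Volume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_label(label: LabelVolume, reference: Volume, path: str | os.PathLike) -> None:
    """Write a label grid as NIfTI carrying the reference volume's affine."""
    if label.data.shape != reference.data.shape:
        raise ValueError(
            f"label shape {label.data.shape} does not match reference {reference.data.shape}")
    img = nib.Nifti1Image(label.data.astype(np.int16), reference.affine)
    img.header.set_zooms(reference.spacing)
    nib.save(img, str(path))


def compute_foreground_stats(volume: Volume, label: LabelVolume,
                             window: tuple[float, float] = DEFAULT_WINDOW
                             ) -> NormalizationStats:
    """Mean/std of window-clipped intensities over ``label > 0`` voxels."""
    return compute_cohort_foreground_stats([(volume, label)], window=window)


def compute_cohort_foreground_stats(pairs, window: tuple[float, float] = DEFAULT_WINDOW
                                    ) -> NormalizationStats:
    """Foreground statistics pooled over several (Volume, LabelVolume) pairs.

    Used to freeze one set of normalization constants over the training split.
    """
    lo, hi = window
    n = 0
    s = 0.0
    s2 = 0.0
    for volume, label in pairs:
        if volume.data.shape != label.data.shape:
            raise ValueError("volume/label shape mismatch")
        fg = np.clip(volume.data[label.data > 0], lo, hi)
        n += fg.size
        s += float(fg.sum())
        s2 += float((fg ** 2).sum())
    if n == 0:
        raise ValueError("no foreground voxels: cannot compute normalization stats")
    mean = s / n
    var = max(s2 / n - mean ** 2, 0.0)
    std = max(float(np.sqrt(var)), STD_EPS)
    return NormalizationStats(mean=mean, std=std, clip_low=lo, clip_high=hi)


def normalize(volume: Volume, stats: NormalizationStats) -> Volume:
    """(clip(x) - mean) / std, preserving geometry metadata."""
    clipped = np.clip(volume.data, stats.clip_low, stats.clip_high)
    return replace(volume, data=(clipped - stats.mean) / stats.std)


def denormalize(volume: Volume, stats: NormalizationStats) -> Volume:
    """Inverse of :func:`normalize` (recovers the clipped intensities)."""
    return replace(volume, data=volume.data * stats.std + stats.mean)


def resample_inplane(volume, target_hw: tuple[int, int], is_label: bool = False):
    """Resample every axial slice to ``target_hw``.

    Linear interpolation for intensities, nearest-neighbour when
    ``is_label=True``.  In-plane spacing is rescaled accordingly.
    """
    th, tw = int(target_hw[0]), int(target_hw[1])
    if th < 1 or tw < 1:
        raise ValueError(f"target extents must be >= 1, got {target_hw}")
    data = volume.data
    ns, h, w = data.shape
    if (h, w) == (th, tw):
        return replace(volume, data=data.copy())
    order = 0 if is_label else 1
    out = resize(data.astype(np.float64), (ns, th, tw), order=order,
                 preserve_range=True, anti_aliasing=False)
    spacing = (volume.spacing[0], volume.spacing[1] * h / th, volume.spacing[2] * w / tw)
    if is_label:
        return replace(volume, data=np.rint(out).astype(np.int16), spacing=spacing)
    return replace(volume, data=out, spacing=spacing)


def case_paths(case_dir: str | os.PathLike) -> tuple[str, str]:
    """Return (imaging, segmentation) paths for a KiTS-layout case directory."""
    case_dir = str(case_dir)
    return (os.path.join(case_dir, "imaging.nii.gz"),
            os.path.join(case_dir, "segmentation.nii.gz"))
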