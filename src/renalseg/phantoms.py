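"""Deterministic KiTS-like synthetic cases.

Each case is a pair of ellipsoidal "kidneys" with optional spherical "tumor"
and "cyst" lesions, HU-like class-mean intensities plus Gaussian noise, in
the same (num_slices, height, width) layout and label coding as the real
data.  Label precedence is cyst > tumor > kidney: a voxel gets the most
specific label.  Identical spec + seed produces bit-identical cases.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .volume_io import (CYST, KIDNEY, LabelVolume, TUMOR, Volume, case_paths,
                        write_image, write_label)

DEFAULT_SHAPE = (24, 96, 96)


@dataclass
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    kidney_axes: tuple[float, float, float] = (6.0, 14.0, 10.0)
    kidney_centers: tuple[tuple[float, float, float], ...] = (
        (12.0, 48.0, 26.0), (12.0, 48.0, 70.0))
    tumor: Sphere | None = field(default_factory=lambda: Sphere((12.0, 40.0, 30.0), 5.0))
    cyst: Sphere | None = None
    intensity_means: dict[str, float] = field(default_factory=lambda: {
        "background": -50.0, "kidney": 120.0, "tumor": 60.0, "cyst": 10.0})
    noise_sigma: float = 10.0
    spacing: tuple[float, float, float] = (3.0, 1.0, 1.0)
    seed: int = 0

    def to_jsonable(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_jsonable(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("tumor", "cyst"):
            if d.get(key) is not None:
                s = d[key]
                d[key] = Sphere(tuple(s["center"]), float(s["radius"]))
        d["shape"] = tuple(d["shape"])
        d["kidney_axes"] = tuple(d["kidney_axes"])
        d["kidney_centers"] = tuple(tuple(c) for c in d["kidney_centers"])
        d["spacing"] = tuple(d["spacing"])
        return cls(**d)


def _ellipsoid_mask(shape, center, axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return q <= 1.0


def _sphere_mask(shape, sphere: Sphere) -> np.ndarray:
    return _ellipsoid_mask(shape, sphere.center, (sphere.radius,) * 3)


def generate_case(spec: PhantomSpec, case_id: str = "case_00000"
                  ) -> tuple[Volume, LabelVolume]:
    """Render one phantom into a (Volume, LabelVolume) pair."""
    shape = tuple(int(s) for s in spec.shape)
    if any(s < 1 for s in shape):
        raise ValueError("phantom shape extents must be >= 1")
    if any(a <= 0 for a in spec.kidney_axes):
        raise ValueError("kidney semi-axes must be positive")
    for c in spec.kidney_centers:
        if not all(0 <= ci < si for ci, si in zip(c, shape)):
            raise ValueError(f"kidney center {c} outside volume {shape}")

    kidney = np.zeros(shape, dtype=bool)
    for center in spec.kidney_centers:
        kidney |= _ellipsoid_mask(shape, center, spec.kidney_axes)

    labels = np.zeros(shape, dtype=np.int16)
    labels[kidney] = KIDNEY
    for lesion, value, name in ((spec.tumor, TUMOR, "tumor"),
                                (spec.cyst, CYST, "cyst")):
        if lesion is None:
            continue
        mask = _sphere_mask(shape, lesion)
        if not (mask & kidney).any():
            raise ValueError(f"{name} lies entirely outside both kidneys")
        labels[mask] = value  # precedence via write order: cyst last overwrites

    means = spec.intensity_means
    intensity = np.full(shape, means["background"], dtype=np.float64)
    intensity[labels == KIDNEY] = means["kidney"]
    intensity[labels == TUMOR] = means["tumor"]
    intensity[labels == CYST] = means["cyst"]
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity + rng.normal(0.0, spec.noise_sigma, size=shape)

    affine = np.diag(list(spec.spacing) + [1.0])
    volume = Volume(intensity, spacing=spec.spacing, affine=affine, case_id=case_id)
    label = LabelVolume(labels, vocabulary="kits21", spacing=spec.spacing,
                        affine=affine, case_id=case_id)
    return volume, label


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class CohortJitter:
    """Uniform jitter ranges applied per case around the base spec."""

    center_jitter: tuple[float, float, float] = (2.0, 6.0, 6.0)
    axes_scale: tuple[float, float] = (0.8, 1.2)
    tumor_radius: tuple[float, float] = (3.0, 6.0)
    cyst_radius: tuple[float, float] = (2.0, 4.0)
    tumor_prob: float = 0.9
    cyst_prob: float = 0.5

    def __post_init__(self):
        for name in ("tumor_prob", "cyst_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("axes_scale", "tumor_radius", "cyst_radius"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"infeasible jitter range for {name}: {(lo, hi)}")


def _sample_lesion(rng, center, axes, radius_range) -> Sphere:
    # place the lesion centre strictly inside one kidney so overlap is assured
    u = rng.uniform(-0.5, 0.5, size=3)
    c = tuple(float(ci + ui * ai) for ci, ui, ai in zip(center, u, axes))
    return Sphere(c, float(rng.uniform(*radius_range)))


def sample_cohort_specs(n: int, seed: int, base: PhantomSpec | None = None,
                        jitter: CohortJitter | None = None) -> list[PhantomSpec]:
    """Draw ``n`` per-case specs; pure function of its arguments."""
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base or PhantomSpec(tumor=None)
    jitter = jitter or CohortJitter()
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        centers = []
        for c in base.kidney_centers:
            off = rng.uniform(-1.0, 1.0, size=3) * np.asarray(jitter.center_jitter)
            centers.append(tuple(float(np.clip(ci + oi, 1, si - 2))
                                 for ci, oi, si in zip(c, off, base.shape)))
        axes = tuple(float(a * rng.uniform(*jitter.axes_scale))
                     for a in base.kidney_axes)
        tumor = None
        if rng.uniform() < jitter.tumor_prob:
            tumor = _sample_lesion(rng, centers[0], axes, jitter.tumor_radius)
        cyst = None
        if rng.uniform() < jitter.cyst_prob:
            host = centers[1] if len(centers) > 1 else centers[0]
            cyst = _sample_lesion(rng, host, axes, jitter.cyst_radius)
        specs.append(replace(base, kidney_centers=tuple(centers), kidney_axes=axes,
                             tumor=tumor, cyst=cyst, seed=int(rng.integers(2 ** 31))))
    return specs


def generate_cohort(out_dir: str | os.PathLike, n: int, seed: int,
                    base: PhantomSpec | None = None,
                    jitter: CohortJitter | None = None) -> list[str]:
    """Write ``n`` cases in the KiTS directory layout plus a JSON manifest.

    Returns the case directory paths.  Regenerating from the manifest's
    recorded specs reproduces every case bit-identically.
    """
    out_dir = str(out_dir)
    specs = sample_cohort_specs(n, seed, base=base, jitter=jitter)
    os.makedirs(out_dir, exist_ok=True)
    case_dirs = []
    manifest = {"n": n, "seed": seed, "cases": {}}
    for i, spec in enumerate(specs):
        case_id = f"case_{i:05d}"
        case_dir = os.path.join(out_dir, case_id)
        os.makedirs(case_dir, exist_ok=True)
        volume, label = generate_case(spec, case_id=case_id)
        img_path, seg_path = case_paths(case_dir)
        write_image(volume, img_path)
        write_label(label, volume, seg_path)
        manifest["cases"][case_id] = spec.to_jsonable()
        case_dirs.append(case_dir)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return case_dirs


def load_cohort(root: str | os.PathLike, vocabulary: str = "kits21"):
    """Load every ``case_*`` directory under ``root`` as (Volume, LabelVolume)."""
    from .volume_io import read_case
    root = str(root)
    cases = []
    for name in sorted(os.listdir(root)):
        case_dir = os.path.join(root, name)
        if not (name.startswith("case_") and os.path.isdir(case_dir)):
            continue
        img_path, seg_path = case_paths(case_dir)
        label_path = seg_path if os.path.exists(seg_path) else None
        cases.append(read_case(img_path, label_path, vocabulary=vocabulary))
    return cases
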