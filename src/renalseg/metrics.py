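"""Evaluation: smoothed mean Dice, tolerance-based Surface Dice, and the
KiTS-style hierarchical evaluation classes (HECs).

The per-image Dice term is the +1-smoothed coefficient

    (2 |A ∩ B| + 1) / (|A| + |B| + 1)

so two empty masks score 1.0 by construction.  Surface Dice is the fraction
of the two masks' boundary voxels lying within a distance tolerance of the
other boundary, computed with spacing-aware Euclidean distance transforms;
boundary voxels are foreground voxels with at least one face-adjacent
(6-connected) background voxel, treating everything outside the grid as
background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import LabelVolume

__all__ = [
    "HecDefinition", "DiceReport", "hecs_for", "binarize", "smoothed_dice",
    "mean_dice", "surface_dice", "boundary_voxels", "dice_report",
]


@dataclass(frozen=True)
class HecDefinition:
    """A named foreground grouping for scoring."""
    name: str
    foreground_labels: frozenset[int]


_KITS21_HECS = (
    HecDefinition("kidney", frozenset({1, 2, 3})),
    HecDefinition("mass", frozenset({2, 3})),
    HecDefinition("tumor", frozenset({2})),
    HecDefinition("cyst", frozenset({3})),
)
_KITS19_HECS = (
    HecDefinition("kidney", frozenset({1, 2})),
    HecDefinition("tumor", frozenset({2})),
)


def hecs_for(vocabulary: str) -> tuple[HecDefinition, ...]:
    if vocabulary == "kits21":
        return _KITS21_HECS
    if vocabulary == "kits19":
        return _KITS19_HECS
    raise ValueError(f"unknown vocabulary {vocabulary!r}")


def binarize(labels: np.ndarray, hec: HecDefinition) -> np.ndarray:
    return np.isin(labels, sorted(hec.foreground_labels))


def smoothed_dice(a: np.ndarray, b: np.ndarray) -> float:
    """+1-smoothed Dice of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    inter = np.count_nonzero(a & b)
    return (2.0 * inter + 1.0) / (np.count_nonzero(a) + np.count_nonzero(b) + 1.0)


def mean_dice(cases, hec: HecDefinition) -> float:
    """Mean smoothed Dice over (label, prediction) pairs for one HEC."""
    scores = []
    for label, pred in cases:
        la = label.data if isinstance(label, LabelVolume) else np.asarray(label)
        pa = pred.data if isinstance(pred, LabelVolume) else np.asarray(pred)
        scores.append(smoothed_dice(binarize(la, hec), binarize(pa, hec)))
    if not scores:
        raise ValueError("mean_dice requires at least one case")
    return float(np.mean(scores))


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with a face-adjacent background voxel (6-conn.).

    The volume border counts as background, so foreground touching the grid
    edge is boundary.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    eroded = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return mask & ~eroded


def surface_dice(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0, 1.0),
                 tolerance: float = 1.0) -> float:
    """Normalized surface overlap at a distance tolerance (mm)."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    sa = boundary_voxels(a)
    sb = boundary_voxels(b)
    na, nb = int(sa.sum()), int(sb.sum())
    if na == 0 and nb == 0:
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    spacing = tuple(float(s) for s in spacing)
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    matched_a = int(np.count_nonzero(dist_to_b[sa] <= tolerance + 1e-9))
    matched_b = int(np.count_nonzero(dist_to_a[sb] <= tolerance + 1e-9))
    return (matched_a + matched_b) / (na + nb)


@dataclass
class DiceReport:
    """Per-case and mean Dice / Surface Dice per HEC."""

    vocabulary: str
    per_case: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    # per_case[case_id][hec][metric] with metric in {"dice", "surface_dice"}

    @property
    def mean(self) -> dict[str, dict[str, float]]:
        hec_names = [h.name for h in hecs_for(self.vocabulary)]
        out: dict[str, dict[str, float]] = {}
        for hec in hec_names:
            for metric in ("dice", "surface_dice"):
                vals = [case[hec][metric] for case in self.per_case.values()
                        if metric in case.get(hec, {})]
                if vals:
                    out.setdefault(hec, {})[metric] = float(np.mean(vals))
        return out

    def to_rows(self) -> list[dict]:
        """Flat rows (case x hec) for CSV export; a final row holds the means."""
        rows = []
        for case_id in sorted(self.per_case):
            for hec, metrics_ in self.per_case[case_id].items():
                rows.append({"case": case_id, "hec": hec, **metrics_})
        for hec, metrics_ in self.mean.items():
            rows.append({"case": "MEAN", "hec": hec, **metrics_})
        return rows


def dice_report(cases: dict[str, tuple], vocabulary: str,
                tolerance: float = 2.0, compute_surface: bool = True) -> DiceReport:
    """Score ``{case_id: (label, prediction)}`` pairs for every HEC.

    Labels/predictions may be ``LabelVolume`` (spacing taken from the label)
    or plain arrays (unit spacing assumed).
    """
    report = DiceReport(vocabulary=vocabulary)
    for case_id, (label, pred) in cases.items():
        la = label.data if isinstance(label, LabelVolume) else np.asarray(label)
        pa = pred.data if isinstance(pred, LabelVolume) else np.asarray(pred)
        spacing = label.spacing if isinstance(label, LabelVolume) else (1.0, 1.0, 1.0)
        if la.shape != pa.shape:
            raise ValueError(f"case {case_id}: label/prediction shape mismatch")
        entry: dict[str, dict[str, float]] = {}
        for hec in hecs_for(vocabulary):
            am = binarize(la, hec)
            bm = binarize(pa, hec)
            scores = {"dice": smoothed_dice(am, bm)}
            if compute_surface:
                scores["surface_dice"] = surface_dice(am, bm, spacing, tolerance)
            entry[hec.name] = scores
        report.per_case[case_id] = entry
    return report
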