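"""Lesion / NAWM masks, mode-derived ROIs, and Dice overlap statistics.

Two routes to regions of interest are compared:

* the classical mask route — a lesion mask obtained by thresholding a
  FLAIR-like intensity volume (candidates from the CSF+lesion segmentation
  class intersected with white matter, kept when brighter than the 30th
  percentile of the robust intensity range [p2, p98]), with NAWM defined as
  the white matter not in the lesion mask; and

* the lesion-mask-free route — ``ROI[m1]`` (WM voxels with MWF strictly
  below the low mixture mode) and ``ROI[m2]`` (strictly above the high
  mode), derived from the fitted gamma mixture alone.

Their correspondence is quantified per subject with the Dice coefficient
``2 |A ∩ B| / (|A| + |B|)`` and, across subjects, with Welch two-sample
t-tests on the Dice lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "LabeledVolume",
    "MaskConsistencyError",
    "UndefinedOverlapError",
    "DiceComparison",
    "lesion_mask_from_intensities",
    "nawm_mask",
    "roi_from_modes",
    "dice",
    "compare_dice_groups",
    "robust_range_threshold",
    "load_masked_values",
]


class MaskConsistencyError(ValueError):
    """Label volumes violate the lesion ⊆ WM / partition contract."""


class UndefinedOverlapError(ValueError):
    """Dice is undefined: both masks are empty."""


@dataclass
class LabeledVolume:
    """A scalar 3D volume (MWF or intensity) with aligned label volumes.

    Invariants enforced at construction: all grids share one shape; the
    lesion and NAWM masks are subsets of the WM mask; when both are present
    they are disjoint and partition the WM mask.
    """

    values: np.ndarray
    wm: np.ndarray
    lesion: np.ndarray | None = None
    nawm: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wm = np.asarray(self.wm, dtype=bool)
        if self.values.shape != self.wm.shape:
            raise MaskConsistencyError("values and wm mask shapes differ")
        for name in ("lesion", "nawm"):
            m = getattr(self, name)
            if m is None:
                continue
            m = np.asarray(m, dtype=bool)
            if m.shape != self.values.shape:
                raise MaskConsistencyError(f"{name} mask shape differs from values")
            if (m & ~self.wm).any():
                raise MaskConsistencyError(f"{name} mask is not contained in the WM mask")
            setattr(self, name, m)
        if self.lesion is not None and self.nawm is not None:
            if (self.lesion & self.nawm).any():
                raise MaskConsistencyError("lesion and NAWM masks overlap")
            if not ((self.lesion | self.nawm) == self.wm).all():
                raise MaskConsistencyError("lesion and NAWM masks do not partition WM")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def wm_values(self) -> np.ndarray:
        """Scalar values pooled over the WM mask (the fitting input)."""
        return self.values[self.wm]

    # -- NIfTI round trip ---------------------------------------------------

    _FILES = {"values": "mwf.nii.gz", "wm": "wm.nii.gz",
              "lesion": "lesion.nii.gz", "nawm": "nawm.nii.gz"}

    def save(self, directory, values_name: str = "mwf.nii.gz") -> None:
        """Write the scalar volume and available masks as NIfTI files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        names = dict(self._FILES, values=values_name)
        for attr, fname in names.items():
            arr = getattr(self, attr)
            if arr is None:
                continue
            data = arr.astype(np.float32) if attr == "values" else arr.astype(np.uint8)
            nib.save(nib.Nifti1Image(data, self.affine), str(directory / fname))

    @classmethod
    def load(cls, directory, values_name: str = "mwf.nii.gz") -> "LabeledVolume":
        directory = Path(directory)
        img = nib.load(str(directory / values_name))
        values = np.asarray(img.dataobj, dtype=float)
        affine = img.affine
        masks = {}
        for attr in ("wm", "lesion", "nawm"):
            path = directory / cls._FILES[attr]
            if path.exists():
                masks[attr] = np.asarray(nib.load(str(path)).dataobj) > 0.5
            elif attr == "wm":
                raise FileNotFoundError(f"required WM mask missing: {path}")
            else:
                masks[attr] = None
        return cls(values=values, affine=affine, **masks)


def load_masked_values(scalar_path, mask_path) -> np.ndarray:
    """Load a NIfTI scalar map and return its values inside a NIfTI mask."""
    values = np.asarray(nib.load(str(scalar_path)).dataobj, dtype=float)
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0.5
    if values.shape != mask.shape:
        raise MaskConsistencyError("scalar map and mask shapes differ")
    return values[mask]


# --------------------------------------------------------------------------
# mask construction
# --------------------------------------------------------------------------


def robust_range_threshold(intensities: np.ndarray, fraction: float = 0.30) -> float:
    """Threshold at ``fraction`` of the robust intensity range [p2, p98].

    The robust range convention takes the 2nd and 98th percentiles of the
    nonzero image (linear interpolation between order statistics); the
    threshold interpolates linearly within that range:
    ``p2 + fraction * (p98 - p2)``.
    """
    nonzero = intensities[intensities != 0]
    if nonzero.size == 0:
        raise ValueError("intensity volume is identically zero")
    p2, p98 = np.percentile(nonzero, [2.0, 98.0])
    return float(p2 + fraction * (p98 - p2))


def lesion_mask_from_intensities(intensity: LabeledVolume, class3: np.ndarray) -> np.ndarray:
    """Lesion mask from a FLAIR-like volume and a CSF+lesion class map.

    Candidate voxels are the intersection of the third tissue class (which
    mixes CSF and WM lesions) with the WM mask; of these, only voxels with
    intensity strictly greater than the 30th percentile of the robust
    intensity range are kept.  An empty candidate set yields an empty mask
    with a warning rather than an error.
    """
    class3 = np.asarray(class3, dtype=bool)
    if class3.shape != intensity.shape:
        raise MaskConsistencyError("class3 mask shape differs from intensity volume")
    candidates = class3 & intensity.wm
    if not candidates.any():
        warnings.warn("no lesion candidate voxels (class3 ∩ WM empty); returning empty mask",
                      RuntimeWarning, stacklevel=2)
        return np.zeros(intensity.shape, dtype=bool)
    threshold = robust_range_threshold(intensity.values)
    return candidates & (intensity.values > threshold)


def nawm_mask(volume: LabeledVolume) -> np.ndarray:
    """Normal-appearing WM: the WM mask minus the lesion mask."""
    if volume.lesion is None:
        raise MaskConsistencyError("volume has no lesion mask")
    # lesion ⊆ wm is already enforced by LabeledVolume
    return volume.wm & ~volume.lesion


def roi_from_modes(volume: LabeledVolume, m1: float, m2: float) -> tuple[np.ndarray, np.ndarray]:
    """Mode-derived ROIs: WM voxels strictly below ``m1`` / strictly above ``m2``.

    Strict inequalities make the two ROIs disjoint for any valid
    ``0 <= m1 <= m2``; for continuous MWF values the voxels exactly at a
    mode have measure zero.
    """
    if not (0.0 <= m1 <= m2):
        raise ValueError(f"need 0 <= m1 <= m2, got m1={m1}, m2={m2}")
    roi_m1 = volume.wm & (volume.values < m1)
    roi_m2 = volume.wm & (volume.values > m2)
    return roi_m1, roi_m2


# --------------------------------------------------------------------------
# overlap statistics
# --------------------------------------------------------------------------


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2 |a ∩ b| / (|a| + |b|)`` of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    size = int(a.sum()) + int(b.sum())
    if size == 0:
        raise UndefinedOverlapError("Dice is undefined for two empty masks")
    return 2.0 * float((a & b).sum()) / size


@dataclass
class DiceComparison:
    """Group-level Welch comparison of Dice(ref, ROI[m1]) vs Dice(ref, ROI[m2])."""

    reference: str
    per_subject_dice_m1: list[float]
    per_subject_dice_m2: list[float]
    t_statistic: float
    df: float
    p_value: float
    direction: str  # "roi_m1" | "roi_m2" — side with the larger mean Dice
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not self.per_subject_dice_m1 or not self.per_subject_dice_m2:
            raise ValueError("Dice lists must be nonempty")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def compare_dice_groups(subjects, reference: str = "lesion") -> DiceComparison:
    """Welch two-sample t-test of per-subject Dice against the two ROIs.

    ``subjects`` is a sequence of ``(reference_mask, roi_m1, roi_m2)``
    triples (one per subject).  Subjects for which either Dice is undefined
    (reference and ROI both empty) are excluded with a warning.  The two
    Dice lists are compared with a two-sided Welch t-test (unequal
    variances, Welch–Satterthwaite degrees of freedom), as if they were
    independent samples.
    """
    from .regression import welch_t  # local import to avoid a cycle at import time

    d1, d2 = [], []
    n_excluded = 0
    for ref, roi1, roi2 in subjects:
        try:
            d1.append(dice(ref, roi1))
            d2.append(dice(ref, roi2))
        except UndefinedOverlapError:
            n_excluded += 1
            warnings.warn("subject excluded from Dice comparison (undefined overlap)",
                          RuntimeWarning, stacklevel=2)
    if len(d1) < 3:
        raise ValueError("need at least 3 subjects with defined Dice coefficients")
    res = welch_t(d1, d2)
    direction = "roi_m1" if float(np.mean(d1)) >= float(np.mean(d2)) else "roi_m2"
    return DiceComparison(reference=reference, per_subject_dice_m1=d1,
                          per_subject_dice_m2=d2, t_statistic=res.statistic,
                          df=res.df, p_value=res.p_value, direction=direction,
                          n_excluded=n_excluded)
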