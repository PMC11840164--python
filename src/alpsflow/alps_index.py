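"""ALPS index computation: ROI diffusivity extraction, the per-hemisphere
diffusion-along-perivascular-space ratio, and test-retest ICC.

The index reads the diagonal diffusivities of projection-fiber (z-dominant)
and association-fiber (y-dominant) ROIs at the lateral-ventricle-body level:

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

Dxx lies along the perivascular (left-right) axis; the denominator terms are
the fiber-dominant diffusivities orthogonal to both the fibers and the
perivascular direction, so the ratio isolates water mobility along the
perivascular space.  An isotropic tensor field gives exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dwi_tensor import TensorField, load_nifti

ROI_LABELS = {"proj_left": 1, "assoc_left": 2, "proj_right": 3, "assoc_right": 4}


# --------------------------------------------------------------------------
# ROI containers
# --------------------------------------------------------------------------

@dataclass
class ROISet:
    """Four disjoint voxel-index ROIs: projection / association x left / right.

    Each entry is an (n, 3) integer array of (i, j, k) voxel indices.
    """

    proj_left: np.ndarray
    assoc_left: np.ndarray
    proj_right: np.ndarray
    assoc_right: np.ndarray

    def __post_init__(self):
        seen = set()
        for name in ROI_LABELS:
            idx = np.asarray(getattr(self, name), dtype=int)
            if idx.ndim != 2 or idx.shape[1] != 3 or idx.shape[0] == 0:
                raise ValueError(f"ROI {name!r} must be a nonempty (n, 3) index array")
            tuples = set(map(tuple, idx))
            if seen & tuples:
                raise ValueError(f"ROI {name!r} overlaps another ROI")
            seen |= tuples
            setattr(self, name, idx)

    def validate_bounds(self, grid_shape) -> None:
        for name in ROI_LABELS:
            idx = getattr(self, name)
            if np.any(idx < 0) or np.any(idx >= np.asarray(grid_shape)):
                raise ValueError(f"ROI {name!r} has indices outside grid {grid_shape}")

    @classmethod
    def from_label_volume(cls, labels: np.ndarray) -> "ROISet":
        """Build from an integer label volume (codes 1-4, see ROI_LABELS)."""
        labels = np.asarray(labels)
        return cls(**{name: np.argwhere(labels == code)
                      for name, code in ROI_LABELS.items()})

    @classmethod
    def from_label_nifti(cls, path) -> "ROISet":
        data, _ = load_nifti(path)
        return cls.from_label_volume(np.rint(data).astype(int))

    @classmethod
    def from_boxes(cls, centers: dict, radius: int = 1) -> "ROISet":
        """Axis-aligned cubic ROIs of half-width ``radius`` around center voxels."""
        r = np.arange(-radius, radius + 1)
        offs = np.stack(np.meshgrid(r, r, r, indexing="ij"), axis=-1).reshape(-1, 3)
        return cls(**{name: np.asarray(centers[name], dtype=int) + offs
                      for name in ROI_LABELS})

    def to_label_volume(self, grid_shape) -> np.ndarray:
        vol = np.zeros(grid_shape, dtype=np.uint8)
        for name, code in ROI_LABELS.items():
            idx = getattr(self, name)
            vol[idx[:, 0], idx[:, 1], idx[:, 2]] = code
        return vol


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------

@dataclass
class ALPSResult:
    """ROI-mean diffusivities (mm^2/s) and the left/right/mean ALPS indices."""

    dxx_proj_left: float
    dxx_assoc_left: float
    dyy_proj_left: float
    dzz_assoc_left: float
    dxx_proj_right: float
    dxx_assoc_right: float
    dyy_proj_right: float
    dzz_assoc_right: float
    alps_left: float
    alps_right: float
    alps_mean: float
    voxel_counts: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {k: getattr(self, k) for k in
                ("alps_left", "alps_right", "alps_mean",
                 "dxx_proj_left", "dxx_assoc_left", "dyy_proj_left", "dzz_assoc_left",
                 "dxx_proj_right", "dxx_assoc_right", "dyy_proj_right", "dzz_assoc_right")}


@dataclass
class ICCResult:
    icc: float
    model_label: str
    n_subjects: int
    p_value: float
    flag: str | None = None


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def extract_roi_diffusivities(tensor_field: TensorField, roi: np.ndarray,
                              roi_name: str = "roi") -> tuple[float, float, float, int]:
    """Mean Dxx, Dyy, Dzz over the ROI voxels passing the fit mask.

    Returns (mean_dxx, mean_dyy, mean_dzz, n_voxels_used); raises if no ROI
    voxel survives the mask intersection.
    """
    roi = np.asarray(roi, dtype=int)
    use = tensor_field.usable[roi[:, 0], roi[:, 1], roi[:, 2]]
    if not use.any():
        raise ValueError(f"ROI {roi_name!r} has no voxels inside the tensor-fit mask")
    sel = roi[use]
    t = tensor_field.tensors[sel[:, 0], sel[:, 1], sel[:, 2]]
    return (float(t[:, 0, 0].mean()), float(t[:, 1, 1].mean()),
            float(t[:, 2, 2].mean()), int(use.sum()))


def compute_alps(dxx_proj: float, dxx_assoc: float,
                 dyy_proj: float, dzz_assoc: float) -> float:
    """The ALPS ratio mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)."""
    vals = (dxx_proj, dxx_assoc, dyy_proj, dzz_assoc)
    if not all(np.isfinite(vals)):
        raise ValueError("non-finite diffusivity input")
    denom = (dyy_proj + dzz_assoc) / 2.0
    if denom <= 0:
        raise ValueError("non-positive ALPS denominator (degenerate tensor field)")
    return ((dxx_proj + dxx_assoc) / 2.0) / denom


def compute_subject_alps(tensor_field: TensorField, rois: ROISet) -> ALPSResult:
    """Left and right ALPS indices and their arithmetic mean for one subject."""
    rois.validate_bounds(tensor_field.mask.shape)
    out: dict[str, float] = {}
    counts: dict[str, int] = {}
    for hemi in ("left", "right"):
        pxx, pyy, _, np_ = extract_roi_diffusivities(
            tensor_field, getattr(rois, f"proj_{hemi}"), f"proj_{hemi}")
        axx, _, azz, na = extract_roi_diffusivities(
            tensor_field, getattr(rois, f"assoc_{hemi}"), f"assoc_{hemi}")
        out[f"dxx_proj_{hemi}"] = pxx
        out[f"dxx_assoc_{hemi}"] = axx
        out[f"dyy_proj_{hemi}"] = pyy
        out[f"dzz_assoc_{hemi}"] = azz
        out[f"alps_{hemi}"] = compute_alps(pxx, axx, pyy, azz)
        counts[f"proj_{hemi}"] = np_
        counts[f"assoc_{hemi}"] = na
    return ALPSResult(alps_mean=(out["alps_left"] + out["alps_right"]) / 2.0,
                      voxel_counts=counts, **out)


def icc_test_retest(values_a, values_b) -> ICCResult:
    """Two-way mixed-effects, absolute-agreement, single-measure ICC — ICC(A,1).

    Computed from the standard two-way ANOVA mean squares with n subjects and
    k = 2 sessions:

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    The p-value is from F = MSR/MSE against F(n-1, (n-1)(k-1)) (test of zero
    subject variance).  Zero between-subject variance leaves the ICC
    undefined and is flagged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length 1D vectors with n >= 3")
    x = np.column_stack([a, b])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = (np.sum((x - grand) ** 2)
           - k * np.sum((row_means - grand) ** 2)
           - n * np.sum((col_means - grand) ** 2))
    mse = sse / ((n - 1) * (k - 1))
    label = "two-way mixed, absolute agreement, single measures (ICC(A,1))"
    if msr <= 0 or (msr == 0 and mse == 0):
        return ICCResult(icc=float("nan"), model_label=label, n_subjects=n,
                         p_value=float("nan"), flag="zero between-subject variance")
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return ICCResult(icc=float("nan"), model_label=label, n_subjects=n,
                         p_value=float("nan"), flag="degenerate mean squares")
    icc = float((msr - mse) / denom)
    if mse == 0:
        p = 0.0
    else:
        p = float(stats.f.sf(msr / mse, n - 1, (n - 1) * (k - 1)))
    return ICCResult(icc=icc, model_label=label, n_subjects=n, p_value=p)
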