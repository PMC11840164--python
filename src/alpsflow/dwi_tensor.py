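"""Diffusion signal model, tensor estimation and NIfTI / gradient-table I/O.

The signal model is the standard monoexponential diffusion tensor model

    S(b, g) = S0 * exp(-b * g^T D g)

with b in s/mm^2, g a unit gradient direction and D the symmetric 3x3
diffusion tensor in mm^2/s.  Fitting inverts the log-linearised model by
ordinary least squares over the 6 unique tensor elements plus log S0.

Coordinate convention (fixed throughout the package): x = left-right (the
perivascular axis), y = anterior-posterior (association fibers),
z = inferior-superior (projection fibers).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger("alpsflow")

#: relative tolerance for "exact" noise-free identities
NOISEFREE_RTOL = 1e-10

# lower-triangular storage order for 6-volume tensor NIfTIs
TENSOR_ELEMENT_ORDER = ("Dxx", "Dxy", "Dyy", "Dxz", "Dyz", "Dzz")
_LT_INDICES = ((0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2))


# --------------------------------------------------------------------------
# acquisition scheme
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionScheme:
    """b-values (s/mm^2) and unit gradient directions defining the signal model.

    Directions with b > 0 must be unit vectors; b = 0 entries may carry any
    vector (conventionally zero).  At least one b = 0 measurement and six
    non-collinear b > 0 directions are required to fit a tensor.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) disagree"
            )
        if np.any(bvals < 0):
            raise ValueError("negative b-value")
        dw = bvals > 0
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted bvecs must be unit norm (1e-6)")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_meas(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def validate_for_fit(self) -> None:
        """Require >=1 b0 and >=6 distinct non-collinear DW directions."""
        if not np.any(self.b0_mask):
            raise ValueError("scheme has no b=0 measurement")
        g = self.bvecs[~self.b0_mask]
        if g.shape[0] < 6:
            raise ValueError("fewer than 6 diffusion-weighted directions")
        # non-collinearity <=> the 6 quadratic-form monomials span R^6
        m = _design_rows(np.full(g.shape[0], 1.0), g)[:, 1:]
        if np.linalg.matrix_rank(m) < 6:
            raise ValueError("gradient directions are collinear/degenerate")


def _design_rows(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]."""
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    b = bvals
    return np.column_stack([
        np.ones_like(b),
        -b * gx * gx, -b * gy * gy, -b * gz * gz,
        -2 * b * gx * gy, -2 * b * gx * gz, -2 * b * gy * gz,
    ])


def _params_to_tensor(p: np.ndarray) -> np.ndarray:
    """(..., 7) design parameters -> (..., 3, 3) symmetric tensor (no s0)."""
    dxx, dyy, dzz, dxy, dxz, dyz = (p[..., i] for i in range(1, 7))
    t = np.empty(p.shape[:-1] + (3, 3))
    t[..., 0, 0] = dxx
    t[..., 1, 1] = dyy
    t[..., 2, 2] = dzz
    t[..., 0, 1] = t[..., 1, 0] = dxy
    t[..., 0, 2] = t[..., 2, 0] = dxz
    t[..., 1, 2] = t[..., 2, 1] = dyz
    return t


def _check_symmetric(tensor: np.ndarray) -> np.ndarray:
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != (3, 3):
        raise ValueError(f"tensor must be 3x3, got {tensor.shape}")
    if not np.allclose(tensor, tensor.T, rtol=0, atol=1e-12 * max(1.0, np.abs(tensor).max())):
        raise ValueError("tensor is not symmetric")
    return tensor


# --------------------------------------------------------------------------
# volumes and tensor fields
# --------------------------------------------------------------------------

@dataclass
class DWIVolume:
    """4D diffusion-weighted signal (x, y, z, measurement) with its scheme."""

    signal: np.ndarray
    scheme: AcquisitionScheme
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, measurement)")
        if self.signal.shape[3] != self.scheme.n_meas:
            raise ValueError(
                f"signal has {self.signal.shape[3]} measurements, "
                f"scheme has {self.scheme.n_meas}"
            )
        if np.any(self.signal < 0):
            raise ValueError("negative signal values")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class TensorField:
    """Per-voxel symmetric 3x3 diffusion tensors (mm^2/s) on a regular grid.

    ``mask`` excludes voxels where the fit failed or was never attempted;
    ``flagged`` marks fitted voxels with a negative diagonal element (kept,
    unclamped, but excluded from ROI means downstream).
    """

    tensors: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]
    s0: np.ndarray | None = None

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must have trailing shape (3, 3)")
        if self.tensors.shape[:-2] != self.mask.shape:
            raise ValueError("mask shape does not match tensor grid")
        if not np.allclose(self.tensors, np.swapaxes(self.tensors, -1, -2)):
            raise ValueError("stored tensors must be symmetric")
        if self.flagged is None:
            self.flagged = np.zeros_like(self.mask)
        diag = np.diagonal(self.tensors, axis1=-2, axis2=-1)
        bad = ~np.isfinite(diag).all(axis=-1) & self.mask
        if np.any(bad):
            raise ValueError("non-finite tensor diagonal inside mask")

    @property
    def usable(self) -> np.ndarray:
        """Voxels that fitted cleanly: in mask and not flagged."""
        return self.mask & ~self.flagged


# --------------------------------------------------------------------------
# forward model and fitting
# --------------------------------------------------------------------------

def predict_signal(tensor: np.ndarray, scheme: AcquisitionScheme, s0: float) -> np.ndarray:
    """Predict the DW signal s0*exp(-b g^T D g) for every measurement.

    Parameters
    ----------
    tensor : (3, 3) symmetric array, mm^2/s
    scheme : AcquisitionScheme
    s0 : positive non-diffusion-weighted signal

    Returns
    -------
    (n_meas,) signal vector; equals ``s0`` exactly wherever b = 0.
    """
    tensor = _check_symmetric(tensor)
    if not s0 > 0:
        raise ValueError("s0 must be positive")
    g = scheme.bvecs
    quad = np.einsum("ni,ij,nj->n", g, tensor, g)
    return s0 * np.exp(-scheme.bvals * quad)


def fit_tensor(signals: np.ndarray, scheme: AcquisitionScheme) -> tuple[np.ndarray, float]:
    """Ordinary least squares tensor fit on log-signals.

    Solves log S = log S0 - b g^T D g for the six unique tensor elements and
    log S0.  Non-positive signals are dropped with a warning; at least 7
    usable measurements including one b=0 are required.

    Returns
    -------
    (tensor, s0) : symmetric (3, 3) array in mm^2/s and the estimated S0.
    """
    signals = np.asarray(signals, dtype=float).ravel()
    if signals.shape[0] != scheme.n_meas:
        raise ValueError("signal length does not match scheme")
    usable = signals > 0
    n_dropped = int(np.sum(~usable))
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} non-positive signal(s) from tensor fit",
                      stacklevel=2)
    if usable.sum() < 7 or not np.any(usable & scheme.b0_mask):
        raise ValueError("fewer than 7 usable measurements (incl. b=0) for tensor fit")
    sub = AcquisitionScheme(scheme.bvals[usable], scheme.bvecs[usable])
    sub.validate_for_fit()
    design = _design_rows(sub.bvals, sub.bvecs)
    params, *_ = np.linalg.lstsq(design, np.log(signals[usable]), rcond=None)
    return _params_to_tensor(params), float(np.exp(params[0]))


def fit_volume(dwi: DWIVolume, mask: np.ndarray | None = None) -> TensorField:
    """Voxel-wise tensor fit over a 4D volume.

    Voxels whose fit fails (non-positive signals leaving <7 usable
    measurements) are removed from the output mask; voxels with a negative
    fitted diagonal are kept but flagged.  The shared design matrix is solved
    once for all all-positive voxels; degenerate voxels fall back to the
    per-voxel path.
    """
    if mask is None:
        mask = np.ones(dwi.spatial_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.spatial_shape:
        raise ValueError("mask shape does not match volume")
    if not mask.any():
        raise ValueError("empty mask")
    dwi.scheme.validate_for_fit()

    shape = dwi.spatial_shape
    tensors = np.zeros(shape + (3, 3))
    s0 = np.zeros(shape)
    out_mask = np.zeros(shape, dtype=bool)
    flagged = np.zeros(shape, dtype=bool)

    sig = dwi.signal[mask]  # (n_vox, n_meas)
    all_pos = (sig > 0).all(axis=1)
    design = _design_rows(dwi.scheme.bvals, dwi.scheme.bvecs)

    params = np.full((sig.shape[0], 7), np.nan)
    if all_pos.any():
        sol, *_ = np.linalg.lstsq(design, np.log(sig[all_pos]).T, rcond=None)
        params[all_pos] = sol.T
    ok = all_pos.copy()
    for i in np.flatnonzero(~all_pos):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t, s = fit_tensor(sig[i], dwi.scheme)
            params[i, 0] = np.log(s)
            params[i, 1:] = [t[0, 0], t[1, 1], t[2, 2], t[0, 1], t[0, 2], t[1, 2]]
            ok[i] = True
        except ValueError:
            ok[i] = False

    vox = np.argwhere(mask)
    good = vox[ok]
    tensors[good[:, 0], good[:, 1], good[:, 2]] = _params_to_tensor(params[ok])
    s0[good[:, 0], good[:, 1], good[:, 2]] = np.exp(params[ok, 0])
    out_mask[good[:, 0], good[:, 1], good[:, 2]] = True
    diag_neg = np.diagonal(tensors, axis1=-2, axis2=-1).min(axis=-1) < 0
    flagged = out_mask & diag_neg

    n_failed = int((~ok).sum())
    if n_failed:
        logger.info("tensor fit failed in %d voxel(s)", n_failed)
    if flagged.any():
        logger.info("negative diagonal flagged in %d voxel(s)", int(flagged.sum()))
    return TensorField(tensors=tensors, mask=out_mask, voxel_size=dwi.voxel_size,
                       flagged=flagged, s0=s0)


# --------------------------------------------------------------------------
# FSL-dialect gradient tables
# --------------------------------------------------------------------------

def read_gradient_table(bval_path, bvec_path) -> AcquisitionScheme:
    """Read FSL-dialect bval/bvec files.

    bvals: one whitespace-separated row; bvecs: three rows (x, y, z).
    Diffusion-weighted vectors whose norm deviates from 1 by more than 1e-3
    are re-normalized with a warning.
    """
    bvals = np.loadtxt(bval_path, ndmin=2)
    if bvals.shape[0] != 1:
        raise ValueError(f"{bval_path}: expected a single row of b-values, "
                         f"got {bvals.shape[0]} rows")
    bvals = bvals.ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise ValueError(f"{bvec_path}: expected 3 rows (x, y, z components), "
                         f"got {bvecs.shape[0]} rows")
    if bvecs.shape[1] != bvals.shape[0]:
        raise ValueError(f"{bvec_path}: {bvecs.shape[1]} vectors but "
                         f"{bvals.shape[0]} b-values in {bval_path}")
    bvecs = bvecs.T.copy()
    dw = bvals > 0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    off = np.abs(norms - 1.0) > 1e-3
    if np.any(norms == 0):
        raise ValueError(f"{bvec_path}: zero vector for a diffusion-weighted entry")
    if np.any(off):
        warnings.warn(f"{bvec_path}: re-normalizing {int(off.sum())} gradient "
                      "vector(s) with norm off unity by >1e-3", stacklevel=2)
    bvecs[dw] = bvecs[dw] / norms[:, None]
    return AcquisitionScheme(bvals, bvecs)


def write_gradient_table(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    """Write FSL-dialect bval/bvec text files (round-trips with the reader)."""
    with open(bval_path, "w") as f:
        f.write(" ".join(format(v, ".6g") for v in scheme.bvals) + "\n")
    with open(bvec_path, "w") as f:
        for axis in range(3):
            f.write(" ".join(format(v, ".10g") for v in scheme.bvecs[:, axis]) + "\n")


# --------------------------------------------------------------------------
# NIfTI I/O (canonical frame, identity-scaled affine)
# --------------------------------------------------------------------------

def _affine(voxel_size) -> np.ndarray:
    a = np.eye(4)
    a[0, 0], a[1, 1], a[2, 2] = voxel_size
    return a


def save_nifti(data: np.ndarray, voxel_size, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), _affine(voxel_size)), str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), vs


def save_tensor_field(field: TensorField, path) -> None:
    """Store a TensorField as a 6-volume lower-triangular NIfTI
    (order Dxx, Dxy, Dyy, Dxz, Dyz, Dzz); mask/flags are not stored."""
    data = np.stack([field.tensors[..., i, j] for i, j in _LT_INDICES], axis=-1)
    save_nifti(data, field.voxel_size, path)


def load_tensor_field(path, mask: np.ndarray | None = None) -> TensorField:
    data, vs = load_nifti(path)
    if data.ndim != 4 or data.shape[3] != 6:
        raise ValueError("tensor NIfTI must have 6 volumes (lower-triangular order)")
    shape = data.shape[:3]
    tensors = np.zeros(shape + (3, 3))
    for k, (i, j) in enumerate(_LT_INDICES):
        tensors[..., i, j] = data[..., k]
        tensors[..., j, i] = data[..., k]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    return TensorField(tensors=tensors, mask=np.asarray(mask, dtype=bool), voxel_size=vs)
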