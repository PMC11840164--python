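"""Synthetic diffusion phantoms and synthetic cohorts with known ground truth.

Phantoms
--------
A rectangular grid holds four fiber compartments (projection / association x
left / right hemisphere) in an isotropic background.  Projection-fiber
tensors are z-dominant, association-fiber tensors y-dominant, and a
perivascular parameter ``g`` (mm^2/s) adds x-axis diffusivity to BOTH
compartments — the minimal mechanism that moves the ALPS numerator while the
denominator stays fixed.  The closed-form ALPS ground truth is therefore

    ALPS = (g + radial) / radial        (per hemisphere)

Cohorts
-------
Subject tables emulate a two-group observational study: a patient group with
reduced perivascular diffusion (Parkinson's disease, PD) versus normal
controls (NC).  Per-hemisphere ALPS values are bivariate normal with the
group means/SDs of the emulated study; regional grey-matter volumes (GMV)
load on ALPS (path a), and the cognitive score (MMSE, 0-30) loads on GMV
(path b) and directly on ALPS (path c'), giving a known mediation structure
with true indirect effect a*b and true proportion mediated 100*a*b/c.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .alps_index import ROISet
from .dwi_tensor import AcquisitionScheme, DWIVolume, TensorField, predict_signal

# --------------------------------------------------------------------------
# acquisition defaults: b = 1000 s/mm^2, 128 directions, 2 mm isotropic
# --------------------------------------------------------------------------

DEFAULT_BVALUE = 1000.0
DEFAULT_N_DIRECTIONS = 128
DEFAULT_VOXEL_SIZE = (2.0, 2.0, 2.0)


def fibonacci_directions(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5 ** 0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(1 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def default_scheme(n_directions: int = DEFAULT_N_DIRECTIONS,
                   bvalue: float = DEFAULT_BVALUE, n_b0: int = 1) -> AcquisitionScheme:
    """b0 measurement(s) followed by a uniform shell of DW directions."""
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, bvalue)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), fibonacci_directions(n_directions)])
    return AcquisitionScheme(bvals, bvecs)


# --------------------------------------------------------------------------
# phantom
# --------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry, diffusivities and noise for a two-hemisphere fiber phantom.

    ``g_left``/``g_right`` are the perivascular x-axis diffusivity increments
    (mm^2/s); ``g`` sets both at once.  axial > radial > 0 required.
    """

    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    axial: float = 1.4e-3
    radial: float = 0.4e-3
    background: float = 0.7e-3
    g_left: float = 0.0
    g_right: float = 0.0
    noise: str = "none"          # none | gaussian | rician
    snr: float = 30.0            # S0 / sigma
    s0: float = 1000.0
    n_directions: int = DEFAULT_N_DIRECTIONS
    bvalue: float = DEFAULT_BVALUE
    seed: int = 0

    def __init__(self, g: float | None = None, **kwargs):
        for f_ in self.__dataclass_fields__.values():
            setattr(self, f_.name, kwargs.pop(f_.name, f_.default))
        if kwargs:
            raise TypeError(f"unknown PhantomSpec fields: {sorted(kwargs)}")
        if g is not None:
            self.g_left = self.g_right = g
        if not (self.axial > self.radial > 0):
            raise ValueError("require axial > radial > 0")
        if min(self.g_left, self.g_right) < 0:
            raise ValueError("perivascular parameter g must be >= 0")
        if self.noise not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    def closed_form_alps(self) -> tuple[float, float, float]:
        """Ground-truth (left, right, mean) ALPS = (g + radial)/radial."""
        left = (self.g_left + self.radial) / self.radial
        right = (self.g_right + self.radial) / self.radial
        return left, right, (left + right) / 2.0


def g_for_alps(alps: float, radial: float = 0.4e-3) -> float:
    """Perivascular parameter whose closed-form ALPS equals ``alps``."""
    if alps < 1.0:
        raise ValueError("phantom ALPS ground truth cannot go below 1")
    return (alps - 1.0) * radial


def _compartment_boxes(shape):
    nx, ny, nz = shape
    if min(nx, ny) < 12 or nz < 7:
        raise ValueError("grid too small for the four fiber compartments")
    hx = nx // 2
    # (x-slice, y-slice) per compartment; z spans the interior
    return {
        "proj_left":   (slice(1, hx - 1),      slice(1, ny // 2 - 1)),
        "assoc_left":  (slice(1, hx - 1),      slice(ny // 2 + 1, ny - 1)),
        "proj_right":  (slice(hx + 1, nx - 1), slice(1, ny // 2 - 1)),
        "assoc_right": (slice(hx + 1, nx - 1), slice(ny // 2 + 1, ny - 1)),
    }


def _roi_centers(shape):
    nx, ny, nz = shape
    boxes = _compartment_boxes(shape)
    centers = {}
    for name, (xs, ys) in boxes.items():
        centers[name] = ((xs.start + xs.stop - 1) // 2,
                         (ys.start + ys.stop - 1) // 2,
                         nz // 2)
    return centers


def ground_truth_tensors(spec: PhantomSpec) -> TensorField:
    """The noiseless tensor field the phantom signals are generated from."""
    shape = spec.grid_shape
    tensors = np.zeros(shape + (3, 3))
    tensors[..., 0, 0] = spec.background
    tensors[..., 1, 1] = spec.background
    tensors[..., 2, 2] = spec.background
    boxes = _compartment_boxes(shape)
    zs = slice(1, shape[2] - 1)
    for name, (xs, ys) in boxes.items():
        g = spec.g_left if name.endswith("left") else spec.g_right
        if name.startswith("proj"):
            diag = (g + spec.radial, spec.radial, spec.axial)
        else:
            diag = (g + spec.radial, spec.axial, spec.radial)
        for ax, v in enumerate(diag):
            tensors[xs, ys, zs, ax, ax] = v
    return TensorField(tensors=tensors, mask=np.ones(shape, dtype=bool),
                       voxel_size=spec.voxel_size)


def generate_phantom(spec: PhantomSpec) -> tuple[DWIVolume, TensorField, ROISet]:
    """Simulate DW signals from the phantom tensors under the spec's scheme.

    Returns the noisy (or noise-free) 4D volume, the ground-truth tensor
    field, and a ROISet of 3x3x3 boxes centred inside each compartment.
    Rician noise is applied as the magnitude of a complex Gaussian with
    sigma = s0 / snr; identical spec + seed is bit-reproducible.
    """
    truth = ground_truth_tensors(spec)
    scheme = default_scheme(spec.n_directions, spec.bvalue)
    shape = spec.grid_shape

    # distinct tensors are few: predict once per unique diagonal
    diags = np.diagonal(truth.tensors, axis1=-2, axis2=-1).reshape(-1, 3)
    uniq, inverse = np.unique(diags, axis=0, return_inverse=True)
    sig_uniq = np.empty((uniq.shape[0], scheme.n_meas))
    for i, d in enumerate(uniq):
        sig_uniq[i] = predict_signal(np.diag(d), scheme, spec.s0)
    signal = sig_uniq[inverse].reshape(shape + (scheme.n_meas,))

    if spec.noise != "none":
        rng = np.random.default_rng(spec.seed)
        sigma = spec.s0 / spec.snr
        if spec.noise == "gaussian":
            signal = np.clip(signal + rng.normal(0, sigma, signal.shape), 0, None)
        else:  # rician: magnitude of complex Gaussian
            re = signal + rng.normal(0, sigma, signal.shape)
            im = rng.normal(0, sigma, signal.shape)
            signal = np.hypot(re, im)

    rois = ROISet.from_boxes(_roi_centers(shape), radius=1)
    rois.validate_bounds(shape)
    # sanity: every ROI voxel must lie inside its compartment
    boxes = _compartment_boxes(shape)
    for name in boxes:
        idx = getattr(rois, name)
        xs, ys = boxes[name]
        inside = ((idx[:, 0] >= xs.start) & (idx[:, 0] < xs.stop)
                  & (idx[:, 1] >= ys.start) & (idx[:, 1] < ys.stop)
                  & (idx[:, 2] >= 1) & (idx[:, 2] < shape[2] - 1))
        if not inside.all():
            raise ValueError(f"ROI {name!r} extends outside its fiber compartment")

    dwi = DWIVolume(signal=signal, scheme=scheme, voxel_size=spec.voxel_size)
    return dwi, truth, rois


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

@dataclass
class RegionSpec:
    """One grey-matter region: mean volume (cm^3), ALPS->GMV path a
    (cm^3 per ALPS unit), GMV->MMSE path b (points per cm^3), residual SD."""

    mean: float
    a: float
    b: float
    noise_sd: float
    # optional covariate loadings on (age, sex, education, tiv), centered
    loadings: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)


def _default_regions() -> dict[str, RegionSpec]:
    # a-paths from the study's printed ALPS-GMV partial correlations at unit
    # region SD (a = r / sd_alps, sd_alps = 0.17); residual SD sqrt(1 - r^2)
    # keeps each region's total SD near 1 cm^3.  b-paths are nonzero only for
    # the two mediating regions and are set so the true proportions mediated
    # are 17.49% (anterior cingulate) and 32.24% (orbital inferior frontal)
    # of a total ALPS->MMSE effect c = 14 points per ALPS unit.
    c_total = 14.0
    ind_acg = 0.1749 * c_total
    ind_orifg = 0.3224 * c_total
    r = {"temporal_pole": 0.43, "posterior_orbital_gyrus": 0.38,
         "orbital_inferior_frontal_gyrus": 0.47, "frontal_operculum": 0.39,
         "central_operculum": 0.40, "anterior_cingulate_gyrus": 0.41}
    means = {"temporal_pole": 9.0, "posterior_orbital_gyrus": 4.0,
             "orbital_inferior_frontal_gyrus": 5.0, "frontal_operculum": 3.5,
             "central_operculum": 5.5, "anterior_cingulate_gyrus": 8.0}
    regions = {}
    for name, rv in r.items():
        a = rv / 0.17
        if name == "anterior_cingulate_gyrus":
            b = ind_acg / a
        elif name == "orbital_inferior_frontal_gyrus":
            b = ind_orifg / a
        else:
            b = 0.0
        regions[name] = RegionSpec(mean=means[name], a=a, b=b,
                                   noise_sd=float(np.sqrt(1 - rv ** 2)))
    return regions


@dataclass
class CohortSpec:
    """Group sizes, ALPS distributions, covariates and mediation paths.

    Defaults reproduce the emulated study's printed group parameters:
    PD n=51 with per-hemisphere ALPS 1.46+/-0.19 (L) and 1.44+/-0.18 (R),
    NC n=30 with 1.62+/-0.17 (L) and 1.66+/-0.20 (R); the inter-hemisphere
    correlation 0.688 is the value that makes SD[(L+R)/2] equal the printed
    0.17 in both groups.
    """

    n_pd: int = 51
    n_nc: int = 30
    alps_pd: tuple[float, float, float, float] = (1.46, 0.19, 1.44, 0.18)  # muL,sdL,muR,sdR
    alps_nc: tuple[float, float, float, float] = (1.62, 0.17, 1.66, 0.20)
    hemisphere_rho: float = 0.688
    age_pd: tuple[float, float] = (61.65, 8.27)
    age_nc: tuple[float, float] = (59.2, 5.90)
    p_male_pd: float = 28 / 51
    p_male_nc: float = 11 / 30
    education_pd: tuple[float, float] = (12.3, 3.7)
    education_nc: tuple[float, float] = (13.0, 3.2)
    tiv: tuple[float, float] = (1450.0, 120.0)   # cm^3
    regions: dict[str, RegionSpec] = field(default_factory=_default_regions)
    c_prime: float | None = None   # direct ALPS->MMSE path; None => c - sum(a*b)
    c_total: float = 14.0          # total ALPS->MMSE effect, points per ALPS unit
    mmse_ref: float = 23.9         # E[MMSE] at the reference ALPS
    alps_ref: float = 1.45         # reference (PD mean) ALPS for centering
    mmse_noise_sd: float = 3.2
    mmse_discretize: bool = True   # False: raw continuous score for analytic checks
    seed: int = 0

    def __post_init__(self):
        if min(self.n_pd, self.n_nc) < 3:
            raise ValueError("group sizes must be >= 3")
        sds = [self.alps_pd[1], self.alps_pd[3], self.alps_nc[1], self.alps_nc[3],
               self.tiv[1], self.mmse_noise_sd]
        sds += [r.noise_sd for r in self.regions.values()]
        if any(s <= 0 for s in sds):
            raise ValueError("all SDs must be > 0")

    @property
    def indirect_effects(self) -> dict[str, float]:
        return {name: r.a * r.b for name, r in self.regions.items()}

    @property
    def direct_effect(self) -> float:
        if self.c_prime is not None:
            return self.c_prime
        return self.c_total - sum(self.indirect_effects.values())

    @property
    def total_effect(self) -> float:
        return self.direct_effect + sum(self.indirect_effects.values())

    def ground_truth(self) -> dict:
        """True paths and proportions mediated, emitted alongside the data."""
        c = self.total_effect
        per_region = {}
        for name, r in self.regions.items():
            ind = r.a * r.b
            per_region[name] = {
                "a": r.a, "b": r.b, "indirect": ind,
                "proportion_mediated_pct": 100.0 * ind / c if c != 0 else float("nan"),
            }
        return {"c_total": c, "c_prime": self.direct_effect,
                "regions": per_region, "seed": self.seed}


#: column order of the cohort table
SUBJECT_COLUMNS = ("subject_id", "group", "age", "sex", "education", "tiv",
                   "mmse", "alps_l", "alps_r", "alps_m")


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a subject table with the spec's group and mediation structure.

    Returns (cohort, ground_truth).  The cohort DataFrame has one row per
    subject with columns SUBJECT_COLUMNS plus ``gmv_<region>`` per region;
    sex is encoded 0/1 (1 = male); MMSE is rounded and clamped to [0, 30].
    Identical spec + seed reproduces the table bit-for-bit.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group, n in (("PD", spec.n_pd), ("NC", spec.n_nc)):
        mul, sdl, mur, sdr = spec.alps_pd if group == "PD" else spec.alps_nc
        rho = spec.hemisphere_rho
        cov = np.array([[sdl ** 2, rho * sdl * sdr], [rho * sdl * sdr, sdr ** 2]])
        lr = rng.multivariate_normal([mul, mur], cov, size=n)
        age_mu, age_sd = spec.age_pd if group == "PD" else spec.age_nc
        edu_mu, edu_sd = spec.education_pd if group == "PD" else spec.education_nc
        p_male = spec.p_male_pd if group == "PD" else spec.p_male_nc
        for i in range(n):
            rows.append({
                "group": group,
                "alps_l": lr[i, 0], "alps_r": lr[i, 1],
                "alps_m": (lr[i, 0] + lr[i, 1]) / 2.0,
                "age": rng.normal(age_mu, age_sd),
                "sex": int(rng.random() < p_male),
                "education": max(0.0, rng.normal(edu_mu, edu_sd)),
                "tiv": rng.normal(*spec.tiv),
            })
    df = pd.DataFrame(rows)
    df.insert(0, "subject_id", [f"S{i:03d}" for i in range(len(df))])

    # covariates centered at their nominal means so zero loadings are inert
    cov_centered = np.column_stack([
        df["age"] - np.mean([spec.age_pd[0], spec.age_nc[0]]),
        df["sex"] - 0.5,
        df["education"] - np.mean([spec.education_pd[0], spec.education_nc[0]]),
        df["tiv"] - spec.tiv[0],
    ])
    alps_c = df["alps_m"].to_numpy() - spec.alps_ref

    mmse = spec.mmse_ref + spec.direct_effect * alps_c
    for name, r in spec.regions.items():
        gmv = (r.mean + r.a * alps_c + cov_centered @ np.asarray(r.loadings)
               + rng.normal(0, r.noise_sd, len(df)))
        df[f"gmv_{name}"] = gmv
        mmse = mmse + r.b * (gmv - r.mean)
    mmse = mmse + rng.normal(0, spec.mmse_noise_sd, len(df))
    if spec.mmse_discretize:
        clamped = (mmse < 0) | (mmse > 30)
        if clamped.mean() > 0.20:
            import warnings
            warnings.warn(f"{100 * clamped.mean():.0f}% of MMSE values clamped "
                          "to [0, 30]", stacklevel=2)
        df["mmse"] = np.clip(np.rint(mmse), 0, 30).astype(int)
    else:
        df["mmse"] = mmse

    order = list(SUBJECT_COLUMNS) + [f"gmv_{n}" for n in spec.regions]
    truth = spec.ground_truth()
    truth["spec"] = {k: v for k, v in asdict(spec).items() if k != "regions"}
    truth["spec"]["regions"] = {n: asdict(r) for n, r in spec.regions.items()}
    return df[order], truth
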