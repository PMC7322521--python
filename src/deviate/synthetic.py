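"""Synthetic cohorts, smooth thickness fields, cases, and lesioned phantoms.

This module is the statistical stand-in for data the analysis was designed
for: a large adult control cohort with age/sex/handedness covariates, smooth
per-vertex thickness maps generated from known linear covariate effects plus
a stationary Gaussian noise field of known FWHM, single cases with a focal
thickness deviation injected over a connected patch, and toy lesioned
volumes for the lesion-fill stage.

Defaults mirror the study conditions the pipeline targets: 188 controls with
mean age 52.2 y (SD 9.5), 140/188 female, 169/188 right-handed, ages
truncated below at 18 (an adult cohort selected within 15 years of cases
aged 43-54); residual noise SD 0.2 mm (a conventional morphometry scale —
control thickness variance is not something the cohort description pins
down) with FWHM three times the mesh's mean edge length; and a focal case
effect of +0.72 mm, the difference between an observed regional mean of
3.05 mm and its normative prediction of 2.33 mm.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import ndimage

from .errors import DataError, IntegrityError
from .glm import DEFAULT_CODING, DESIGN_COLUMNS, design_row
from .mesh import TriangleMesh, VertexMap, vertex_areas
from .rft import estimate_field_fwhm
from .volume import MaskVolume, VolumeImage

# study-condition defaults
DEFAULT_N = 188
DEFAULT_AGE_MEAN = 52.2
DEFAULT_AGE_SD = 9.5
DEFAULT_P_FEMALE = 140 / 188
DEFAULT_P_RIGHT = 169 / 188
AGE_FLOOR = 18.0
DEFAULT_SIGMA = 0.2  # mm
DEFAULT_DELTA = 0.72  # mm = 3.05 - 2.33
MIN_THICKNESS = 0.1  # mm clip floor


def icosphere(subdivisions: int = 4, radius: float = 70.0) -> TriangleMesh:
    """Icosphere test surface; radius 70 mm gives a hemisphere-scale area."""
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces))


# ------------------------------------------------------------------ cohort
def generate_cohort(
    n: int = DEFAULT_N,
    age_mean: float = DEFAULT_AGE_MEAN,
    age_sd: float = DEFAULT_AGE_SD,
    p_female: float = DEFAULT_P_FEMALE,
    p_right: float = DEFAULT_P_RIGHT,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a control cohort table (id, age, sex, handedness).

    Ages are normal(age_mean, age_sd) truncated below at 18 by resampling;
    sex (0=female, 1=male) and handedness (0=right, 1=left) are Bernoulli.
    """
    if n < 2:
        raise DataError("a normative cohort needs at least 2 subjects")
    if not (0 <= p_female <= 1 and 0 <= p_right <= 1):
        raise DataError("proportions must lie in [0, 1]")
    if age_sd < 0:
        raise DataError("age_sd must be non-negative")
    rng = np.random.default_rng(seed)
    ages = np.full(n, np.nan)
    todo = np.ones(n, dtype=bool)
    while todo.any():
        draw = age_mean + age_sd * rng.standard_normal(int(todo.sum()))
        ages[todo] = draw
        todo = ages < AGE_FLOOR
        if age_sd == 0:
            if todo.any():
                raise DataError(f"age_mean {age_mean} below the {AGE_FLOOR} y floor with age_sd=0")
            break
    sex = (rng.random(n) >= p_female).astype(int)  # 1 = male
    hand = (rng.random(n) >= p_right).astype(int)  # 1 = left
    return pd.DataFrame(
        {
            "id": [f"ctrl{i:04d}" for i in range(n)],
            "age": ages,
            "sex": sex,
            "handedness": hand,
        }
    )


# ------------------------------------------------------------ smooth fields
def _diffusion_operator(mesh: TriangleMesh, lam: float) -> sp.csr_matrix:
    """One smoothing step: blend each vertex with the mean of its neighbours."""
    adj = mesh.adjacency_matrix().astype(np.float64)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    D_inv = sp.diags(1.0 / deg)
    return (sp.eye(mesh.n_vertices) * (1.0 - lam) + lam * D_inv @ adj).tocsr()


class SmoothFieldSampler:
    """Draws unit-variance Gaussian fields of a target FWHM on a mesh.

    White noise is diffused with a fixed neighbour-blend operator; the number
    of iterations is calibrated once (deterministically, from a probe batch)
    so that the estimated FWHM of the output reaches the target. Sampling is
    then a pure function of the supplied generator.
    """

    _PROBE_SEED = 1234567
    _PROBE_BATCH = 32

    def __init__(self, mesh: TriangleMesh, target_fwhm: float, lam: float = 0.5):
        if mesh.n_components() != 1:
            raise IntegrityError("smoothing requires a connected mesh")
        self.mesh = mesh
        self.target_fwhm = float(target_fwhm)
        edge = mesh.mean_edge_length()
        if not target_fwhm >= edge:
            raise DataError(
                f"target FWHM {target_fwhm:g} mm is below the mean edge length {edge:g} mm"
            )
        self.op = _diffusion_operator(mesh, lam)
        self.iterations = self._calibrate()

    def _calibrate(self) -> int:
        rng = np.random.default_rng(self._PROBE_SEED)
        F = rng.standard_normal((self.mesh.n_vertices, self._PROBE_BATCH))
        it = 0
        while estimate_field_fwhm(self.mesh, F.T) < self.target_fwhm:
            F = self.op @ F
            it += 1
            if it > 10000:
                raise DataError("smoothing calibration failed to converge")
        return it

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """(n, V) array of independent smooth fields, unit variance each."""
        F = rng.standard_normal((self.mesh.n_vertices, n))
        for _ in range(self.iterations):
            F = self.op @ F
        F = F.T
        return F / F.std(axis=1, keepdims=True)


def _sampler(mesh: TriangleMesh, target_fwhm: float) -> SmoothFieldSampler:
    key = ("smooth_sampler", round(float(target_fwhm), 12))
    if key not in mesh._cache:
        mesh._cache[key] = SmoothFieldSampler(mesh, target_fwhm)
    return mesh._cache[key]


def smooth_field(
    mesh: TriangleMesh,
    noise_map: VertexMap,
    target_fwhm: float,
    seed: int | None = None,
) -> VertexMap:
    """Diffuse a per-vertex field until its estimated FWHM reaches a target.

    The input is smoothed by iterated neighbour-weighted diffusion until the
    edge-gradient FWHM estimate reaches ``target_fwhm`` (within 10%; a
    warning reports a larger overshoot), then rescaled to unit variance
    across vertices. Targets below the mean edge length return the input
    unchanged with a warning. A constant (zero-variance) input cannot be
    rescaled; it is returned as-is with a warning.

    ``seed`` is accepted for signature symmetry with the other generators;
    this operation is deterministic in its input.
    """
    if mesh.n_components() != 1:
        raise IntegrityError("smoothing requires a connected mesh")
    values = np.asarray(noise_map.values, dtype=np.float64).copy()
    edge = mesh.mean_edge_length()
    if target_fwhm < edge:
        warnings.warn(
            f"target FWHM {target_fwhm:g} mm below mean edge length {edge:g} mm; "
            "returning the field unsmoothed",
            stacklevel=2,
        )
        return VertexMap(values, kind=noise_map.kind)
    if values.std() == 0:
        warnings.warn("field has degenerate (zero) variance; cannot smooth or rescale",
                      stacklevel=2)
        return VertexMap(values, kind=noise_map.kind)
    op = _diffusion_operator(mesh, 0.5)
    op_fine = _diffusion_operator(mesh, 0.15)
    achieved = estimate_field_fwhm(mesh, values)
    for _ in range(10000):
        if achieved >= target_fwhm:
            break
        new = op @ values
        new_fwhm = estimate_field_fwhm(mesh, new)
        if op is not op_fine and new_fwhm > 1.1 * target_fwhm:
            op = op_fine  # refine with smaller steps near the target
            continue
        values, achieved = new, new_fwhm
    if abs(achieved - target_fwhm) > 0.1 * target_fwhm:
        warnings.warn(
            f"achieved FWHM {achieved:g} mm misses target {target_fwhm:g} mm by >10%",
            stacklevel=2,
        )
    return VertexMap(values / values.std(), kind=noise_map.kind)


# -------------------------------------------------------------- truth model
@dataclass
class SimulationTruth:
    """Ground-truth generative parameters for a synthetic cohort.

    ``coef`` rows follow the design columns (intercept mm, age slope mm/yr,
    sex effect mm, age x sex mm/yr, handedness mm) at the stated centring
    age. Noise is a stationary Gaussian field of ``noise_fwhm`` mm scaled by
    the per-vertex ``noise_sd`` (mm).
    """

    coef: np.ndarray  # (5, V)
    noise_sd: np.ndarray  # (V,)
    noise_fwhm: float  # mm
    center_age: float
    seed: int = 0
    region: np.ndarray | None = None
    delta: float = 0.0
    coding: dict = field(default_factory=lambda: DEFAULT_CODING)

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=np.float64)
        self.noise_sd = np.asarray(self.noise_sd, dtype=np.float64).ravel()
        if self.coef.shape != (5, len(self.noise_sd)):
            raise IntegrityError(
                f"coef shape {self.coef.shape} inconsistent with noise_sd ({len(self.noise_sd)})"
            )
        if (self.noise_sd < 0).any():
            raise IntegrityError("noise SD must be non-negative")
        if not self.noise_fwhm > 0:
            raise IntegrityError("noise FWHM must be positive")


def default_truth(
    mesh: TriangleMesh,
    center_age: float = 43.0,
    intercept: float = 2.5,
    age_slope: float = -0.01,
    sex_effect: float = 0.05,
    age_sex: float = -0.002,
    hand_effect: float = 0.02,
    sigma: float = DEFAULT_SIGMA,
    fwhm_factor: float = 3.0,
    seed: int = 0,
) -> SimulationTruth:
    """Spatially constant truth coefficients at morphometry-plausible scales.

    The intercept is the expected thickness (mm) of a female right-hander at
    the centring age; cortical thinning with age is ~0.01 mm/yr.
    """
    V = mesh.n_vertices
    coef = np.zeros((5, V))
    coef[0] = intercept
    coef[1] = age_slope
    coef[2] = sex_effect
    coef[3] = age_sex
    coef[4] = hand_effect
    return SimulationTruth(
        coef=coef,
        noise_sd=np.full(V, sigma),
        noise_fwhm=fwhm_factor * mesh.mean_edge_length(),
        center_age=center_age,
        seed=seed,
    )


def _noise_fields(mesh: TriangleMesh, truth: SimulationTruth, n: int, rng) -> np.ndarray:
    edge = mesh.mean_edge_length()
    if truth.noise_fwhm < edge:
        F = rng.standard_normal((n, mesh.n_vertices))
        return F / F.std(axis=1, keepdims=True)
    return _sampler(mesh, truth.noise_fwhm).sample(n, rng)


def generate_thickness(
    mesh: TriangleMesh,
    cohort: pd.DataFrame,
    truth: SimulationTruth,
) -> np.ndarray:
    """Per-subject thickness maps: linear covariate effects + smooth noise.

    Returns an (n, V) stack, rows ordered as the cohort table. Thickness is
    clipped at 0.1 mm; any clipping is reported with a warning. Reproducible
    from ``truth.seed``.
    """
    if truth.coef.shape[1] != mesh.n_vertices:
        raise DataError("truth maps are not defined on this mesh")
    for col in ("age", "sex", "handedness"):
        if col not in cohort.columns:
            raise DataError(f"cohort table lacks column {col!r}")
        if col != "age" and not np.isin(cohort[col].to_numpy(), (0, 1)).all():
            raise DataError(f"cohort column {col!r} must be coded 0/1 to match the truth")
    X = np.stack(
        [
            design_row(a, s, h, truth.center_age)
            for a, s, h in zip(cohort["age"], cohort["sex"], cohort["handedness"])
        ]
    )
    rng = np.random.default_rng([truth.seed, 1])
    noise = _noise_fields(mesh, truth, len(cohort), rng)
    Y = X @ truth.coef + truth.noise_sd * noise
    n_clip = int((Y < MIN_THICKNESS).sum())
    if n_clip:
        warnings.warn(f"clipped {n_clip} thickness values at {MIN_THICKNESS} mm", stacklevel=2)
        Y = np.maximum(Y, MIN_THICKNESS)
    return Y


def make_case(
    mesh: TriangleMesh,
    truth: SimulationTruth,
    case_covariates: dict,
    region: np.ndarray | None = None,
    delta: float = 0.0,
    seed: int | None = None,
) -> VertexMap:
    """A case thickness map: a matched control draw plus a focal deviation.

    ``delta`` mm is added on ``region`` vertices, tapered to half over the
    1-ring collar just outside the region. ``region=None`` with ``delta=0``
    yields a null pseudo-case. The region must be a connected subset of the
    mesh vertices.
    """
    rng = np.random.default_rng([truth.seed if seed is None else seed, 2])
    x0 = design_row(
        case_covariates["age"],
        case_covariates["sex"],
        case_covariates["handedness"],
        truth.center_age,
    )
    y = x0 @ truth.coef + truth.noise_sd * _noise_fields(mesh, truth, 1, rng)[0]
    if region is not None:
        region = np.asarray(region, dtype=np.int64)
        if region.size == 0:
            raise DataError("region must be non-empty")
        if region.min() < 0 or region.max() >= mesh.n_vertices:
            raise DataError("region is not a subset of the mesh vertices")
        adj = mesh.adjacency_matrix()
        sub = adj[region][:, region]
        from scipy.sparse.csgraph import connected_components

        n_comp, _ = connected_components(sub, directed=False)
        if n_comp != 1:
            raise DataError(f"region is not connected ({n_comp} components)")
        in_region = np.zeros(mesh.n_vertices, dtype=bool)
        in_region[region] = True
        collar = np.unique(adj[region].indices)
        collar = collar[~in_region[collar]]
        y[region] += delta
        y[collar] += 0.5 * delta
    return VertexMap(np.maximum(y, MIN_THICKNESS), kind="thickness")


def grow_patch(mesh: TriangleMesh, seed_vertex: int, size: int) -> np.ndarray:
    """Deterministic connected patch of ``size`` vertices grown by BFS rings."""
    if not 0 < size <= mesh.n_vertices:
        raise DataError("patch size must be in [1, n_vertices]")
    adj = mesh.adjacency_matrix()
    selected = [int(seed_vertex)]
    in_set = np.zeros(mesh.n_vertices, dtype=bool)
    in_set[seed_vertex] = True
    frontier = [int(seed_vertex)]
    while len(selected) < size and frontier:
        nxt = np.unique(adj[frontier].indices)
        nxt = [int(v) for v in nxt if not in_set[v]]
        for v in sorted(nxt):
            if len(selected) >= size:
                break
            selected.append(v)
            in_set[v] = True
        frontier = nxt
    return np.array(sorted(selected[:size]), dtype=np.int64)


# ---------------------------------------------------------------- volumes
def _lesion_mask_array(shape, lesion_spec) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    for prim in lesion_spec:
        kind = prim[0]
        if kind == "sphere":
            _, center, radius = prim
            c = np.asarray(center, dtype=float)
            lo, hi = c - radius, c + radius
            if (lo < -0.5).any() or (hi > np.asarray(shape) - 0.5).any():
                raise DataError(f"sphere {prim} extends outside the grid {shape}")
            d2 = (ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2
            mask |= d2 <= radius**2
        elif kind == "box":
            _, lo, hi = prim
            lo, hi = np.asarray(lo, int), np.asarray(hi, int)
            if (lo < 0).any() or (hi > np.asarray(shape)).any() or (hi <= lo).any():
                raise DataError(f"box {prim} invalid for grid {shape}")
            mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
        else:
            raise DataError(f"unknown lesion primitive {kind!r}")
    return mask


def generate_lesioned_volume(
    shape=(32, 32, 32),
    lesion_spec=(),
    seed: int = 0,
) -> tuple[VolumeImage, VolumeImage, MaskVolume]:
    """Toy lesioned T1: (subject, co-registered template, lesion mask).

    The template is a smooth ellipsoidal head phantom (background 0); the
    subject equals the template with lesioned voxels set to the background
    intensity; the mask is 1 exactly on lesioned voxels. The template doubles
    as the pre-lesion ground truth for compositing tests.
    """
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise DataError(f"grid shape must be positive, got {shape}")
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(*(np.linspace(-1, 1, s) for s in shape), indexing="ij")
    r2 = sum((g / 0.8) ** 2 for g in grids)
    head = r2 <= 1.0
    intensity = np.zeros(shape)
    intensity[head] = 80.0 + 40.0 * (1.0 - r2[head])
    intensity += ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0) * 5.0 * head
    affine = np.eye(4)
    template = VolumeImage(intensity, affine)
    mask = _lesion_mask_array(shape, lesion_spec)
    subject_data = intensity.copy()
    subject_data[mask] = 0.0  # background intensity
    subject = VolumeImage(subject_data, affine)
    return subject, template, MaskVolume(mask.astype(np.float64), affine, tag="lesion")


# ------------------------------------------------------------------- I/O
def save_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"id", "age", "sex", "handedness"} - set(df.columns)
    if missing:
        raise DataError(f"cohort CSV lacks columns {sorted(missing)}")
    if df["id"].duplicated().any():
        raise DataError("cohort ids are not unique")
    if (df["age"] <= 0).any():
        raise DataError("ages must be strictly positive")
    return df
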