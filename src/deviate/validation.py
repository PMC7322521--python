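"""Simulation-based validation experiments: null calibration, power, recovery.

These scenarios exercise the whole pipeline against the synthetic generator's
known ground truth. They are used three ways: by the test suite, by the
``deviate simulate`` CLI, and by the acceptance script. All of them are
deterministic given a seed.

Default problem sizes are the study conditions the generator emulates: a
2562-vertex icosphere standing in for the common surface template, 188
controls with the emulated covariate structure, residual noise SD 0.2 mm at
FWHM three mean edge lengths, and a 150-vertex focal effect of +0.72 mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .errors import DataError
from .glm import (
    NormativeModel,
    build_design,
    fit_normative,
    predict_case,
    region_summary,
    studentized_residual,
)
from .lesion import composite_brain, subtract_mask
from .mesh import TriangleMesh, VertexMap, vertex_areas
from .rft import (
    cluster_corrected_p,
    cluster_forming_threshold,
    estimate_fwhm,
    find_clusters,
    peak_corrected_p,
)
from .synthetic import (
    DEFAULT_DELTA,
    DEFAULT_SIGMA,
    default_truth,
    generate_cohort,
    generate_lesioned_volume,
    generate_thickness,
    grow_patch,
    icosphere,
    make_case,
)
from .volume import MaskVolume

# the case the simulations are centred on: a 43-year-old right-handed female
CASE_COV = {"age": 43.0, "sex": 0, "handedness": 0}
CASE_INTERCEPT = 2.33  # mm: normative prediction at the case covariates
PATCH_SIZE = 150

_MESH_CACHE: dict = {}


def study_mesh(subdivisions: int = 4, radius: float = 70.0) -> TriangleMesh:
    key = (subdivisions, radius)
    if key not in _MESH_CACHE:
        _MESH_CACHE[key] = icosphere(subdivisions, radius)
    return _MESH_CACHE[key]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31 - 1, size=n)


def _study_truth(mesh, seed, sigma=DEFAULT_SIGMA, fwhm_factor=3.0):
    return default_truth(
        mesh,
        center_age=CASE_COV["age"],
        intercept=CASE_INTERCEPT,
        sigma=sigma,
        fwhm_factor=fwhm_factor,
        seed=int(seed),
    )


def _fit_cohort(mesh, seed, n_controls, sigma=DEFAULT_SIGMA, fwhm_factor=3.0):
    """Generate a cohort + thickness stack and fit the normative model."""
    cohort = generate_cohort(n=n_controls, seed=int(seed))
    truth = _study_truth(mesh, seed, sigma, fwhm_factor)
    stack = generate_thickness(mesh, cohort, truth)
    design = build_design(cohort, CASE_COV["age"])
    model, resid = fit_normative(stack, design, return_residuals=True)
    return cohort, truth, stack, model, resid


# ------------------------------------------------------------------ oracles
def _ols_oracle(X: np.ndarray, Y: np.ndarray, rank: int):
    """Brute-force normal-equations OLS, solved vertex by vertex."""
    XtX = X.T @ X
    coef = np.empty((X.shape[1], Y.shape[1]))
    for v in range(Y.shape[1]):
        coef[:, v] = np.linalg.solve(XtX, X.T @ Y[:, v])
    resid = Y - X @ coef
    sd = np.sqrt((resid**2).sum(axis=0) / (X.shape[0] - rank))
    return coef, sd


def ols_equivalence(seed: int = 0, n_instances: int = 50) -> dict:
    """Max relative disagreement between the fit and a normal-equations oracle.

    Random cohorts (8 <= n <= 200) and random thickness stacks (<= 100
    vertices); relative error is measured instance-wise in the sup norm.
    """
    rng = np.random.default_rng(seed)
    worst_coef = worst_sd = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(8, 201))
        V = int(rng.integers(1, 101))
        # the normal-equations oracle needs a full-rank design; redraw the
        # rare small cohort that lacks covariate variation
        while True:
            cohort = generate_cohort(n=n, seed=int(rng.integers(2**31 - 1)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                design = build_design(cohort, CASE_COV["age"])
            if design.rank == 5:
                break
        Y = 2.5 + 0.3 * rng.standard_normal((n, V))
        model = fit_normative(Y, design)
        coef_o, sd_o = _ols_oracle(design.X, Y, design.rank)
        worst_coef = max(
            worst_coef, float(np.abs(model.coef - coef_o).max() / np.abs(coef_o).max())
        )
        worst_sd = max(worst_sd, float(np.abs(model.resid_sd - sd_o).max() / sd_o.max()))
    return {"max_rel_err_coef": worst_coef, "max_rel_err_sd": worst_sd, "n": n_instances}


def studentized_exactness() -> dict:
    """Check the deviation formula verbatim on a constructed fixture.

    Includes the zero-SD branch: the vertex with controlStddevs = 0 must be
    flagged missing (NaN), never infinite.
    """
    V = 3
    coef = np.zeros((5, V))
    model = NormativeModel(
        coef=coef,
        resid_sd=np.array([0.25, 0.5, 0.0]),
        dof=10.0,
        rank=5,
        center_age=43.0,
        gram_inv=np.eye(5) / 10,
    )
    actual = VertexMap(np.array([3.0, 2.0, 2.5]), kind="thickness")
    predicted = VertexMap(np.array([2.5, 3.0, 2.5]), kind="thickness")
    dev = studentized_residual(actual, predicted, model)
    expected = np.array([2.0, -2.0, np.nan])
    finite_err = float(np.abs(dev.values[:2] - expected[:2]).max())
    branch_ok = bool(np.isnan(dev.values[2]) and dev.excluded[2] and not dev.excluded[:2].any())
    return {"max_abs_err": finite_err if branch_ok else np.inf, "zero_sd_flagged": branch_ok,
            "n": V}


# --------------------------------------------------------------- recovery
def coefficient_recovery(
    seed: int = 0,
    n_reps: int = 200,
    n_controls: int = 188,
    subdivisions: int = 4,
    sigma: float = DEFAULT_SIGMA,
) -> dict:
    """Bias of each fitted coefficient against the generator's truth.

    For each replicate the vertex-averaged coefficient error is recorded;
    the scenario reports, per coefficient, the bias z-score
    mean / (SD / sqrt(reps)) over replicates.
    """
    mesh = study_mesh(subdivisions)
    seeds = _child_seeds(seed, n_reps)
    errs = np.empty((n_reps, 5))
    for r, s in enumerate(seeds):
        cohort = generate_cohort(n=n_controls, seed=int(s))
        truth = _study_truth(mesh, s, sigma)
        stack = generate_thickness(mesh, cohort, truth)
        design = build_design(cohort, CASE_COV["age"])
        model = fit_normative(stack, design)
        errs[r] = (model.coef - truth.coef).mean(axis=1)
    bias = errs.mean(axis=0)
    se = errs.std(axis=0, ddof=1) / np.sqrt(n_reps)
    z = bias / se
    return {
        "bias": bias,
        "se": se,
        "z": z,
        "max_abs_z": float(np.abs(z).max()),
        "n": n_reps,
    }


def fwhm_recovery(
    seed: int = 0,
    multiples=(2.0, 3.0, 4.0, 6.0),
    n_controls: int = 50,
    subdivisions: int = 4,
) -> dict:
    """Relative error of the residual-based FWHM estimate vs generator target."""
    mesh = study_mesh(subdivisions)
    edge = mesh.mean_edge_length()
    seeds = _child_seeds(seed, len(multiples))
    rel_errs = {}
    for mult, s in zip(multiples, seeds):
        _, truth, _, model, resid = _fit_cohort(mesh, s, n_controls, fwhm_factor=mult)
        est = estimate_fwhm(resid, model, mesh)
        rel_errs[mult] = float(abs(est.fwhm - truth.noise_fwhm) / truth.noise_fwhm)
    return {
        "rel_err": rel_errs,
        "max_rel_err": float(max(rel_errs.values())),
        "mean_edge_mm": edge,
        "n": len(multiples),
    }


# -------------------------------------------------------------------- null
def null_deviation_variance(
    seed: int = 0,
    n_reps: int = 100,
    n_controls: int = 50,
    subdivisions: int = 2,
) -> dict:
    """Pooled variance of null pseudo-case studentized residuals.

    Slight inflation above 1 is expected: the plain ratio omits the
    prediction-variance factor sqrt(1 + x0'(X'X)^-1 x0) and the t scaling.
    """
    mesh = study_mesh(subdivisions)
    seeds = _child_seeds(seed, n_reps)
    ss = n_tot = 0.0
    for s in seeds:
        _, truth, _, model, _ = _fit_cohort(mesh, s, n_controls)
        case_map = make_case(mesh, truth, CASE_COV, seed=int(s) + 1)
        pred = predict_case(model, CASE_COV)
        dev = studentized_residual(case_map, pred, model)
        vals = dev.values[~dev.excluded]
        ss += float((vals**2).sum())
        n_tot += vals.size
    return {"pooled_variance": ss / n_tot, "n": int(n_reps)}


def null_fwer(
    seed: int = 0,
    n_sims: int = 1000,
    n_cohorts: int = 20,
    n_controls: int = 188,
    subdivisions: int = 4,
    alpha: float = 0.05,
    cluster_forming_p: float = 0.001,
    sign: str = "two_sided",
) -> dict:
    """Family-wise error of cluster- and peak-wise RFT inference under the null.

    ``n_sims`` null pseudo-cases are spread over ``n_cohorts`` independently
    generated control cohorts (sharing a fitted model within a cohort); a
    family-wise error is any cluster (or any vertex) reaching corrected
    p <= alpha.
    """
    mesh = study_mesh(subdivisions)
    per = int(np.ceil(n_sims / n_cohorts))
    cohort_seeds = _child_seeds(seed, n_cohorts)
    hits_cluster = hits_peak = 0
    done = 0
    for cs in cohort_seeds:
        if done >= n_sims:
            break
        _, truth, _, model, resid = _fit_cohort(mesh, cs, n_controls)
        smooth = estimate_fwhm(resid, model, mesh)
        z = cluster_forming_threshold(cluster_forming_p, model.dof)
        pred = predict_case(model, CASE_COV)
        case_seeds = _child_seeds(int(cs) + 1, per)
        for ks in case_seeds:
            if done >= n_sims:
                break
            case_map = make_case(mesh, truth, CASE_COV, seed=int(ks))
            dev = studentized_residual(case_map, pred, model)
            clusters = find_clusters(dev, z, mesh, sign=sign)
            clusters = cluster_corrected_p(clusters, z, smooth, model.dof)
            if clusters.significant(alpha):
                hits_cluster += 1
            pk = peak_corrected_p(dev, smooth, model.dof, sign=sign)
            if (pk.values <= alpha).any():
                hits_peak += 1
            done += 1
    lo_c, hi_c = _binom_ci(hits_cluster, done)
    lo_p, hi_p = _binom_ci(hits_peak, done)
    return {
        "fwer_cluster": hits_cluster / done,
        "fwer_peak": hits_peak / done,
        "ci_cluster": (lo_c, hi_c),
        "ci_peak": (lo_p, hi_p),
        "n": done,
    }


def _binom_ci(k: int, n: int, level: float = 0.95):
    """Clopper-Pearson interval."""
    a = (1 - level) / 2
    lo = 0.0 if k == 0 else float(beta_dist.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - a, k + 1, n - k))
    return lo, hi


# ------------------------------------------------------------------- power
def effect_detection(
    seed: int = 0,
    n_runs: int = 50,
    delta: float = DEFAULT_DELTA,
    sigma: float = DEFAULT_SIGMA,
    n_controls: int = 188,
    subdivisions: int = 4,
    patch_size: int = PATCH_SIZE,
    alpha: float = 0.05,
    cluster_forming_p: float = 0.001,
) -> dict:
    """Power to detect a focal reference-scale thickening, and effect recovery.

    Each run injects ``delta`` mm over a connected ``patch_size``-vertex
    region into a case map, runs the full inference, and records whether any
    significant cluster overlaps the patch. For detected runs the region
    summary of the best-overlapping cluster gives the recovered effect
    (mean actual - mean predicted, mm); note this is a mean over
    *suprathreshold* vertices, so selection inflates it slightly above the
    injected delta (winner's curse) — the scenario reports it as measured.
    """
    mesh = study_mesh(subdivisions)
    areas = vertex_areas(mesh)
    patch = grow_patch(mesh, seed_vertex=0, size=patch_size)
    in_patch = np.zeros(mesh.n_vertices, dtype=bool)
    in_patch[patch] = True
    seeds = _child_seeds(seed, n_runs)
    detected = 0
    recovered = []
    dices = []
    for s in seeds:
        _, truth, _, model, resid = _fit_cohort(mesh, s, n_controls, sigma=sigma)
        smooth = estimate_fwhm(resid, model, mesh)
        z = cluster_forming_threshold(cluster_forming_p, model.dof)
        case_map = make_case(mesh, truth, CASE_COV, region=patch, delta=delta, seed=int(s) + 7)
        pred = predict_case(model, CASE_COV)
        dev = studentized_residual(case_map, pred, model)
        clusters = find_clusters(dev, z, mesh, sign="two_sided")
        clusters = cluster_corrected_p(clusters, z, smooth, model.dof)
        overlapping = [
            c for c in clusters.significant(alpha) if in_patch[c.vertices].any()
        ]
        if not overlapping:
            continue
        detected += 1
        best = max(overlapping, key=lambda c: in_patch[c.vertices].sum())
        mean_actual, mean_pred = region_summary(case_map, pred, best.vertices, areas)
        recovered.append(mean_actual - mean_pred)
        inter = in_patch[best.vertices].sum()
        dices.append(2.0 * inter / (len(best.vertices) + patch_size))
    recovered = np.asarray(recovered)
    return {
        "power": detected / n_runs,
        "delta_mean": float(recovered.mean()) if recovered.size else np.nan,
        "delta_se": float(recovered.std(ddof=1) / np.sqrt(recovered.size))
        if recovered.size > 1
        else np.nan,
        "dice_median": float(np.median(dices)) if dices else np.nan,
        "n": n_runs,
    }


# ------------------------------------------------------------------ lesion
def lesion_fill_exactness(seed: int = 0, shape=(24, 24, 24)) -> dict:
    """Bit-exactness checks of the compositing algebra on a generated phantom."""
    c = tuple(s // 2 for s in shape)
    subject, template, mask = generate_lesioned_volume(
        shape, lesion_spec=[("sphere", c, 5.0)], seed=seed
    )
    empty = MaskVolume(np.zeros(shape), mask.affine, tag="lesion")
    full = MaskVolume(np.ones(shape), mask.affine, tag="lesion")
    checks = {}
    checks["identity_empty_mask"] = np.array_equal(
        composite_brain(subject, template, empty).data, subject.data
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        checks["total_replacement_full_mask"] = np.array_equal(
            composite_brain(subject, template, full).data, template.data
        )
    once = composite_brain(subject, template, mask)
    twice = composite_brain(once, template, mask)
    checks["idempotence"] = np.array_equal(once.data, twice.data)
    m = mask.as_bool
    checks["locality_outside_mask"] = np.array_equal(once.data[~m], subject.data[~m])
    checks["restores_truth_inside_mask"] = np.array_equal(once.data[m], template.data[m])
    brain = MaskVolume((template.data > 0).astype(float), mask.affine, tag="brain")
    sub = subtract_mask(brain, mask)
    checks["subtract_counts"] = (
        sub.data.sum() == brain.data.sum() - (brain.as_bool & m).sum()
    )
    return {
        "all_exact": float(all(checks.values())),
        "checks": checks,
        "n": int(np.prod(shape)),
    }


# ------------------------------------------------------------ orchestration
@dataclass
class ValidationSettings:
    """Replicate counts and seed for the validation suite."""

    seed: int = 0
    scenarios: tuple = ("ols", "null", "power", "recovery", "fwhm", "lesion")
    n_null: int = 1000
    n_power: int = 50
    n_recovery: int = 200
    subdivisions: int = 4


def run_validation_suite(settings: ValidationSettings) -> pd.DataFrame:
    """Run the requested scenarios; one row per (scenario, metric)."""
    for n in (settings.n_null, settings.n_power, settings.n_recovery):
        if n < 50:
            warnings.warn(f"replicate count {n} < 50: Monte-Carlo intervals will be wide",
                          stacklevel=2)
    rows = []

    def add(scenario, metric, value, ci=(np.nan, np.nan), n=np.nan):
        rows.append(
            {"scenario": scenario, "metric": metric, "value": value,
             "ci_low": ci[0], "ci_high": ci[1], "n": n}
        )

    if "ols" in settings.scenarios:
        r = ols_equivalence(settings.seed)
        add("ols", "max_rel_err_coef", r["max_rel_err_coef"], n=r["n"])
        add("ols", "max_rel_err_sd", r["max_rel_err_sd"], n=r["n"])
    if "null" in settings.scenarios:
        r = null_fwer(settings.seed, n_sims=settings.n_null, subdivisions=settings.subdivisions)
        add("null", "fwer_cluster", r["fwer_cluster"], r["ci_cluster"], r["n"])
        add("null", "fwer_peak", r["fwer_peak"], r["ci_peak"], r["n"])
    if "power" in settings.scenarios:
        r = effect_detection(settings.seed, n_runs=settings.n_power,
                             subdivisions=settings.subdivisions)
        add("power", "power", r["power"], _binom_ci(round(r["power"] * r["n"]), r["n"]), r["n"])
        add("power", "delta_mean_mm", r["delta_mean"],
            (r["delta_mean"] - 2 * r["delta_se"], r["delta_mean"] + 2 * r["delta_se"]), r["n"])
    if "recovery" in settings.scenarios:
        r = coefficient_recovery(settings.seed, n_reps=settings.n_recovery,
                                 subdivisions=settings.subdivisions)
        add("recovery", "max_abs_bias_z", r["max_abs_z"], n=r["n"])
    if "fwhm" in settings.scenarios:
        r = fwhm_recovery(settings.seed, subdivisions=settings.subdivisions)
        add("fwhm", "max_rel_err", r["max_rel_err"], n=r["n"])
    if "lesion" in settings.scenarios:
        r = lesion_fill_exactness(settings.seed)
        add("lesion", "all_exact", r["all_exact"], n=r["n"])
    return pd.DataFrame(rows)
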