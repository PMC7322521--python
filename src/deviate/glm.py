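"""Vertex-wise normative general linear model and single-case deviation maps.

The normative model regresses per-vertex cortical thickness on demographic
covariates over a healthy control cohort:

    thickness ~ 1 + age_c + sex + age_c * sex + handedness

where ``age_c`` is age centred on the age of the case under study (so the
intercept is the expected thickness of a reference subject of exactly the
case's age). The fitted model predicts the case's expected thickness per
vertex, and the case's deviation is the studentized residual

    (actual - predicted) / control residual SD.

Covariate coding is female=0/male=1 and right=0/left=1; the coding is stored
with the model so predictions can never silently mix conventions.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, IntegrityError
from .mesh import TriangleMesh, VertexMap, load_map, save_map

DESIGN_COLUMNS = ("intercept", "age_c", "sex", "age_c_x_sex", "handedness")
DEFAULT_CODING = {"sex": {"female": 0, "male": 1}, "handedness": {"right": 0, "left": 1}}


@dataclass
class DesignMatrix:
    """Control design matrix with its centring age and covariate coding."""

    X: np.ndarray  # (n, 5)
    center_age: float
    coding: dict = field(default_factory=lambda: DEFAULT_CODING)
    columns: tuple = DESIGN_COLUMNS

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[1] != 5:
            raise IntegrityError(f"design matrix must be (n, 5), got {self.X.shape}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X))


@dataclass
class NormativeModel:
    """Per-vertex OLS coefficients and residual SDs fitted on controls.

    Attributes
    ----------
    coef : (5, V) array
        mm per covariate unit, rows ordered as ``DESIGN_COLUMNS``.
    resid_sd : (V,) array
        Control residual standard deviation (mm), divisor ``n - rank``.
    dof : float
        Residual degrees of freedom ``n - rank``.
    gram_inv : (5, 5) array
        Pseudo-inverse of X'X, kept for optional prediction-variance
        inflation of out-of-sample deviations.
    """

    coef: np.ndarray
    resid_sd: np.ndarray
    dof: float
    rank: int
    center_age: float
    coding: dict = field(default_factory=lambda: DEFAULT_CODING)
    gram_inv: np.ndarray | None = None

    @property
    def n_vertices(self) -> int:
        return self.coef.shape[1]


@dataclass
class DeviationMap:
    """Per-vertex studentized residuals for one case.

    Vertices where the control residual SD is zero carry NaN and are flagged
    in ``excluded``; they never produce infinities.
    """

    values: np.ndarray
    excluded: np.ndarray
    case: dict | None = None

    @property
    def n_excluded(self) -> int:
        return int(self.excluded.sum())


# ----------------------------------------------------------------- design
def design_row(age: float, sex: int, handedness: int, center_age: float) -> np.ndarray:
    """One design row [1, age_c, sex, age_c*sex, handedness]."""
    a = float(age) - float(center_age)
    return np.array([1.0, a, float(sex), a * float(sex), float(handedness)])


def build_design(cohort: pd.DataFrame, center_age: float) -> DesignMatrix:
    """Build the control design matrix centred on the case age.

    ``cohort`` needs numeric columns ``age``, ``sex`` (0=female, 1=male) and
    ``handedness`` (0=right, 1=left). A rank-deficient design (e.g. a
    single-sex cohort) triggers a warning; fitting then proceeds through the
    pseudo-inverse.
    """
    for col in ("age", "sex", "handedness"):
        if col not in cohort.columns:
            raise DataError(f"cohort table lacks required column {col!r}")
    rows = np.stack(
        [
            design_row(a, s, h, center_age)
            for a, s, h in zip(cohort["age"], cohort["sex"], cohort["handedness"])
        ]
    )
    design = DesignMatrix(rows, float(center_age))
    if design.rank < 5:
        warnings.warn(
            f"design matrix is rank deficient (rank {design.rank} < 5); "
            "fit will use minimum-norm least squares",
            stacklevel=2,
        )
    return design


# -------------------------------------------------------------------- fit
def fit_normative(
    thickness_stack: np.ndarray,
    design: DesignMatrix,
    return_residuals: bool = False,
):
    """Ordinary least squares at every vertex.

    Parameters
    ----------
    thickness_stack : (n, V) array
        One row per control subject.
    design : DesignMatrix
        Must have the same number of rows.
    return_residuals : bool
        Also return the (n, V) residual matrix (needed for smoothness
        estimation downstream).

    Notes
    -----
    The residual SD uses the unbiased divisor ``n - rank(X)``. Coefficients
    are the minimum-norm least-squares solution, so rank-deficient designs
    still fit (with the warning already issued by :func:`build_design`).
    """
    Y = np.asarray(thickness_stack, dtype=np.float64)
    if Y.ndim != 2:
        raise DataError(f"thickness stack must be 2-D (subjects x vertices), got {Y.shape}")
    if Y.shape[0] != design.n:
        raise DataError(f"stack has {Y.shape[0]} rows but design has {design.n}")
    if design.n <= 5:
        raise DataError("need more than 5 control subjects to fit the 5-column model")
    bad = ~np.isfinite(Y)
    if bad.any():
        i, v = np.argwhere(bad)[0]
        raise DataError(f"non-finite thickness for subject {i} at vertex {v}")

    rank = design.rank
    pinv = np.linalg.pinv(design.X)
    coef = pinv @ Y  # (5, V)
    resid = Y - design.X @ coef
    dof = design.n - rank
    resid_sd = np.sqrt((resid**2).sum(axis=0) / dof)
    model = NormativeModel(
        coef=coef,
        resid_sd=resid_sd,
        dof=float(dof),
        rank=rank,
        center_age=design.center_age,
        coding=design.coding,
        gram_inv=np.linalg.pinv(design.X.T @ design.X),
    )
    if return_residuals:
        return model, resid
    return model


def _case_row(model: NormativeModel, case: Mapping) -> np.ndarray:
    for key in ("age", "sex", "handedness"):
        if key not in case:
            raise DataError(f"case covariates lack {key!r}")
    sex, hand = case["sex"], case["handedness"]
    if isinstance(sex, str):
        sex = model.coding["sex"][sex.lower()]
    if isinstance(hand, str):
        hand = model.coding["handedness"][hand.lower()]
    if sex not in (0, 1) or hand not in (0, 1):
        raise DataError("sex/handedness must be coded 0/1 (or named per the model's coding)")
    return design_row(case["age"], sex, hand, model.center_age)


def predict_case(model: NormativeModel, case: Mapping) -> VertexMap:
    """Predicted thickness map for the case's age, sex and handedness.

    Warns if the model was not centred on the case's age — the normative fit
    is meant to be rebuilt per case so the intercept refers to the case.
    """
    if abs(float(case["age"]) - model.center_age) > 1e-9:
        warnings.warn(
            f"model centring age {model.center_age} differs from case age "
            f"{case['age']}; prediction is still valid but the model was "
            "meant to be refitted per case",
            stacklevel=2,
        )
    x0 = _case_row(model, case)
    return VertexMap(x0 @ model.coef, kind="thickness")


def studentized_residual(
    actual: VertexMap,
    predicted: VertexMap,
    model: NormativeModel,
    case: Mapping | None = None,
    inflate: bool = False,
) -> DeviationMap:
    """Per-vertex (actual - predicted) / control residual SD.

    With ``inflate=True`` the denominator is multiplied by
    ``sqrt(1 + x0' (X'X)^-1 x0)`` (Crawford–Howell-style prediction-variance
    inflation for an out-of-sample case); the plain ratio is the default.
    Vertices with zero residual SD are excluded (NaN), never infinite.
    """
    a, p = np.asarray(actual.values), np.asarray(predicted.values)
    if len(a) != len(p) or len(a) != model.n_vertices:
        raise DataError(
            f"size mismatch: actual {len(a)}, predicted {len(p)}, model {model.n_vertices}"
        )
    sd = model.resid_sd.copy()
    if inflate:
        if case is None:
            raise DataError("inflate=True needs the case covariates")
        x0 = _case_row(model, case)
        sd = sd * np.sqrt(1.0 + x0 @ model.gram_inv @ x0)
    excluded = sd == 0
    values = np.full(len(a), np.nan)
    np.divide(a - p, sd, out=values, where=~excluded)
    return DeviationMap(values=values, excluded=excluded, case=dict(case) if case else None)


def region_summary(
    actual: VertexMap,
    predicted: VertexMap,
    region: np.ndarray,
    areas: VertexMap,
) -> tuple[float, float]:
    """Area-weighted mean actual and predicted thickness (mm) over a region."""
    region = np.asarray(region, dtype=np.int64)
    if region.size == 0:
        raise DataError("region is empty")
    w = np.asarray(areas.values)[region]
    wsum = w.sum()
    mean_actual = float((np.asarray(actual.values)[region] * w).sum() / wsum)
    mean_pred = float((np.asarray(predicted.values)[region] * w).sum() / wsum)
    return mean_actual, mean_pred


# ---------------------------------------------------------------- model I/O
def save_model(model: NormativeModel, directory) -> None:
    """Write coefficient/SD maps as scalar ASCII plus a JSON metadata sidecar."""
    os.makedirs(directory, exist_ok=True)
    for name, row in zip(DESIGN_COLUMNS, model.coef):
        save_map(VertexMap(row, kind="statistic"), os.path.join(directory, f"coef_{name}.txt"))
    save_map(VertexMap(model.resid_sd, kind="statistic"), os.path.join(directory, "resid_sd.txt"))
    meta = {
        "dof": model.dof,
        "rank": model.rank,
        "center_age": model.center_age,
        "coding": model.coding,
        "gram_inv": model.gram_inv.tolist() if model.gram_inv is not None else None,
        "columns": list(DESIGN_COLUMNS),
    }
    with open(os.path.join(directory, "model.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_model(directory) -> NormativeModel:
    with open(os.path.join(directory, "model.json")) as fh:
        meta = json.load(fh)
    coef = np.stack(
        [load_map(os.path.join(directory, f"coef_{name}.txt")).values for name in DESIGN_COLUMNS]
    )
    resid_sd = load_map(os.path.join(directory, "resid_sd.txt")).values
    return NormativeModel(
        coef=coef,
        resid_sd=resid_sd,
        dof=meta["dof"],
        rank=meta["rank"],
        center_age=meta["center_age"],
        coding=meta["coding"],
        gram_inv=np.array(meta["gram_inv"]) if meta["gram_inv"] is not None else None,
    )
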