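"""End-to-end single-case analysis: config in, deviation map + report out.

One run analyses one case against one control cohort, because the design
matrix is centred on the case's age and must be refitted per case. The run
is fully reproducible from the config (plus the seed recorded in the
report's provenance block), and no partial outputs are written: every stage
must succeed before anything lands in the output directory.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from .errors import DataError, PipelineError
from .glm import (
    build_design,
    fit_normative,
    predict_case,
    region_summary,
    studentized_residual,
)
from .mesh import VertexMap, load_map, load_mesh, save_map, vertex_areas
from .rft import (
    cluster_corrected_p,
    cluster_forming_threshold,
    estimate_fwhm,
    find_clusters,
    peak_corrected_p,
)
from .synthetic import load_cohort


@dataclass
class AnalysisConfig:
    """Inputs and settings for one single-case analysis."""

    mesh_path: str
    cohort_csv: str
    case_age: float
    case_sex: int  # 0=female, 1=male
    case_handedness: int  # 0=right, 1=left
    case_map_path: str
    output_dir: str
    cluster_forming_p: float = 0.001
    sign: str = "two_sided"
    alpha: float = 0.05
    seed: int = 0
    inflate_prediction_variance: bool = False

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise DataError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.cluster_forming_p < 1.0:
            raise DataError(f"cluster_forming_p must be in (0, 1), got {self.cluster_forming_p}")

    @property
    def case(self) -> dict:
        return {
            "age": self.case_age,
            "sex": self.case_sex,
            "handedness": self.case_handedness,
        }

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CaseReport:
    """What one run produced: file paths, regions, smoothness, provenance."""

    deviation_map: str
    cluster_table: str
    regions: list  # dicts: cluster id, sign, p, area, mean actual/predicted
    fwhm: float
    resels: tuple
    n_clusters: int
    n_excluded_vertices: int
    provenance: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def run_case_analysis(config: AnalysisConfig) -> CaseReport:
    """Execute the full normative-deviation analysis for one case.

    Stages: design build (centred on the case's age) -> vertex-wise OLS fit
    -> case prediction -> studentized residuals -> residual smoothness ->
    cluster detection at the configured threshold -> RFT cluster p-values ->
    region summaries for significant clusters. Outputs (deviation map,
    cluster TSV, report JSON) are written only after all stages succeed.
    """
    mesh = _stage("load_mesh", load_mesh, config.mesh_path)
    cohort = _stage("load_cohort", load_cohort, config.cohort_csv)

    def load_stack():
        base = os.path.dirname(os.path.abspath(config.cohort_csv))
        if "map_path" not in cohort.columns:
            raise DataError("cohort CSV needs a map_path column")
        maps = []
        for mp in cohort["map_path"]:
            p = mp if os.path.isabs(mp) else os.path.join(base, mp)
            vm = load_map(p)
            if len(vm.values) != mesh.n_vertices:
                raise DataError(f"{p}: map is not on the analysis mesh")
            maps.append(vm.values)
        return np.stack(maps)

    stack = _stage("load_control_maps", load_stack)
    actual = _stage("load_case_map", load_map, config.case_map_path)
    if len(actual.values) != mesh.n_vertices:
        raise PipelineError("stage 'load_case_map' failed: case map is not on the analysis mesh")

    design = _stage("build_design", build_design, cohort, config.case_age)
    model, resid = _stage("fit_normative", fit_normative, stack, design, return_residuals=True)
    predicted = _stage("predict_case", predict_case, model, config.case)
    deviation = _stage(
        "studentized_residual",
        studentized_residual,
        actual,
        predicted,
        model,
        case=config.case,
        inflate=config.inflate_prediction_variance,
    )
    smoothness = _stage("estimate_fwhm", estimate_fwhm, resid, model, mesh)
    z = cluster_forming_threshold(config.cluster_forming_p, model.dof)
    clusters = _stage("find_clusters", find_clusters, deviation, z, mesh, sign=config.sign)
    clusters = _stage("cluster_corrected_p", cluster_corrected_p, clusters, z, smoothness, model.dof)
    peak_p = _stage("peak_corrected_p", peak_corrected_p, deviation, smoothness, model.dof,
                    sign=config.sign)

    areas = vertex_areas(mesh)
    regions = []
    for c in clusters.significant(config.alpha):
        mean_actual, mean_pred = _stage(
            "region_summary", region_summary, actual, predicted, c.vertices, areas
        )
        regions.append(
            {
                "cluster_id": c.id,
                "sign": c.sign,
                "p_cluster": c.p,
                "n_vertices": c.n_vertices,
                "area_mm2": c.area_mm2,
                "mean_actual_mm": mean_actual,
                "mean_predicted_mm": mean_pred,
            }
        )

    # ---- all stages done; write outputs
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    dev_path = os.path.join(out, "deviation.txt")
    dev_map = VertexMap(np.where(deviation.excluded, np.nan, deviation.values), kind="statistic")
    save_map(dev_map, dev_path)
    save_map(predicted, os.path.join(out, "predicted.txt"))
    save_map(peak_p, os.path.join(out, "peak_corrected_p.txt"))
    tsv_path = os.path.join(out, "clusters.tsv")
    clusters.write_tsv(tsv_path)
    report = CaseReport(
        deviation_map=dev_path,
        cluster_table=tsv_path,
        regions=regions,
        fwhm=smoothness.fwhm,
        resels=tuple(smoothness.resels),
        n_clusters=len(clusters),
        n_excluded_vertices=deviation.n_excluded,
        provenance={
            "deviate_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
            "config_sha256_16": config.digest(),
            "config": asdict(config),
            "cluster_forming_t": z,
            "dof": model.dof,
        },
    )
    report.to_json(os.path.join(out, "report.json"))
    return report
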