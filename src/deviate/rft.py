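"""Random-field-theory inference for deviation maps on triangulated surfaces.

The deviation statistic at each vertex behaves like a t field with
``nu = n - rank`` degrees of freedom under the null (a pseudo-case drawn
from the control population). Multiplicity over the surface is handled with
the expected-Euler-characteristic bound:

    P(max T > t)  <~  sum_d  R_d * rho_d(t)

where ``R_d`` are the resel counts of the search region (R_0 its Euler
characteristic, R_1 half its boundary length in FWHM units — zero for a
closed surface — and R_2 its area / FWHM^2) and ``rho_d`` are the
d-dimensional EC densities of a t field. Cluster-wise p-values use the
standard extent approximation: cluster sizes (in resels) are exponential
with mean E[N]/E[m], where E[m] is the expected cluster count (the expected
EC at the cluster-forming threshold) and E[N] the expected suprathreshold
volume; a cluster of k resels then gets

    p = 1 - exp(-E[m] * exp(-beta k)),   beta = E[m] / E[N].

The field smoothness (global FWHM) is estimated from the normalized control
residuals: for a unit-variance field the mean squared gradient g along mesh
edges satisfies FWHM = sqrt(4 ln 2 / g).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import log, pi

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln
from scipy.stats import t as t_dist

from .errors import DataError, IntegrityError
from .glm import DeviationMap, NormativeModel
from .mesh import TriangleMesh, VertexMap, region_topology, vertex_areas

_4LN2 = 4.0 * log(2.0)

SIGNS = ("positive", "negative", "two_sided")


# ------------------------------------------------------------- EC densities
def ec_density(d: int, t, nu: float):
    """d-dimensional Euler-characteristic density of a t field with nu df.

    ``rho_0`` is the upper-tail t probability; ``rho_1`` and ``rho_2`` are
    the standard 1- and 2-dimensional densities (per resel), which converge
    to the Gaussian densities as nu grows.
    """
    t = np.asarray(t, dtype=np.float64)
    if d == 0:
        return t_dist.sf(t, nu)
    finite = np.isfinite(t)
    tf = np.where(finite, t, 0.0)
    shape = np.power(1.0 + tf * tf / nu, -(nu - 1.0) / 2.0)
    if d == 1:
        rho = np.sqrt(_4LN2) / (2.0 * pi) * shape
    elif d == 2:
        c = np.exp(gammaln((nu + 1.0) / 2.0) - gammaln(nu / 2.0)) / np.sqrt(nu / 2.0)
        rho = _4LN2 / (2.0 * pi) ** 1.5 * c * tf * shape
    else:
        raise ValueError(f"no EC density for dimension {d}")
    # densities vanish at t = +/-inf
    return np.where(finite, rho, 0.0)


def expected_ec(t, resels, nu: float):
    """Expected Euler characteristic of the excursion set above t."""
    r0, r1, r2 = resels
    return r0 * ec_density(0, t, nu) + r1 * ec_density(1, t, nu) + r2 * ec_density(2, t, nu)


def cluster_forming_threshold(p: float, nu: float) -> float:
    """Convert an uncorrected vertex-wise p to the t quantile used for clusters."""
    if not 0.0 < p < 1.0:
        raise DataError(f"cluster-forming p must be in (0, 1), got {p}")
    return float(t_dist.isf(p, nu))


# ------------------------------------------------------------- smoothness
@dataclass
class SmoothnessEstimate:
    """Global field smoothness and the search region's resel counts."""

    fwhm: float  # mm
    resels: tuple  # (R_0, R_1, R_2)
    area: float  # mm^2 of the search region
    n_excluded: int = 0


def mean_squared_gradient(mesh: TriangleMesh, fields: np.ndarray, include=None) -> float:
    """Mean over edges of sum_k (field_k(a) - field_k(b))^2 / L_ab^2.

    ``fields`` is (k, V); the caller is responsible for normalization (unit
    variance per field, or unit sum-of-squares per vertex for residuals).
    """
    U = np.atleast_2d(np.asarray(fields, dtype=np.float64))
    edges = mesh.edges()
    if include is not None:
        keep = include[edges].all(axis=1)
        edges = edges[keep]
    if len(edges) == 0:
        raise DataError("no edges in the included region")
    L = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1)
    d2 = ((U[:, edges[:, 0]] - U[:, edges[:, 1]]) ** 2).sum(axis=0)
    return float((d2 / L**2).mean())


def estimate_field_fwhm(mesh: TriangleMesh, fields: np.ndarray, include=None) -> float:
    """FWHM (mm) of one or more raw unit-scale fields (rows normalized here)."""
    U = np.atleast_2d(np.asarray(fields, dtype=np.float64))
    sd = U.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise DataError("cannot estimate smoothness of a constant field")
    g = mean_squared_gradient(mesh, U / sd, include) / U.shape[0]
    return float(np.sqrt(_4LN2 / g))


def estimate_fwhm(
    residual_stack: np.ndarray,
    model: NormativeModel,
    mesh: TriangleMesh,
) -> SmoothnessEstimate:
    """Estimate the global FWHM and resel counts from control residuals.

    Residuals are normalized to unit sum of squares at every vertex, the mean
    squared gradient is taken along mesh edges, and the Gaussian-field
    relation FWHM = sqrt(4 ln 2 / g) converts it to millimetres. Zero-variance
    vertices are excluded from the search region; more than 50% excluded is a
    data error.
    """
    R = np.asarray(residual_stack, dtype=np.float64)
    if R.ndim != 2 or R.shape[1] != mesh.n_vertices:
        raise DataError(f"residual stack has shape {R.shape}; mesh has {mesh.n_vertices} vertices")
    if model.dof < 2:
        raise DataError("need at least 2 residual degrees of freedom")
    ss = (R**2).sum(axis=0)
    include = ss > 0
    n_excl = int((~include).sum())
    if n_excl > 0.5 * mesh.n_vertices:
        raise DataError(f"{n_excl}/{mesh.n_vertices} vertices have zero variance")
    U = np.zeros_like(R)
    np.divide(R, np.sqrt(ss), out=U, where=include)
    g = mean_squared_gradient(mesh, U, include)
    fwhm = float(np.sqrt(_4LN2 / g))
    chi, boundary, area = region_topology(mesh, include)
    resels = (float(chi), boundary / 2.0 / fwhm, area / fwhm**2)
    return SmoothnessEstimate(fwhm=fwhm, resels=resels, area=area, n_excluded=n_excl)


# ---------------------------------------------------------------- clusters
@dataclass
class Cluster:
    """One maximal connected suprathreshold component."""

    id: int
    sign: int  # +1 or -1
    vertices: np.ndarray
    area_mm2: float
    peak_stat: float
    peak_vertex: int
    resels: float | None = None
    p: float | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class ClusterTable:
    """Clusters found at one threshold, plus the settings that produced them."""

    clusters: list
    threshold: float
    sign: str

    def __len__(self):
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def significant(self, alpha: float) -> list:
        return [c for c in self.clusters if c.p is not None and c.p <= alpha]

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "id": c.id,
                "sign": c.sign,
                "n_vertices": c.n_vertices,
                "area_mm2": c.area_mm2,
                "resels": c.resels,
                "peak_stat": c.peak_stat,
                "peak_vertex": c.peak_vertex,
                "p_cluster": c.p,
            }
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "id",
                "sign",
                "n_vertices",
                "area_mm2",
                "resels",
                "peak_stat",
                "peak_vertex",
                "p_cluster",
            ],
        )

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def _components(mask: np.ndarray, adjacency: sp.csr_matrix):
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = adjacency[idx][:, idx]
    n, labels = connected_components(sub, directed=False)
    return [idx[labels == k] for k in range(n)]


def find_clusters(
    deviation: DeviationMap,
    threshold: float,
    mesh: TriangleMesh,
    sign: str = "two_sided",
) -> ClusterTable:
    """Connected components of suprathreshold vertices.

    ``sign`` selects positive excursions (s > z), negative (s < -z) or both
    (tracked separately, so a cluster never mixes signs). Extent is the sum
    of barycentric vertex areas over members. NaN (excluded) vertices are
    never suprathreshold.
    """
    if sign not in SIGNS:
        raise DataError(f"sign must be one of {SIGNS}")
    if not threshold > 0:
        raise DataError("cluster-forming threshold must be positive")
    s = np.asarray(deviation.values)
    areas = vertex_areas(mesh).values
    adjacency = mesh.adjacency_matrix()
    clusters: list[Cluster] = []
    with np.errstate(invalid="ignore"):
        masks = []
        if sign in ("positive", "two_sided"):
            masks.append((+1, s > threshold))
        if sign in ("negative", "two_sided"):
            masks.append((-1, s < -threshold))
    for sgn, mask in masks:
        mask = mask & ~deviation.excluded
        for verts in _components(mask, adjacency):
            vals = s[verts]
            peak_local = int(np.argmax(sgn * vals))
            clusters.append(
                Cluster(
                    id=0,
                    sign=sgn,
                    vertices=np.sort(verts),
                    area_mm2=float(areas[verts].sum()),
                    peak_stat=float(vals[peak_local]),
                    peak_vertex=int(verts[peak_local]),
                )
            )
    # deterministic order: largest |peak| first, ties broken by peak vertex
    clusters.sort(key=lambda c: (-abs(c.peak_stat), c.peak_vertex))
    for i, c in enumerate(clusters, start=1):
        c.id = i
    return ClusterTable(clusters=clusters, threshold=float(threshold), sign=sign)


# ------------------------------------------------------------- corrected p
def _sides(sign: str) -> int:
    return 2 if sign == "two_sided" else 1


def peak_corrected_p(
    deviation: DeviationMap,
    smoothness: SmoothnessEstimate,
    nu: float,
    sign: str = "two_sided",
) -> VertexMap:
    """Vertex-wise RFT-corrected p: the expected-EC bound at each statistic.

    Two-sided mode doubles the bound (two symmetric excursion sets). Excluded
    vertices get p = 1. Values are clipped to [0, 1], so deep negative
    statistics in one-sided positive mode saturate at 1.
    """
    if sign not in SIGNS:
        raise DataError(f"sign must be one of {SIGNS}")
    s = np.asarray(deviation.values, dtype=np.float64)
    if sign == "two_sided":
        stat = np.abs(s)
    elif sign == "negative":
        stat = -s
    else:
        stat = s.copy()
    stat = np.where(np.isnan(stat), -np.inf, stat)
    stat[deviation.excluded] = -np.inf
    p = _sides(sign) * expected_ec(stat, smoothness.resels, nu)
    p[deviation.excluded] = 1.0
    return VertexMap(np.clip(p, 0.0, 1.0), kind="p_value")


def cluster_corrected_p(
    clusters: ClusterTable,
    threshold: float,
    smoothness: SmoothnessEstimate,
    nu: float,
) -> ClusterTable:
    """Fill cluster-wise corrected p-values from the extent distribution.

    Requires ``threshold`` to match the one the clusters were formed at.
    Larger extent implies smaller p at fixed smoothness.
    """
    if abs(threshold - clusters.threshold) > 1e-9:
        raise DataError(
            f"threshold {threshold} does not match the cluster table's {clusters.threshold}"
        )
    z = float(threshold)
    sides = _sides(clusters.sign)
    e_m1 = float(expected_ec(z, smoothness.resels, nu))  # per excursion set
    e_n1 = float(smoothness.resels[2] * t_dist.sf(z, nu))  # suprathreshold resels
    e_m = sides * max(e_m1, 1e-300)
    beta = e_m1 / e_n1 if e_n1 > 0 else np.inf
    fwhm2 = smoothness.fwhm**2
    out = []
    for c in clusters:
        k = c.area_mm2 / fwhm2
        tail = np.exp(-beta * k) if np.isfinite(beta) else 0.0
        p = float(-np.expm1(-e_m * tail))
        out.append(replace(c, resels=k, p=min(1.0, max(p, 0.0))))
    return ClusterTable(clusters=out, threshold=clusters.threshold, sign=clusters.sign)
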