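"""Probabilistic posture maps: likelihood surfaces, region grids, ellipses.

Maps are rendered on the min-max-normalized [0,1]^2 feature square.  A
likelihood map evaluates the mixture density at cell centers; a region map
tags each cell with the posture region of the cluster that wins the posterior
responsibility; covariance ellipses visualize each component's uncertainty
through the eigendecomposition of its covariance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .svi_gmm import DIM, GMMParams, gmm_log_likelihood, posterior_responsibility
from .trajectory_features import FeatureVector


@dataclass
class NormalizationRecord:
    """Per-axis min-max transform fitted on training samples."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self):
        self.mins = np.asarray(self.mins, dtype=float).reshape(DIM)
        self.maxs = np.asarray(self.maxs, dtype=float).reshape(DIM)
        if np.any(self.maxs - self.mins <= 0):
            raise ValueError("degenerate axis")

    @property
    def ranges(self) -> np.ndarray:
        return self.maxs - self.mins

    def transform_array(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mins) / self.ranges

    def transform(self, points: Sequence[FeatureVector]) -> List[FeatureVector]:
        if any(p.normalized for p in points):
            raise ValueError("input is already normalized")
        return [
            FeatureVector(
                s=self.transform_array(p.s), t=p.t, label=p.label, normalized=True
            )
            for p in points
        ]

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(), "maxs": self.maxs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationRecord":
        return cls(np.array(d["mins"]), np.array(d["maxs"]))


def normalize_features(
    points: Sequence[FeatureVector],
) -> Tuple[List[FeatureVector], NormalizationRecord]:
    """Fit per-axis min-max scaling on the given points and apply it.

    The record re-applies the identical transform to new points (and refuses
    points that are already normalized, to prevent double scaling).
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points per axis")
    X = np.stack([p.s for p in points])
    mins, maxs = X.min(axis=0), X.max(axis=0)
    if np.any(maxs - mins <= 0):
        raise ValueError("degenerate axis")
    record = NormalizationRecord(mins, maxs)
    return record.transform(points), record


def transform_gmm(params: GMMParams, record: NormalizationRecord) -> GMMParams:
    """Push the mixture through the min-max affine map (posture-region
    responsibilities are invariant under this transform)."""
    S = np.diag(1.0 / record.ranges)
    means = record.transform_array(params.means)
    covs = S @ params.covariances @ S
    return GMMParams(weights=params.weights.copy(), means=means, covariances=covs)


@dataclass
class MapGrid:
    """A gridded surface over feature space."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray  # shape (ny, nx); rows indexed by y
    kind: str  # "likelihood" | "posterior" | "region"
    legend: Optional[Dict[int, str]] = None  # region code -> tag

    def __post_init__(self):
        self.x_edges = np.asarray(self.x_edges, dtype=float)
        self.y_edges = np.asarray(self.y_edges, dtype=float)
        if np.any(np.diff(self.x_edges) <= 0) or np.any(np.diff(self.y_edges) <= 0):
            raise ValueError("grid edges must be strictly increasing")
        if self.kind == "likelihood" and np.any(np.asarray(self.values) < 0):
            raise ValueError("likelihood values must be nonnegative")

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def cell_area(self) -> float:
        return float(np.diff(self.x_edges)[0] * np.diff(self.y_edges)[0])


def _grid(resolution: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    edges = np.linspace(0.0, 1.0, resolution + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    xx, yy = np.meshgrid(centers, centers)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    return edges, centers, pts


def likelihood_map(params: GMMParams, resolution: int = 200) -> MapGrid:
    """Mixture density evaluated at cell centers of the unit square."""
    if resolution < 16:
        raise ValueError("resolution must be >= 16")
    edges, _, pts = _grid(resolution)
    dens = np.exp(gmm_log_likelihood(pts, params)).reshape(resolution, resolution)
    return MapGrid(edges, edges, dens, kind="likelihood")


def region_map(
    params: GMMParams,
    labels: Dict[int, str],
    resolution: int = 200,
) -> MapGrid:
    """Each cell tagged by its winning cluster's posture region.

    Ties in the responsibility argmax go to the lowest cluster index.
    """
    if resolution < 16:
        raise ValueError("resolution must be >= 16")
    missing = set(range(params.K)) - set(labels)
    if missing:
        raise ValueError(f"labels must cover all clusters (missing {sorted(missing)})")
    edges, _, pts = _grid(resolution)
    r = posterior_responsibility(pts, params)
    codes = r.argmax(axis=1).reshape(resolution, resolution)
    return MapGrid(edges, edges, codes, kind="region", legend=dict(labels))


@dataclass
class Ellipse:
    """Uncertainty ellipse of one mixture component."""

    center: np.ndarray
    semi_axes: np.ndarray  # descending
    angle: float  # radians, rotation of the leading eigenvector

    def covariance(self, n_std: float = 1.0) -> np.ndarray:
        c, s = np.cos(self.angle), np.sin(self.angle)
        R = np.array([[c, -s], [s, c]])
        lam = (self.semi_axes / n_std) ** 2
        return R @ np.diag(lam) @ R.T


def covariance_ellipses(params: GMMParams, n_std: float = 1.0) -> List[Ellipse]:
    """Eigendecomposition of each component covariance as an ellipse record."""
    out = []
    for k in range(params.K):
        vals, vecs = np.linalg.eigh(params.covariances[k])
        if np.any(vals <= 0):
            raise ValueError("degenerate component")
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        lead = vecs[:, 0]
        if lead[0] < 0:  # fix the sign so the angle is reproducible
            lead = -lead
        out.append(
            Ellipse(
                center=params.means[k].copy(),
                semi_axes=n_std * np.sqrt(vals),
                angle=float(np.arctan2(lead[1], lead[0])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# CSV round trip: header row of x centers, first column of y centers


def write_map_csv(grid: MapGrid, path) -> None:
    xs = grid.x_centers
    ys = grid.y_centers
    with open(path, "w") as fh:
        fh.write("," + ",".join(repr(float(v)) for v in xs) + "\n")
        for i, yv in enumerate(ys):
            row = ",".join(repr(float(v)) for v in grid.values[i])
            fh.write(f"{float(yv)!r},{row}\n")
    if grid.kind == "region" and grid.legend is not None:
        sidecar = str(path) + ".legend.json"
        with open(sidecar, "w") as fh:
            json.dump({str(k): v for k, v in grid.legend.items()}, fh)


def read_map_csv(path, kind: str = "likelihood") -> MapGrid:
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        xs = np.array([float(v) for v in header[1:]])
        ys = []
        for line in fh:
            parts = line.strip().split(",")
            ys.append(float(parts[0]))
            rows.append([float(v) for v in parts[1:]])
    ys = np.array(ys)
    values = np.array(rows)

    def centers_to_edges(c):
        step = c[1] - c[0]
        return np.concatenate([[c[0] - step / 2], c + step / 2])

    legend = None
    if kind == "region":
        try:
            with open(str(path) + ".legend.json") as fh:
                legend = {int(k): v for k, v in json.load(fh).items()}
        except FileNotFoundError:
            pass
        values = values.astype(int)
    return MapGrid(centers_to_edges(xs), centers_to_edges(ys), values, kind, legend)
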