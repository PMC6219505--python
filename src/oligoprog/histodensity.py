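"""Cellular density from nuclei point patterns.

Nuclei centroids extracted from histopathology images are treated as a
realisation of a planar Poisson point process.  The spacing between
neighboring nuclei (nearest-neighbor distances via a KD-tree) follows,
for a homogeneous process of intensity lambda (nuclei per square
micron), the law

    f(r) = 2 pi lambda r exp(-pi lambda r^2).

Slides mix dense tumor regions with sparser normal tissue, so observed
spacings are modelled as a two-component mixture of this law; EM
deconvolves the tumor intensity lambda_tumor (the larger component) and
the normal intensity.  Across a cohort, the median lambda_tumor splits
samples into "less dense" and "more dense" categories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "PointPattern",
    "DensityFit",
    "DensityClassification",
    "nearest_neighbor_distances",
    "nn_pdf",
    "sample_nn_distances",
    "fit_poisson_mixture",
    "classify_cohort",
]


@dataclass
class PointPattern:
    """Nuclei centroids (microns) inside a rectangular field."""

    points: np.ndarray
    field_width: float
    field_height: float
    magnification: str = "20x"
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.field_width <= 0 or self.field_height <= 0:
            raise ValueError("degenerate field dimensions")
        if len(self.points) and (
            np.any(self.points[:, 0] < 0) or np.any(self.points[:, 0] > self.field_width)
            or np.any(self.points[:, 1] < 0) or np.any(self.points[:, 1] > self.field_height)
        ):
            raise ValueError("points outside the field")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        return self.field_width * self.field_height

    def write_csv(self, path) -> None:
        """CSV of x,y plus a JSON sidecar with field geometry/units."""
        path = Path(path)
        pd.DataFrame(self.points, columns=["x", "y"]).to_csv(path, index=False)
        meta = {"field_width": self.field_width, "field_height": self.field_height,
                "units": "um", "magnification": self.magnification,
                "sample_id": self.sample_id}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def read_csv(cls, path) -> "PointPattern":
        path = Path(path)
        pts = pd.read_csv(path)[["x", "y"]].to_numpy(float)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(pts, meta["field_width"], meta["field_height"],
                   meta.get("magnification", "20x"), meta.get("sample_id", ""))


def nearest_neighbor_distances(pattern: PointPattern,
                               border_margin: float = 0.0) -> np.ndarray:
    """Per-nucleus distance to its closest neighbor, via a KD-tree.

    Identical to exhaustive pairwise search.  ``border_margin``
    optionally drops query points within that distance of the field
    edge (their true neighbor may lie outside the field); neighbors are
    still searched among all points.
    """
    if pattern.n_points < 2:
        raise ValueError("need at least 2 points for nearest-neighbor distances")
    tree = cKDTree(pattern.points)
    d, _ = tree.query(pattern.points, k=2)
    nn = d[:, 1]
    if border_margin > 0:
        x, y = pattern.points.T
        inner = ((x >= border_margin) & (x <= pattern.field_width - border_margin)
                 & (y >= border_margin) & (y <= pattern.field_height - border_margin))
        nn = nn[inner]
        if len(nn) == 0:
            raise ValueError("border margin excluded every point")
    return nn


def nn_pdf(r, lam: float):
    """Nearest-neighbor distance density of a 2-D homogeneous Poisson
    process: 2 pi lam r exp(-pi lam r^2), mean 1/(2 sqrt(lam))."""
    if lam <= 0:
        raise ValueError("intensity must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be nonnegative")
    return 2.0 * np.pi * lam * r * np.exp(-np.pi * lam * r ** 2)


def _log_nn_pdf(r: np.ndarray, lam: float) -> np.ndarray:
    return np.log(2.0 * np.pi * lam) + np.log(r) - np.pi * lam * r ** 2


def _pooled_lambda(r: np.ndarray) -> float:
    """Maximum-likelihood single-Poisson intensity: n / (pi sum r^2)."""
    return len(r) / (np.pi * float(np.sum(r ** 2)))


def sample_nn_distances(lam: float, n: int, rng: np.random.Generator | int = 0,
                        ) -> np.ndarray:
    """Draw spacings directly from the Poisson nearest-neighbor law by
    inverting its CDF 1 - exp(-pi lam r^2)."""
    if lam <= 0 or n < 1:
        raise ValueError("need positive intensity and sample size")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    u = rng.random(n)
    return np.sqrt(-np.log1p(-u) / (np.pi * lam))


@dataclass
class DensityFit:
    """EM estimates of the two-component Poisson-spacing mixture.

    ``lambda_tumor`` is the larger intensity (denser component),
    ``mixing_weight`` the fraction of spacings attributed to it.
    ``lambda_inverse_tumor`` exposes the spacing-scale parameterisation
    (1/lambda)."""

    lambda_tumor: float
    lambda_normal: float
    mixing_weight: float
    log_likelihood: np.ndarray
    converged: bool
    n_iter: int
    lambda_pooled: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.lambda_tumor >= self.lambda_normal > 0):
            raise ValueError("require lambda_tumor >= lambda_normal > 0")
        if not 0 <= self.mixing_weight <= 1:
            raise ValueError("mixing weight must lie in [0, 1]")

    @property
    def lambda_inverse_tumor(self) -> float:
        return 1.0 / self.lambda_tumor


def _em_run(r: np.ndarray, lam: np.ndarray, w: float, max_iter: int,
            tol: float) -> tuple[np.ndarray, float, list[float], bool, int, bool]:
    ll_trace: list[float] = []
    prev = -np.inf
    degenerate = False
    for it in range(1, max_iter + 1):
        logp = np.column_stack([
            np.log(w) + _log_nn_pdf(r, lam[0]),
            np.log1p(-w) + _log_nn_pdf(r, lam[1]),
        ])
        m = logp.max(axis=1, keepdims=True)
        lse = m.ravel() + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        ll_trace.append(ll)
        gamma = np.exp(logp[:, 0] - lse)
        n1 = gamma.sum()
        n2 = len(r) - n1
        if n1 < 1e-6 * len(r) or n2 < 1e-6 * len(r):
            degenerate = True
            break
        lam = np.array([
            n1 / (np.pi * float(np.sum(gamma * r ** 2))),
            n2 / (np.pi * float(np.sum((1 - gamma) * r ** 2))),
        ])
        w = float(n1 / len(r))
        if prev > -np.inf and (ll - prev) < tol * max(1.0, abs(prev)):
            return lam, w, ll_trace, True, it, degenerate
        prev = ll
    return lam, w, ll_trace, False, len(ll_trace), degenerate


def fit_poisson_mixture(distances: np.ndarray, max_iter: int = 500,
                        tol: float = 1e-6, init_strategy: str = "median_split",
                        seed: int = 0) -> DensityFit:
    """Deconvolve tumor/normal intensities from pooled spacings by EM.

    E-step: posterior responsibility of the denser component for each
    spacing.  M-step (closed form): lambda_k = sum(gamma_k) /
    (pi * sum(gamma_k r^2)); w = mean responsibility.  Stops when the
    relative log-likelihood gain drops below ``tol``.  If a component
    collapses, the fit is retried from a random split; a persistent
    collapse is flagged ``degenerate`` and both components fall back to
    the pooled single-Poisson estimate.
    """
    r = np.asarray(distances, dtype=float).ravel()
    if len(r) < 10:
        raise ValueError("need at least 10 nearest-neighbor distances")
    if np.any(r <= 0):
        raise ValueError("distances must be strictly positive")

    def init_median() -> tuple[np.ndarray, float]:
        med = np.median(r)
        lo, hi = r[r <= med], r[r > med]
        return np.array([_pooled_lambda(lo), _pooled_lambda(hi)]), 0.5

    def init_random(rng: np.random.Generator) -> tuple[np.ndarray, float]:
        mask = rng.random(len(r)) < 0.5
        if mask.all() or not mask.any():
            mask[0] = not mask[0]
        a, b = r[mask], r[~mask]
        la, lb = _pooled_lambda(a), _pooled_lambda(b)
        return np.array([max(la, lb) * 2.0, min(la, lb) / 2.0]), 0.5

    rng = np.random.default_rng(seed)
    if init_strategy == "median_split":
        lam0, w0 = init_median()
    elif init_strategy == "random":
        lam0, w0 = init_random(rng)
    else:
        raise ValueError("init_strategy must be 'median_split' or 'random'")

    lam, w, trace, converged, n_iter, degen = _em_run(r, lam0, w0, max_iter, tol)
    if degen:
        lam0, w0 = init_random(rng)
        lam, w, trace, converged, n_iter, degen = _em_run(r, lam0, w0, max_iter, tol)
    pooled = _pooled_lambda(r)
    if degen:
        lam = np.array([pooled, pooled])
        w = 1.0
    # the denser (larger-lambda) component is the tumor component
    if lam[1] > lam[0]:
        lam = lam[::-1]
        w = 1.0 - w
    return DensityFit(float(lam[0]), float(lam[1]), float(w),
                      np.asarray(trace), converged, n_iter, pooled, degen)


@dataclass
class DensityClassification:
    """Cohort median split of per-sample tumor intensities."""

    sample_ids: list[str]
    lambda_tumor: np.ndarray
    cohort_median: float
    labels: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids,
                             "lambda_tumor": self.lambda_tumor,
                             "density_class": self.labels})


def classify_cohort(fits: dict[str, DensityFit]) -> DensityClassification:
    """Label each sample "more dense" iff its lambda_tumor exceeds the
    cohort median (ties -> "less dense")."""
    if len(fits) < 2:
        raise ValueError("need at least 2 samples to form a cohort split")
    ids = sorted(fits)
    lam = np.array([fits[s].lambda_tumor for s in ids])
    med = float(np.median(lam))
    labels = ["more dense" if v > med else "less dense" for v in lam]
    return DensityClassification(ids, lam, med, labels)
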