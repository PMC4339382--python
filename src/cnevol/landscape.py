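"""Mutational-landscape embedding and heterogeneity indices.

The pairwise minimum-event distances of one patient's samples are embedded
by classical multidimensional scaling into a Euclidean "mutational
landscape" in which distances approximate evolutionary distances.  Two
summary indices are computed there:

* the temporal heterogeneity (TH) index -- the distance between the robust
  centres of mass (geometric medians) of the pre-chemotherapy biopsy
  samples and the interval-debulking surgery samples, in event units;
* the clonal expansion (CE) index -- minus log10 of a Monte-Carlo p-value
  for local spatial clustering of the samples, measured by the mean
  nearest-neighbour distance against a uniform null in the bounding box
  of the observed coordinates.  Larger CE means tighter subclonal
  clusters, i.e. stronger clonal expansion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import DIPLOID_ID, DistanceMatrix
from .profiles import SampleRecord

__all__ = [
    "LandscapeEmbedding",
    "embed_landscape",
    "robust_center",
    "th_index",
    "ce_index",
    "dichotomize_by_median",
    "lower_median",
    "quartiles",
]


@dataclass(frozen=True)
class LandscapeEmbedding:
    ids: tuple[str, ...]
    coords: np.ndarray  # samples x retained dimensions
    eigenvalues: np.ndarray  # retained (positive) eigenvalues, descending

    @property
    def n_dimensions(self) -> int:
        return self.coords.shape[1]


def embed_landscape(
    dm: DistanceMatrix, include_diploid: bool = False, rel_tol: float = 1e-8
) -> LandscapeEmbedding:
    """Classical MDS of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and retains
    dimensions with eigenvalue > ``rel_tol`` times the largest.  Signs are
    fixed per dimension by making the largest-magnitude loading positive,
    so coordinates are deterministic.  The diploid pseudo-sample is
    dropped by default: the landscape describes the tumour samples.
    """
    ids = list(dm.ids)
    d = np.asarray(dm.values, dtype=float)
    if not include_diploid and DIPLOID_ID in ids:
        k = ids.index(DIPLOID_ID)
        keep = [i for i in range(len(ids)) if i != k]
        ids = [ids[i] for i in keep]
        d = d[np.ix_(keep, keep)]
    n = len(ids)
    if n < 3:
        raise ValueError("embedding needs >= 3 points")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    if w[0] <= 0:
        raise ValueError("degenerate distance matrix: no positive eigenvalue")
    keep = w > rel_tol * w[0]
    w, V = w[keep], V[:, keep]
    coords = V * np.sqrt(w)
    for j in range(coords.shape[1]):  # deterministic sign convention
        k = int(np.argmax(np.abs(coords[:, j])))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    return LandscapeEmbedding(tuple(ids), coords, w)


def robust_center(points: np.ndarray, tol: float = 1e-9, max_iter: int = 1000) -> np.ndarray:
    """Geometric median by Weiszfeld iterative reweighting.

    Equals the point itself for n = 1 and the midpoint for n = 2.  When an
    iterate lands on a data point the modified update of Vardi & Zhang is
    used so the iteration cannot stall.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) == 1:
        return pts[0].copy()
    if len(pts) == 2:
        return pts.mean(axis=0)
    y = pts.mean(axis=0)
    for _ in range(max_iter):
        dist = np.linalg.norm(pts - y, axis=1)
        at_point = dist < tol
        if at_point.any():
            others = ~at_point
            if not others.any():
                return y
            w = 1.0 / dist[others]
            t = (pts[others] * w[:, None]).sum(axis=0) / w.sum()
            # Vardi-Zhang correction: balance the coincident mass against
            # the pull of the remaining points
            R = np.linalg.norm(((pts[others] - y) / dist[others, None]).sum(axis=0))
            eta = at_point.sum()
            if R <= eta:
                return y
            step = min(1.0, eta / R)
            y_new = (1 - step) * t + step * y
        else:
            w = 1.0 / dist
            y_new = (pts * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def th_index(embedding: LandscapeEmbedding, records: list[SampleRecord]) -> float | None:
    """Distance between the robust centres of biopsy and surgery samples.

    Returns ``None`` when either timepoint class is absent (reported as
    missing, matching cohorts without paired biopsy/surgery sampling).
    """
    tp = {r.sample_id: r.timepoint for r in records}
    biopsy = [i for i, s in enumerate(embedding.ids) if tp.get(s) == "biopsy"]
    surgery = [i for i, s in enumerate(embedding.ids) if tp.get(s) == "surgery"]
    if not biopsy or not surgery:
        return None
    cb = robust_center(embedding.coords[biopsy])
    cs = robust_center(embedding.coords[surgery])
    return float(np.linalg.norm(cb - cs))


def _mean_nn_distance(coords: np.ndarray) -> float:
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def ce_index(embedding: LandscapeEmbedding, n_null: int = 10_000, seed: int = 0) -> float:
    """Clonal expansion index: -log10 p for nearest-neighbour clustering.

    The observed statistic is the mean nearest-neighbour distance among
    the embedded samples; the null draws the same number of points
    uniformly in the axis-aligned bounding box of the observed
    coordinates.  p = (1 + #{null <= observed}) / (n_null + 1).  A fully
    degenerate configuration (all samples identical) is maximally
    clustered and reports the maximum attainable CE.
    """
    coords = embedding.coords
    n, k = coords.shape
    if n < 3:
        raise ValueError("CE needs >= 3 samples")
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    if np.all(hi - lo <= 0):
        return float(-np.log10(1.0 / (n_null + 1)))
    observed = _mean_nn_distance(coords)
    rng = np.random.default_rng(seed)
    null_pts = rng.uniform(lo, hi, size=(n_null, n, k))
    diff = null_pts[:, :, None, :] - null_pts[:, None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    idx = np.arange(n)
    d[:, idx, idx] = np.inf
    null_w = d.min(axis=2).mean(axis=1)
    p = (1 + int(np.sum(null_w <= observed))) / (n_null + 1)
    return float(max(0.0, -np.log10(p)))


def lower_median(values) -> float:
    """Inverse-empirical-CDF median: the ceil(n/2)-th order statistic."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("empty input")
    return float(v[int(np.ceil(n / 2)) - 1])


def quartiles(values, method: str = "lower") -> tuple[float, float]:
    """First and third quartiles under the chosen quantile convention."""
    v = np.asarray(values, dtype=float)
    if method == "lower":
        s = np.sort(v)
        n = len(s)
        q1 = s[int(np.ceil(0.25 * n)) - 1]
        q3 = s[int(np.ceil(0.75 * n)) - 1]
        return float(q1), float(q3)
    if method == "linear":
        return tuple(float(x) for x in np.percentile(v, [25, 75]))
    raise ValueError(f"unknown method {method!r}")


def dichotomize_by_median(ce_values: dict[str, float], method: str = "lower") -> dict[str, str]:
    """Split patients into CE-low/CE-high groups at the median CE.

    The default threshold is the lower median (inverse empirical CDF at
    0.5); a patient is CE-high iff its CE is strictly greater than the
    threshold, so with distinct values the groups differ in size by at
    most one.  ``method='linear'`` uses the interpolated median instead.
    """
    items = [(k, v) for k, v in ce_values.items() if v is not None and np.isfinite(v)]
    if len(items) < 2:
        raise ValueError("need >= 2 patients with CE values")
    vals = [v for _, v in items]
    thr = lower_median(vals) if method == "lower" else float(np.median(vals))
    return {k: ("CE-high" if v > thr else "CE-low") for k, v in items}
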