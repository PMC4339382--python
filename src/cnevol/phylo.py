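"""Per-patient tree reconstruction and tree-shape hypothesis tests.

Trees are built by neighbour joining on the minimum-event distance matrix
(including the diploid pseudo-sample) and re-rooted at the diploid leaf,
so branch lengths are in event units and root-to-leaf paths measure
divergence from the normal genome.

Two cohort-level hypothesis tests operate on tree shape: a goodness-of-fit
test of the star topology (all samples radiating independently from the
ancestor, the expectation under exclusively primary-to-metastasis
seeding), and a dispersion test of clock-like evolution (equal
root-to-leaf path lengths).  P-values are corrected across patients with
the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import TreeNode, nj

from .distance import DIPLOID_ID, DistanceMatrix, PhasedPatient, med_symmetric

__all__ = [
    "build_tree",
    "split_support",
    "star_topology_test",
    "clock_test",
    "bh_adjust",
    "StarTestResult",
    "ClockTestResult",
]


def build_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbour-joining tree re-rooted at the diploid pseudo-sample.

    Negative NJ branch lengths are clamped to zero.  Ties during joining
    are broken by the (fixed) input order of the matrix, so the result is
    deterministic for a given sample ordering.
    """
    if not np.isfinite(dm.values).all():
        raise ValueError("distance matrix contains non-finite entries")
    if len(dm.ids) < 3:
        if len(dm.ids) != 2:
            raise ValueError("need >= 2 taxa")
        root = TreeNode(name=None)
        a = TreeNode(name=dm.ids[0], length=float(dm.values[0, 1]))
        b = TreeNode(name=dm.ids[1], length=0.0)
        root.extend([b, a])
        return root
    tree = nj(SkbioDM(dm.values, ids=list(dm.ids)))
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    rooted = tree.root_at(DIPLOID_ID if DIPLOID_ID in dm.ids else dm.ids[-1], above=0.0)
    for node in rooted.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    return rooted


def _splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each as the smaller-side tip-name set."""
    all_tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            other = all_tips - side
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def split_support(
    phased: PhasedPatient, n_replicates: int = 100, seed: int = 0
) -> dict[frozenset[str], float]:
    """Bootstrap support for each internal split of the patient's tree.

    Segments are resampled with replacement; the distance matrix and NJ
    tree are recomputed per replicate, and support is the fraction of
    replicates containing each split of the original tree.  Requires >= 4
    leaves (including the diploid); otherwise returns an empty mapping.
    """
    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    from .distance import distance_matrix

    dm = distance_matrix(phased)
    if len(dm.ids) < 4:
        return {}
    base = _splits(build_tree(dm))
    if not base:
        return {}
    rng = np.random.default_rng(seed)
    n_seg = phased.dataset.n_segments
    haps = [(np.asarray(p.cn_a), np.asarray(p.cn_b)) for p in phased.profiles]
    haps.append((np.ones(n_seg, dtype=np.int64), np.ones(n_seg, dtype=np.int64)))
    counts = {s: 0 for s in base}
    n = len(haps)
    for _ in range(n_replicates):
        idx = rng.integers(0, n_seg, size=n_seg)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = med_symmetric(haps[i][0][idx], haps[j][0][idx]) + med_symmetric(
                    haps[i][1][idx], haps[j][1][idx]
                )
        rep = _splits(build_tree(DistanceMatrix(dm.ids, d)))
        for s in base:
            if s in rep:
                counts[s] += 1
    return {s: c / n_replicates for s, c in counts.items()}


@dataclass(frozen=True)
class StarTestResult:
    chi2: float
    df: int
    p: float
    testable: bool = True
    p_adj: float | None = None


@dataclass(frozen=True)
class ClockTestResult:
    statistic: float
    df: int
    p: float
    testable: bool = True
    p_adj: float | None = None


def star_topology_test(dm: DistanceMatrix, eps: float = 1.0) -> StarTestResult:
    """Chi-squared goodness of fit of the star-topology null.

    Under a star, every pairwise distance decomposes as d_ij = b_i + b_j
    with per-taxon branch lengths b >= 0.  Branches are fitted by
    non-negative least squares over all taxa (the diploid included, which
    makes patients with only three samples testable); the statistic is
    sum (d_ij - e_ij)^2 / max(e_ij, eps) on n(n-1)/2 - n degrees of
    freedom.  Small p-values indicate branched (metastasis-to-metastasis)
    evolution.
    """
    n = len(dm.ids)
    df = n * (n - 1) // 2 - n
    if df < 1:
        return StarTestResult(float("nan"), df, float("nan"), testable=False)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    A = np.zeros((len(pairs), n))
    y = np.empty(len(pairs))
    for r, (i, j) in enumerate(pairs):
        A[r, i] = A[r, j] = 1.0
        y[r] = dm.values[i, j]
    b, _ = optimize.nnls(A, y)
    expected = A @ b
    chi2 = float(np.sum((y - expected) ** 2 / np.maximum(expected, eps)))
    p = float(stats.chi2.sf(chi2, df))
    return StarTestResult(chi2, df, p)


def clock_test(tree: TreeNode, exclude: str = DIPLOID_ID) -> ClockTestResult:
    """Dispersion test of rate constancy across lineages.

    Root-to-leaf path lengths l_i (the diploid pseudo-leaf excluded, being
    the root itself) should be equal under a molecular clock; the index of
    dispersion sum (l_i - lbar)^2 / lbar is referred to chi-squared with
    n_leaves - 1 degrees of freedom.
    """
    lengths = []
    for tip in tree.tips():
        if tip.name == exclude:
            continue
        lengths.append(sum(n.length or 0.0 for n in tip.ancestors() if n.parent is not None)
                       + (tip.length or 0.0))
    lengths = np.asarray(lengths, dtype=float)
    if len(lengths) < 3:
        return ClockTestResult(float("nan"), max(len(lengths) - 1, 0), float("nan"), testable=False)
    mean = lengths.mean()
    df = len(lengths) - 1
    if mean == 0:
        return ClockTestResult(float("nan"), df, float("nan"), testable=False)
    stat = float(np.sum((lengths - mean) ** 2) / mean)
    return ClockTestResult(stat, df, float(stats.chi2.sf(stat, df)))


def bh_adjust(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjustment; NaN/None pass through."""
    p = [None if (x is None or (isinstance(x, float) and np.isnan(x))) else float(x) for x in p_values]
    finite = [(i, x) for i, x in enumerate(p) if x is not None]
    for _, x in finite:
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {x}")
    out: list[float] = [np.nan] * len(p)
    if finite:
        from statsmodels.stats.multitest import multipletests

        idx, vals = zip(*finite)
        adj = multipletests(list(vals), method="fdr_bh")[1]
        for i, a in zip(idx, adj):
            out[i] = float(a)
    return out
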