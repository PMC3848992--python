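"""Geographic overlap versus divergence time.

For every internal node of the species tree the present-day geographic
ranges (zone sets) of its two daughter clades either intersect (overlap = 1)
or not (overlap = 0).  Under prevailing allopatric speciation, young nodes
should show no overlap while older splits have had time for secondary range
expansion, so the probability of overlap should increase with node age; this
is tested by a logistic regression of the binary overlap on node age with a
Wald test on the slope.

Cosmopolitan species are handled by policy: ``expand`` treats the
cosmopolitan token as the full zone vocabulary (overlapping everything) while
``origin`` keeps it as a private token unless a per-species area of origin is
supplied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .treeio import Node, UltrametricTree, ZONES

__all__ = [
    "OverlapRecord",
    "LogisticFit",
    "clade_zone_set",
    "overlap_table",
    "fit_overlap_logistic",
    "sister_pair_range_overlap",
]

COSMOPOLITAN = "Cosmopolitan"


@dataclass
class OverlapRecord:
    node_index: int
    age: float
    overlap: int
    left_zones: frozenset
    right_zones: frozenset


@dataclass
class LogisticFit:
    """Logit(P(overlap)) = intercept + slope * age."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    p_value: float
    converged: bool
    separation: bool
    degenerate: bool
    firth: bool
    n: int


def _tip_zones_resolved(
    label: str,
    tip_zones: Mapping[str, frozenset],
    policy: str,
    vocabulary: Sequence[str],
    origins: Mapping[str, frozenset] | None,
) -> frozenset:
    zones = frozenset(tip_zones[label])
    if COSMOPOLITAN in zones:
        if origins and label in origins:
            zones = (zones - {COSMOPOLITAN}) | frozenset(origins[label])
        elif policy == "expand":
            zones = (zones - {COSMOPOLITAN}) | frozenset(v for v in vocabulary if v != COSMOPOLITAN)
        elif policy != "origin":
            raise ValueError(f"unknown cosmopolitan policy {policy!r}")
    return zones


def clade_zone_set(
    tree: UltrametricTree,
    node: Node,
    tip_zones: Mapping[str, frozenset],
    policy: str = "expand",
    vocabulary: Sequence[str] = ZONES,
    origins: Mapping[str, frozenset] | None = None,
) -> frozenset:
    """Union of the member species' zone sets (cosmopolitan by policy)."""
    tips = tree.clade_tips(node)
    missing = [t.label for t in tips if t.label not in tip_zones or not tip_zones[t.label]]
    if missing:
        raise ValueError(f"tips without zones: {missing[:5]}")
    out: frozenset = frozenset()
    for t in tips:
        out |= _tip_zones_resolved(t.label, tip_zones, policy, vocabulary, origins)
    return out


def overlap_table(
    tree: UltrametricTree,
    tip_zones: Mapping[str, frozenset],
    policy: str = "expand",
    vocabulary: Sequence[str] = ZONES,
    origins: Mapping[str, frozenset] | None = None,
    min_support: float | None = None,
) -> list[OverlapRecord]:
    """One record per internal node: (age, daughter-clade range overlap).

    ``min_support`` optionally restricts the table to well-supported splits;
    by default every internal node contributes.
    """
    tree.require_ultrametric()
    tree.require_binary()
    cache: dict[Node, frozenset] = {}
    for node in tree.postorder():
        if node.is_tip:
            cache[node] = clade_zone_set(tree, node, tip_zones, policy, vocabulary, origins)
        else:
            cache[node] = frozenset().union(*(cache[c] for c in node.children))
    records = []
    for node in tree.internal_nodes():
        if min_support is not None and node.support is not None and node.support < min_support:
            continue
        left, right = (cache[c] for c in node.children)
        records.append(
            OverlapRecord(
                node_index=node.index,
                age=node.age,
                overlap=int(bool(left & right)),
                left_zones=left,
                right_zones=right,
            )
        )
    return records


def _detect_separation(age: np.ndarray, y: np.ndarray) -> bool:
    """Complete or quasi-complete separation on a single covariate: the two
    response classes occupy non-interleaved age ranges."""
    a0, a1 = age[y == 0], age[y == 1]
    if a0.size == 0 or a1.size == 0:
        return False
    return bool(a0.max() <= a1.min() or a1.max() <= a0.min())


def _firth_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Firth-penalized logistic regression (Jeffreys-prior score adjustment),
    which yields finite estimates under separation."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return beta, None, False
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, info_inv, True
    return beta, info_inv, False


def fit_overlap_logistic(
    records: Sequence[OverlapRecord], firth: bool = False
) -> LogisticFit:
    """Maximum-likelihood logistic fit of overlap on node age.

    Uses iteratively reweighted least squares (statsmodels) with a Wald test
    on the slope.  An all-0 or all-1 response yields a degenerate result with
    flags rather than an exception; separation is flagged and, when ``firth``
    is on, handled by Jeffreys penalization.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 overlap records")
    age = np.array([r.age for r in records], dtype=float)
    y = np.array([r.overlap for r in records], dtype=float)
    n = len(records)
    nan = float("nan")

    if y.min() == y.max():
        return LogisticFit(nan, nan, nan, nan, nan, False, False, True, firth, n)

    separation = _detect_separation(age, y)
    X = np.column_stack([np.ones(n), age])

    if firth:
        beta, cov, converged = _firth_fit(X, y)
        if cov is None:
            return LogisticFit(nan, nan, nan, nan, nan, False, separation, False, True, n)
        se = np.sqrt(np.diag(cov))
        z = beta[1] / se[1]
        from scipy.stats import norm

        p = 2.0 * norm.sf(abs(z))
        return LogisticFit(
            beta[0], beta[1], se[0], se[1], float(p), converged, separation, False, True, n
        )

    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, X)
            res = model.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False)) and not separation
        se = res.bse
        pval = float(res.pvalues[1])
        if not math.isfinite(se[1]) or se[1] > 1e6 / max(np.ptp(age), 1e-12):
            separation = True
        return LogisticFit(
            float(res.params[0]), float(res.params[1]), float(se[0]), float(se[1]),
            pval if not separation else nan,
            converged, separation, False, False, n,
        )
    except Exception:
        return LogisticFit(nan, nan, nan, nan, nan, False, True, False, False, n)


def sister_pair_range_overlap(
    tree: UltrametricTree,
    tip_zones: Mapping[str, frozenset],
    policy: str = "expand",
    vocabulary: Sequence[str] = ZONES,
    origins: Mapping[str, frozenset] | None = None,
) -> tuple[int, int]:
    """(total cherries, cherries with disjoint zone sets under the policy)."""
    from .treeio import sister_pairs

    pairs = sister_pairs(tree)
    non_overlap = 0
    for a, b, _ in pairs:
        za = _tip_zones_resolved(a, tip_zones, policy, vocabulary, origins)
        zb = _tip_zones_resolved(b, tip_zones, policy, vocabulary, origins)
        if not (za & zb):
            non_overlap += 1
    return len(pairs), non_overlap
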