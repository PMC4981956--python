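"""Phylogenetic comparative methods: tree calibration, Brownian-motion
covariance, phylogenetic signal (Blomberg's K, Pagel's lambda) and
squared-change parsimony ancestral-state reconstruction.

Traits are tip-indexed :class:`pandas.Series` (label -> value).

Calibration model
-----------------
Node ages come from three sources, in priority order: explicit node
constraints (fixed or minimum ages on named MRCAs), tip first
occurrences (terminal branches extend to the tip's oldest fossil; 0 for
extant tips), and — for every node neither constrained nor terminal —
the mean of its nearest dated ancestor and its oldest dated descendant
("mean between two bracketing estimates"), applied root-to-tips. Branch
duration is simply parent age minus child age, so ghost lineages (the
span between a clade's origin and its oldest fossil) fall out of the
arithmetic. Conflicts (a parent not strictly older than a child) are
raised, never silently adjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .errors import CalibrationError, TreeError
from .tree import Phylogeny
from .types import CalibrationConstraint

#: jitter (Ma) applied to zero off-diagonal covariance gaps for matrix
#: inversion only; reported ages are never altered
ZERO_BRANCH_EPSILON = 1e-6


# ---------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------


def calibrate_tree(
    topology: Phylogeny,
    tip_ages: Optional[Dict[str, Tuple[float, float]]] = None,
    constraints: Sequence[CalibrationConstraint] = (),
) -> Phylogeny:
    """Assign an age (Ma) to every node; returns a dated copy.

    ``tip_ages`` maps taxon -> (first, last) occurrence and overrides
    ages carried by ``topology``; unlisted tips are extant. If the root
    is unconstrained it takes the age of its oldest dated descendant —
    with only minimum ages available the tree is as shallow as the
    evidence allows ("hard minimum rather than soft maximum").
    Deterministic and idempotent: ages depend only on topology,
    occurrences and constraints.
    """
    phy = topology.clone()
    if tip_ages:
        for taxon, (fo, lo) in tip_ages.items():
            if fo < lo:
                raise CalibrationError(f"tip {taxon!r}: first {fo} < last {lo}")
            phy.first_occurrence[taxon] = fo
            phy.last_occurrence[taxon] = lo

    for leaf in phy.tree.leaf_node_iter():
        leaf.age = phy.first_occurrence.get(leaf.taxon.label, 0.0)

    # resolve constraints to nodes
    fixed_age: Dict[dendropy.Node, float] = {}
    oldest_tip_below = _oldest_tip_first_occurrence(phy)
    for c in constraints:
        node = phy.mrca(c.mrca_of)
        if node.is_leaf():
            raise CalibrationError(
                f"constraint {sorted(c.mrca_of)} resolves to a tip, not a clade"
            )
        oldest = oldest_tip_below[node]
        if c.kind == "fixed":
            if c.age < oldest[0]:
                raise CalibrationError(
                    f"fixed age {c.age} Ma on MRCA of {sorted(c.mrca_of)} is younger "
                    f"than descendant tip {oldest[1]!r} (first occurrence {oldest[0]} Ma)"
                )
            age = c.age
        else:  # minimum
            age = max(c.age, oldest[0])
        if node in fixed_age and fixed_age[node] != age:
            raise CalibrationError(
                f"conflicting constraints on one node: {fixed_age[node]} vs {age} Ma"
            )
        fixed_age[node] = age

    # oldest *dated* evidence below each node: constrained descendants
    # and tip first occurrences
    oldest_dated_below: Dict[dendropy.Node, float] = {}
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            continue
        best = -math.inf
        for child in node.child_nodes():
            if child.is_leaf():
                best = max(best, child.age)
            else:
                own = fixed_age.get(child, -math.inf)
                best = max(best, own, oldest_dated_below[child])
        oldest_dated_below[node] = best

    root = phy.root
    if root in fixed_age:
        root.age = fixed_age[root]
    else:
        root.age = oldest_dated_below[root]

    for node in phy.tree.preorder_node_iter():
        if node is root or node.is_leaf():
            continue
        if node in fixed_age:
            node.age = fixed_age[node]
        else:
            node.age = 0.5 * (node.parent_node.age + oldest_dated_below[node])

    # hard-minimum dating can leave a zero-length branch on the path to
    # the oldest fossil (handled downstream by the inversion jitter);
    # only a parent *younger* than its child is a genuine conflict
    violations = []
    for node in phy.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.parent_node.age < node.age - 1e-12:
            child = node.taxon.label if node.is_leaf() else "internal node"
            violations.append(
                f"parent age {node.parent_node.age} Ma younger than "
                f"{child} at {node.age} Ma"
            )
    if violations:
        raise CalibrationError("; ".join(violations))
    return phy


def _oldest_tip_first_occurrence(phy: Phylogeny) -> Dict[dendropy.Node, Tuple[float, str]]:
    out: Dict[dendropy.Node, Tuple[float, str]] = {}
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            out[node] = (phy.first_occurrence.get(lab, 0.0), lab)
        else:
            out[node] = max((out[c] for c in node.child_nodes()), key=lambda p: p[0])
    return out


def branch_duration_table(phy: Phylogeny) -> pd.DataFrame:
    """Per-edge durations (Ma) of a calibrated tree, tips named."""
    rows = []
    for node in phy.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        rows.append(
            {
                "child": node.taxon.label if node.is_leaf() else "",
                "is_tip": node.is_leaf(),
                "child_age": phy.node_age(node),
                "parent_age": phy.node_age(node.parent_node),
                "duration": phy.node_age(node.parent_node) - phy.node_age(node),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Brownian-motion covariance
# ---------------------------------------------------------------------


def bm_covariance(phy: Phylogeny) -> pd.DataFrame:
    """Brownian-motion covariance of a calibrated tree.

    ``C[i, j]`` is the elapsed time (Ma) from the root to the MRCA of
    tips i and j; the diagonal is each tip's depth. Symmetric PSD;
    polytomies need no resolution. Zero-length interior branches are
    legal here (they collapse covariance ties) — downstream inversion
    applies :data:`ZERO_BRANCH_EPSILON` if needed.
    """
    if not phy.is_calibrated:
        raise TreeError("bm_covariance needs a calibrated tree")
    labels = phy.tip_labels
    ix = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    root_age = phy.node_age(phy.root)
    C = np.zeros((n, n))
    tipsets: Dict[dendropy.Node, List[int]] = {}
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            i = ix[node.taxon.label]
            C[i, i] = root_age - phy.node_age(node)
            tipsets[node] = [i]
        else:
            depth = root_age - phy.node_age(node)
            kids = [tipsets.pop(c) for c in node.child_nodes()]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            C[i, j] = C[j, i] = depth
            tipsets[node] = [i for k in kids for i in k]
    return pd.DataFrame(C, index=labels, columns=labels)


def _aligned(C: pd.DataFrame, trait: pd.Series) -> Tuple[np.ndarray, np.ndarray]:
    missing = [t for t in C.index if t not in trait.index]
    if missing:
        raise TreeError(f"trait values missing for tips: {missing}")
    x = trait.reindex(C.index).to_numpy(dtype=float)
    if np.isnan(x).any():
        bad = [t for t, v in zip(C.index, x) if np.isnan(v)]
        raise TreeError(f"non-finite trait values for tips: {bad}")
    return C.to_numpy(dtype=float), x


def _safe_inv(C: np.ndarray) -> np.ndarray:
    try:
        return linalg.inv(C)
    except linalg.LinAlgError:
        # singular from zero-length branches: jitter the diagonal only
        return linalg.inv(C + ZERO_BRANCH_EPSILON * np.eye(C.shape[0]))


# ---------------------------------------------------------------------
# phylogenetic signal
# ---------------------------------------------------------------------


@dataclass
class SignalResult:
    """One phylogenetic-signal estimate.

    ``statistic_name`` is ``"K"`` (permutation p-value) or ``"lambda"``
    (maximum-likelihood estimate; p-value from a likelihood-ratio test
    against lambda = 0 on 1 df).
    """

    statistic_name: str
    estimate: float
    n_tips: int
    log_likelihood: Optional[float] = None
    p_value: Optional[float] = None
    n_permutations: int = 0


def _k_ratio(x: np.ndarray, Cinv: np.ndarray, n: int) -> float:
    ones = np.ones(n)
    a_hat = (ones @ Cinv @ x) / (ones @ Cinv @ ones)
    r = x - a_hat
    mse0 = (r @ r) / (n - 1)
    mse = (r @ Cinv @ r) / (n - 1)
    return mse0 / mse


def blomberg_k(
    phy: Phylogeny,
    trait: pd.Series,
    n_permutations: int = 999,
    seed: Optional[int] = None,
) -> SignalResult:
    """Blomberg's K: observed MSE0/MSE against its Brownian expectation.

    K = 1 is the Brownian-motion reference; K < 1 means less resemblance
    among relatives than BM predicts. The p-value is the fraction of
    tip-label permutations whose K is at least the observed one
    (observed permutation included).
    """
    C_df = bm_covariance(phy)
    C, x = _aligned(C_df, trait)
    n = x.size
    if n < 4:
        raise TreeError(f"Blomberg's K needs >= 4 tips, got {n}")
    Cinv = _safe_inv(C)
    expected = (np.trace(C) - n / Cinv.sum()) / (n - 1)
    k_obs = _k_ratio(x, Cinv, n) / expected
    p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            k_perm = _k_ratio(rng.permutation(x), Cinv, n) / expected
            if k_perm >= k_obs - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    return SignalResult(
        statistic_name="K",
        estimate=float(k_obs),
        n_tips=n,
        p_value=p,
        n_permutations=n_permutations,
    )


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform: off-diagonal covariances scaled by
    ``lam``, diagonal unchanged. lam = 1 returns C; lam = 0 its diagonal."""
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _lambda_max(C: np.ndarray, cap: float = 1.2) -> float:
    lam = cap
    while lam > 1.0:
        try:
            linalg.cholesky(lambda_transform(C, lam))
            return lam
        except linalg.LinAlgError:
            lam = 1.0 + (lam - 1.0) / 2.0
            if lam - 1.0 < 1e-4:
                break
    return 1.0


def _lambda_loglik(lam: float, C: np.ndarray, x: np.ndarray) -> float:
    n = x.size
    V = lambda_transform(C, lam)
    try:
        cho = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.log(np.diag(cho[0])).sum()
    ones = np.ones(n)
    Vi_x = linalg.cho_solve(cho, x)
    Vi_1 = linalg.cho_solve(cho, ones)
    a_hat = (ones @ Vi_x) / (ones @ Vi_1)
    r = x - a_hat
    sig2 = (r @ linalg.cho_solve(cho, r)) / n
    if sig2 <= 0:
        return -np.inf
    return -0.5 * (n * math.log(2 * math.pi * sig2) + logdet + n)


def pagel_lambda(phy: Phylogeny, trait: pd.Series) -> SignalResult:
    """Maximum-likelihood Pagel's lambda on [0, lambda_max].

    The mean and Brownian rate are profiled analytically at each lambda;
    the search bound keeps the transformed covariance positive-definite
    (capped at 1.2 so estimates near 1 are not artificially truncated).
    """
    C_df = bm_covariance(phy)
    C, x = _aligned(C_df, trait)
    n = x.size
    if n < 4:
        raise TreeError(f"Pagel's lambda needs >= 4 tips, got {n}")
    lam_max = _lambda_max(C)
    res = optimize.minimize_scalar(
        lambda lam: -_lambda_loglik(lam, C, x),
        bounds=(0.0, lam_max),
        method="bounded",
        options={"xatol": 1e-6},
    )
    candidates = [float(res.x), 0.0, lam_max] + ([1.0] if lam_max >= 1.0 else [])
    lam_hat = max(candidates, key=lambda lam: _lambda_loglik(lam, C, x))
    ll_hat = _lambda_loglik(lam_hat, C, x)
    ll_0 = _lambda_loglik(0.0, C, x)
    lr = max(0.0, 2.0 * (ll_hat - ll_0))
    p = float(stats.chi2.sf(lr, df=1))
    return SignalResult(
        statistic_name="lambda",
        estimate=float(lam_hat),
        n_tips=n,
        log_likelihood=float(ll_hat),
        p_value=p,
    )


# ---------------------------------------------------------------------
# squared-change parsimony
# ---------------------------------------------------------------------


@dataclass
class ASRResult:
    """Squared-change parsimony reconstruction.

    ``node_values`` maps every node (tips included) to its value; tips
    keep their observed values. ``cost`` is the minimised sum over edges
    of (parent - child)^2 with every branch length treated as 1 —
    divergence times deliberately ignored.
    """

    node_values: Dict[dendropy.Node, float]
    cost: float

    def root_value(self, phy: Phylogeny) -> float:
        return self.node_values[phy.root]

    def table(self, phy: Phylogeny) -> pd.DataFrame:
        rows = []
        for i, node in enumerate(phy.tree.preorder_node_iter()):
            rows.append(
                {
                    "node": node.taxon.label if node.is_leaf() else f"internal_{i}",
                    "is_tip": node.is_leaf(),
                    "value": self.node_values[node],
                }
            )
        return pd.DataFrame(rows)


def parsimony_asr(phy: Phylogeny, trait: pd.Series) -> ASRResult:
    """Exact squared-change parsimony on unit branch lengths.

    Two passes of dynamic programming over quadratics: the minimal
    subtree cost below any node is a parabola in the node's value, so
    the down-pass propagates (curvature, vertex, offset) triples —
    polytomies combine additively — and the up-pass fixes each node at
    the minimiser given its parent. Deterministic; cost is the global
    minimum of sum over edges of (parent - child)^2.
    """
    missing = [t for t in phy.tip_labels if t not in trait.index or pd.isna(trait[t])]
    if missing:
        raise TreeError(f"trait values missing for tips: {missing}")

    # down-pass: f_node(v) = A (v - B)^2 + Cst = min cost of the subtree
    # if the node takes value v (edge to parent excluded)
    quad: Dict[dendropy.Node, Tuple[float, float, float]] = {}
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            continue
        A = Csum = AB = AB2 = 0.0
        for child in node.child_nodes():
            if child.is_leaf():
                a, b, c = 1.0, float(trait[child.taxon.label]), 0.0
            else:
                ca, cb, cc = quad[child]
                # min_x ca (x-cb)^2 + cc + (v-x)^2 = ca/(ca+1) (v-cb)^2 + cc
                a, b, c = ca / (ca + 1.0), cb, cc
            A += a
            AB += a * b
            AB2 += a * b * b
            Csum += c
        B = AB / A
        quad[node] = (A, B, Csum + AB2 - A * B * B)

    values: Dict[dendropy.Node, float] = {}
    root = phy.root
    if root.is_leaf():
        raise TreeError("tree has a single tip; nothing to reconstruct")
    values[root] = quad[root][1]
    for node in phy.tree.preorder_node_iter():
        if node is root:
            continue
        p = values[node.parent_node]
        if node.is_leaf():
            values[node] = float(trait[node.taxon.label])
        else:
            A, B, _ = quad[node]
            values[node] = (A * B + p) / (A + 1.0)

    cost = 0.0
    for node in phy.tree.preorder_node_iter():
        if node.parent_node is not None:
            d = values[node.parent_node] - values[node]
            cost += d * d
    return ASRResult(node_values=values, cost=cost)
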