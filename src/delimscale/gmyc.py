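"""Single-threshold general mixed Yule-coalescent (GMYC) species delimitation.

The model views an ultrametric tree as the outcome of two branching
processes separated by a threshold age ``T``: nodes older than ``T`` are
diversification (Yule-like) events among species lineages, nodes younger
than ``T`` are coalescent events inside species clusters.  Between
successive events the total branching rate is

    b_i = lambda_z * n_z^p_z  +  lambda_coal * sum_k [n_k (n_k - 1)]^p_c

where ``n_z`` counts diversification-class lineages alive in the interval
(all lineages above ``T``; singleton lineages below ``T``) and ``n_k`` the
lineages of cluster ``k``.  Following the GMYC literature, each inter-event
waiting time ``x_i`` is modelled as exponential with the combined rate:
the interval contributes ``log(b_i) - b_i x_i``, with ``b_i`` evaluated
from the lineage counts on the young side of the closing event.  (Any
interval boundary inserted at ``T`` itself closes no event and contributes
only its exponential term.)  The exponents ``p_z`` and ``p_c`` let each
process deviate from its pure form; the null model is a single coalescent
process over the whole tree.

The Moran-style estimator ``lambda = m / sum n_i (n_i - 1) x_i`` (exponent
fixed at 1) is exposed separately because its explosion on near-zero waiting
intervals is the mechanism behind GMYC's oversplitting on long alignments:
longer alignments resolve more unique haplotypes, which adds near-zero
internal branches, which drives the coalescent-rate estimate towards
infinity and the fitted threshold towards zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .trees import is_ultrametric, node_ages

__all__ = [
    "GmycIntervalTable",
    "GmycFit",
    "classify_lineages",
    "interval_table",
    "mixed_loglik",
    "null_loglik",
    "fit_gmyc",
    "moran_lambda",
]

@dataclass
class GmycIntervalTable:
    """Inter-event intervals of an ultrametric tree under a fixed threshold.

    Interval ``i`` runs from age ``t[i]`` to ``t[i+1]`` (ascending from the
    tips); ``x[i]`` is its waiting time.  ``nz[i]`` counts
    diversification-class lineages; ``cluster_w_flat`` holds the
    ``n_k (n_k - 1)`` terms of all clusters with >= 2 lineages, indexed into
    intervals by ``cluster_interval_idx``.  Events close every interval whose
    upper boundary is a node age; the boundary inserted at ``T`` closes no
    event.  Event arrays store the young-side count entering its rate term.
    """

    x: np.ndarray  # (m,) waiting times, sums to root age
    nz: np.ndarray  # (m,) diversification-class lineage counts
    cluster_w_flat: np.ndarray  # flattened n_k(n_k-1) >= 2 terms
    cluster_interval_idx: np.ndarray  # interval index of each flat term
    is_event: np.ndarray  # (m,) True when the interval is closed by a node
    yule_event_n: np.ndarray  # n_z at each Yule event (young side; diagnostics)
    coal_event_w: np.ndarray  # n_k(n_k-1) at each coalescent event (young side)

    @property
    def n_events(self) -> int:
        return int(self.is_event.sum())


def _crossing_lineages(tree: dendropy.Tree, T: float, ages: dict) -> list[list]:
    """Tip-sets of the lineages crossing age ``T`` (whole tree if root <= T)."""
    root = tree.seed_node
    if ages[root] <= T:
        return [list(tree.leaf_node_iter())]
    out = []

    def walk(node) -> None:
        if ages[node] <= T:
            out.append(list(node.leaf_iter()))
            return
        for ch in node.child_nodes():
            walk(ch)

    walk(root)
    return out


def classify_lineages(
    tree: dendropy.Tree, T: float
) -> tuple[list[list[str]], list[str], dict[str, str]]:
    """Split tips into clusters (>= 2 tips) and singletons at threshold ``T``.

    Clusters are the maximal subtrees whose root age is <= ``T`` while the
    parent node is older; tips whose lineage crosses ``T`` alone are
    singletons.  Returns ``(clusters, singletons, partition)`` where the
    partition maps every sample to a species label.
    """
    if not is_ultrametric(tree):
        raise ValueError("GMYC requires an ultrametric tree")
    if T < 0:
        raise ValueError("threshold must be >= 0")
    ages = node_ages(tree)
    groups = _crossing_lineages(tree, T, ages)
    clusters: list[list[str]] = []
    singletons: list[str] = []
    for tips in groups:
        labels = sorted(lf.taxon.label for lf in tips)
        if len(labels) >= 2:
            clusters.append(labels)
        else:
            singletons.extend(labels)
    clusters.sort(key=lambda c: c[0])
    partition: dict[str, str] = {}
    k = 0
    for c in clusters:
        k += 1
        for s in c:
            partition[s] = f"sp{k}"
    for s in sorted(singletons):
        k += 1
        partition[s] = f"sp{k}"
    return clusters, singletons, partition


def interval_table(tree: dendropy.Tree, T: float) -> GmycIntervalTable:
    """Build the inter-event interval table for threshold ``T``."""
    ages = node_ages(tree)
    root_age = ages[tree.seed_node]
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    internals.sort(key=lambda n: ages[n])
    n_tips = sum(1 for _ in tree.leaf_node_iter())

    # map every internal node to the crossing lineage (cluster) containing it
    groups = _crossing_lineages(tree, T, ages)
    node_cluster: dict = {}
    cluster_count: list[int] = []
    for ci, tips in enumerate(groups):
        if len(tips) < 2:
            continue
        # group root: highest ancestor of any member tip with age <= T
        node = tips[0]
        while node.parent_node is not None and ages[node.parent_node] <= T:
            node = node.parent_node
        idx = len(cluster_count)
        cluster_count.append(len(tips))
        stack = [node]
        while stack:
            v = stack.pop()
            if not v.is_leaf():
                node_cluster[id(v)] = idx
            stack.extend(v.child_nodes())

    # sweep events from the tips towards the root, maintaining counts
    n_clusters = len(cluster_count)
    cl_lineages = np.array(cluster_count, dtype=np.int64)  # below T at age 0
    n_singletons = sum(1 for g in groups if len(g) == 1)
    total = n_tips

    x: list[float] = []
    nz: list[int] = []
    w_flat: list[float] = []
    w_idx: list[int] = []
    is_event: list[bool] = []
    yule_event_n: list[float] = []
    coal_event_w: list[float] = []

    def push_interval(lo: float, hi: float, above: bool) -> None:
        x.append(hi - lo)
        is_event.append(True)  # flipped to False for the synthetic T boundary
        i = len(x) - 1
        if above:
            nz.append(total)
        else:
            nz.append(n_singletons)
            for c in cl_lineages:
                if c >= 2:
                    w_flat.append(float(c * (c - 1)))
                    w_idx.append(i)

    prev = 0.0
    for node in internals:
        a = ages[node]
        if prev < T < a:
            push_interval(prev, T, above=False)
            is_event[-1] = False
            prev = T
        push_interval(prev, a, above=prev >= T)
        prev = a
        if a > T:
            yule_event_n.append(float(total))
        else:
            ci = node_cluster[id(node)]
            c = cl_lineages[ci]
            coal_event_w.append(float(c * (c - 1)))
            cl_lineages[ci] -= 1
        total -= 1
    # if T >= root_age the threshold is never crossed: all events coalescent

    return GmycIntervalTable(
        x=np.asarray(x),
        nz=np.asarray(nz, dtype=np.int64),
        cluster_w_flat=np.asarray(w_flat),
        cluster_interval_idx=np.asarray(w_idx, dtype=np.int64),
        is_event=np.asarray(is_event, dtype=bool),
        yule_event_n=np.asarray(yule_event_n),
        coal_event_w=np.asarray(coal_event_w),
    )


def _rate_per_interval(
    tab: GmycIntervalTable,
    lambda_z: float,
    p_z: float,
    lambda_coal: float,
    p_c: float,
) -> np.ndarray:
    nz = tab.nz.astype(float)
    b = lambda_z * np.where(nz > 0, nz**p_z, 0.0)
    if len(tab.cluster_w_flat):
        b = b + lambda_coal * np.bincount(
            tab.cluster_interval_idx,
            weights=tab.cluster_w_flat**p_c,
            minlength=len(tab.x),
        )
    return b


def _loglik_from_table(
    tab: GmycIntervalTable,
    lambda_z: float,
    p_z: float,
    lambda_coal: float,
    p_c: float,
) -> float:
    if min(lambda_z, lambda_coal) < 0:
        raise ValueError("rates must be >= 0")
    b = _rate_per_interval(tab, lambda_z, p_z, lambda_coal, p_c)
    b_event = b[tab.is_event]
    if np.any(b_event <= 0):
        return -math.inf
    return float(np.log(b_event).sum() - (b * tab.x).sum())


def mixed_loglik(
    tree: dendropy.Tree,
    T: float,
    lambda_z: float,
    p_z: float,
    lambda_coal: float,
    p_c: float,
) -> float:
    """Log likelihood of the mixed Yule/coalescent model at threshold ``T``.

    Returns ``-inf`` (rather than raising) when a class with observed events
    has zero rate.
    """
    return _loglik_from_table(interval_table(tree, T), lambda_z, p_z, lambda_coal, p_c)


def null_loglik(tree: dendropy.Tree, lambda_coal: float, p_c: float) -> float:
    """Single-coalescent null model: one process over the whole tree."""
    ages = node_ages(tree)
    T = ages[tree.seed_node] * 2.0 + 1.0
    return _loglik_from_table(interval_table(tree, T), 0.0, 1.0, lambda_coal, p_c)


def _profile_loglik(tab: GmycIntervalTable, p_z: float, p_c: float):
    """Profile out both rates in closed form; returns (logL, lz, lc)."""
    nz = tab.nz.astype(float)
    S_z = float((np.where(nz > 0, nz**p_z, 0.0) * tab.x).sum())
    if len(tab.cluster_w_flat):
        S_c = float((tab.cluster_w_flat**p_c * tab.x[tab.cluster_interval_idx]).sum())
    else:
        S_c = 0.0
    m_z = len(tab.yule_event_n)
    m_c = len(tab.coal_event_w)
    total = 0.0
    lz = 0.0
    lc = 0.0
    if m_z:
        if S_z <= 0:
            return -math.inf, math.inf, lc
        lz = m_z / S_z
        total += m_z * math.log(lz) + p_z * float(np.log(tab.yule_event_n).sum()) - m_z
    if m_c:
        if S_c <= 0:
            return -math.inf, lz, math.inf
        lc = m_c / S_c
        total += m_c * math.log(lc) + p_c * float(np.log(tab.coal_event_w).sum()) - m_c
    return total, lz, lc


@dataclass
class GmycFit:
    """Fitted single-threshold GMYC model."""

    threshold: float
    lambda_z: float
    p_z: float
    lambda_coal: float
    p_c: float
    logL_mixed: float
    logL_null: float
    lr: float
    df: int
    p_value: float
    n_clusters: int
    n_entities: int
    partition: dict[str, str]
    clusters: list[list[str]] = field(default_factory=list)
    singletons: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_species(self) -> int:
        return self.n_entities


def _candidate_thresholds(ages_sorted: np.ndarray, root_age: float) -> list[float]:
    distinct = np.unique(ages_sorted)
    cands = []
    if distinct[0] > 0:
        cands.append(distinct[0] / 2.0)
    else:
        cands.append(0.0)
    for a, b in zip(distinct, distinct[1:]):
        cands.append((a + b) / 2.0)
    cands.append(root_age * 1.5 + 1e-12)
    return cands


def _maximise_at_threshold(
    tab: GmycIntervalTable,
    p_bounds: tuple[float, float],
    n_starts: int,
    rng: np.random.Generator,
):
    lo, hi = p_bounds
    has_yule = bool(np.any(tab.nz > 0))
    has_coal = len(tab.cluster_w_flat) > 0
    starts = [(1.0, 1.0), (0.5, 2.0), (2.0, 0.5)]
    while len(starts) < n_starts:
        starts.append(tuple(rng.uniform(lo, min(hi, 4.0), size=2)))
    best = (-math.inf, 1.0, 1.0, 0.0, 0.0)  # logL, p_z, p_c, lz, lc
    LOGL_BOUNDS = (-35.0, 35.0)

    def unpack(params):
        i = 0
        lz = pz = lc = pc = 0.0
        if has_yule:
            lz, pz = math.exp(params[i]), params[i + 1]
            i += 2
        else:
            pz = 1.0
        if has_coal:
            lc, pc = math.exp(params[i]), params[i + 1]
        else:
            pc = 1.0
        return lz, pz, lc, pc

    def neg(params):
        ll = _loglik_from_table(tab, *unpack(params))
        return -ll if np.isfinite(ll) else 1e12

    for s in starts[:n_starts]:
        pz0, pc0 = float(np.clip(s[0], lo, hi)), float(np.clip(s[1], lo, hi))
        # initialise the rates at their single-class (per-process) MLEs
        _, lz0, lc0 = _profile_loglik(tab, pz0, pc0)
        x0 = []
        bounds = []
        if has_yule:
            x0 += [math.log(max(lz0, 1e-8)), pz0]
            bounds += [LOGL_BOUNDS, (lo, hi)]
        if has_coal:
            x0 += [math.log(max(lc0, 1e-8)), pc0]
            bounds += [LOGL_BOUNDS, (lo, hi)]
        res = minimize(
            neg,
            x0=np.asarray(x0),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200},
        )
        lz, pz, lc, pc = unpack(res.x)
        ll = _loglik_from_table(tab, lz, pz, lc, pc)
        if ll > best[0]:
            best = (ll, pz, pc, lz, lc)
    return best


def fit_gmyc(
    tree: dendropy.Tree,
    p_bounds: tuple[float, float] = (0.0, 10.0),
    n_starts: int = 5,
    df: int = 3,
    seed: int = 0,
) -> GmycFit:
    """Fit the single-threshold GMYC model by maximum likelihood.

    Candidate thresholds are the midpoints between consecutive distinct node
    ages plus one candidate below all nodes and one above the root.  At each
    candidate the rates (log scale) and exponents are optimised numerically
    (multi-start L-BFGS-B, initialised at per-class closed-form rate
    estimates).  Ties within 1e-8
    log-likelihood resolve towards fewer entities.  The likelihood-ratio
    test compares against the single-coalescent null with ``df`` degrees of
    freedom (3 by default: threshold + extra rate + extra exponent).
    """
    if not is_ultrametric(tree):
        raise ValueError("GMYC requires an ultrametric tree")
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    if n_tips < 3:
        raise ValueError("need >= 3 tips")
    warns: list[str] = []
    ages = node_ages(tree)
    internal_ages = np.array(
        sorted(ages[n] for n in tree.preorder_node_iter() if not n.is_leaf())
    )
    root_age = internal_ages[-1]
    if root_age <= 0:
        warns.append("degenerate tree: all node ages are zero")
    if np.any(internal_ages < 1e-12 * max(root_age, 1.0)):
        warns.append(
            "near-zero node ages detected (identical haplotypes?); "
            "deduplication before GMYC is recommended"
        )
    if np.ptp(internal_ages) <= 1e-12 * max(root_age, 1.0):
        warns.append("all node ages equal within tolerance; threshold degenerate")

    rng = np.random.default_rng(seed)
    candidates = _candidate_thresholds(internal_ages, root_age)

    null_tab = interval_table(tree, root_age * 2.0 + 1.0)
    best_null = (-math.inf, 1.0, 0.0)
    for p0 in (0.5, 1.0, 2.0):
        res = minimize(
            lambda p: -_profile_loglik(null_tab, 1.0, float(p[0]))[0],
            x0=[p0],
            method="L-BFGS-B",
            bounds=[p_bounds],
            options={"maxiter": 200},
        )
        ll, _, lc = _profile_loglik(null_tab, 1.0, float(res.x[0]))
        if ll > best_null[0]:
            best_null = (ll, float(res.x[0]), lc)
    logL_null, null_p, null_lambda = best_null

    best = None
    for T in candidates:
        tab = interval_table(tree, T)
        ll, p_z, p_c, lz, lc = _maximise_at_threshold(tab, p_bounds, n_starts, rng)
        n_ent = len(_crossing_lineages(tree, T, ages))
        cand = {
            "T": T,
            "logL": ll,
            "p_z": p_z,
            "p_c": p_c,
            "lambda_z": lz,
            "lambda_coal": lc,
            "n_entities": n_ent,
        }
        if best is None:
            best = cand
        elif ll > best["logL"] + 1e-8:
            best = cand
        elif abs(ll - best["logL"]) <= 1e-8 and n_ent < best["n_entities"]:
            best = cand
    assert best is not None
    if not np.isfinite(best["logL"]):
        raise RuntimeError("GMYC optimisation failed at every candidate threshold")

    clusters, singletons, partition = classify_lineages(tree, best["T"])
    lr = max(2.0 * (best["logL"] - logL_null), 0.0)
    p_value = float(chi2.sf(lr, df)) if df > 0 else math.nan
    return GmycFit(
        threshold=float(best["T"]),
        lambda_z=float(best["lambda_z"]),
        p_z=float(best["p_z"]),
        lambda_coal=float(best["lambda_coal"]),
        p_c=float(best["p_c"]),
        logL_mixed=float(best["logL"]),
        logL_null=float(logL_null),
        lr=float(lr),
        df=df,
        p_value=p_value,
        n_clusters=len(clusters),
        n_entities=len(clusters) + len(singletons),
        partition=partition,
        clusters=clusters,
        singletons=singletons,
        warnings=warns,
    )


def moran_lambda(tree: dendropy.Tree) -> float:
    """Closed-form coalescent rate ``m / sum n_i (n_i - 1) x_i`` (exponent 1).

    The denominator accumulates ``n (n - 1)`` times the waiting time over the
    inter-event intervals of the whole tree treated as one coalescent.
    Near-zero waiting intervals drive the estimate towards infinity, which is
    the oversplitting mechanism this package's scaling experiment probes.
    """
    ages = node_ages(tree)
    internal = sorted(
        ages[n] for n in tree.preorder_node_iter() if not n.is_leaf()
    )
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    m = len(internal)
    denom = 0.0
    prev = 0.0
    alive = n_tips
    for a in internal:
        denom += alive * (alive - 1) * (a - prev)
        prev = a
        alive -= 1
    if denom <= 0:
        warnings.warn("all waiting times are zero; lambda estimate is infinite")
        return math.inf
    return m / denom
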