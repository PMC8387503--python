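"""Permutational multivariate statistics, prey aggregation, and clustering.

PERMANOVA partitions the total sum of squared inter-point distances
(Anderson's identity SS_total = (1/N) Σ_{i<j} d²_ij) into among- and
within-group components and assesses the pseudo-F statistic by permuting
observations.  When the number of distinct relabelings is small the
permutation distribution is enumerated exactly; otherwise a Monte-Carlo
p-value (1 + #{F_perm ≥ F_obs}) / (1 + B) is used, which can never be zero.

SIMPER decomposes the average between-group dissimilarity into per-variable
contributions.  The default decomposition is the squared-difference
(Euclidean-compatible) one, consistent with Euclidean-distance PERMANOVA;
the classical Bray–Curtis mode is available behind a flag.

Pairwise tests are adjusted with the Benjamini–Yekutieli method (FDR control
under arbitrary dependence), and statistically indistinguishable,
ecologically compatible prey are merged into functional groups.  Cluster
analysis is Ward linkage on z-standardised tracer values, the number of
clusters selected by the Dunn index and validated by leave-one-out linear
discriminant accuracy.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MultivarError",
    "PermanovaResult",
    "SimperResult",
    "ClusterTree",
    "ClusterSolution",
    "FunctionalGroup",
    "permanova",
    "permanova_two_way",
    "pairwise_permanova",
    "benjamini_yekutieli",
    "simper",
    "merge_sources",
    "hierarchical_cluster",
    "select_k_dunn",
    "dunn_index",
    "lda_validate",
    "pearson_screen",
]

logger = logging.getLogger(__name__)


class MultivarError(ValueError):
    """Invalid input to a multivariate statistic."""


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermanovaResult:
    """One-way PERMANOVA outcome: pseudo-F, permutation p, SS partition."""

    pseudo_f: float
    p_value: float
    df_among: int
    df_within: int
    n_permutations: int
    ss_among: float
    ss_within: float
    ss_total: float
    method: str = "monte-carlo"  # or "exact"


def _as_sq_distance(data: np.ndarray, precomputed: bool) -> np.ndarray:
    """Return the squared Euclidean distance matrix (n, n)."""
    data = np.asarray(data, float)
    if precomputed:
        if data.ndim != 2 or data.shape[0] != data.shape[1]:
            raise MultivarError("precomputed distance matrix must be square")
        return data**2
    if data.ndim == 1:
        data = data[:, None]
    return squareform(pdist(data, metric="sqeuclidean"))


def _ss_within_batch(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """SS_within for a batch of labelings.

    ``onehot``: (B, n, g) indicator arrays, ``sizes``: (g,) group sizes.
    SS_within = Σ_g (1/n_g) Σ_{i<j in g} d²_ij.
    """
    out = np.zeros(onehot.shape[0])
    for gi in range(onehot.shape[2]):
        v = onehot[:, :, gi]  # (B, n)
        out += np.einsum("bi,ij,bj->b", v, d2, v) / (2.0 * sizes[gi])
    return out


def _labels_to_onehot(labels: np.ndarray, g: int) -> np.ndarray:
    b, n = labels.shape
    eye = np.eye(g)
    return eye[labels]  # (B, n, g)


def permanova(
    data,
    labels,
    *,
    n_permutations: int = 9999,
    seed: int | None = None,
    precomputed: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances.

    ``data`` is an (n, p) value matrix (or an (n, n) distance matrix with
    ``precomputed=True``); ``labels`` the group of each row.  Requires at
    least two groups of at least two observations.  Exact enumeration over
    all distinct relabelings replaces Monte-Carlo sampling when it is cheaper
    than ``n_permutations``.
    """
    labels = np.asarray(labels)
    codes, uniques = pd.factorize(labels)
    g = len(uniques)
    n = len(codes)
    if g < 2:
        raise MultivarError("need at least 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise MultivarError("singleton group: every group needs >= 2 observations")

    d2 = _as_sq_distance(data, precomputed)
    if d2.shape[0] != n:
        raise MultivarError("labels length does not match data")
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    if ss_total <= 1e-12:
        raise MultivarError("constant data: total sum of squares is zero")

    def f_stat(ssw: np.ndarray) -> np.ndarray:
        ssa = ss_total - ssw
        return (ssa / (g - 1)) / np.where(ssw > 0, ssw / (n - g), np.nan)

    ss_within = float(_ss_within_batch(d2, _labels_to_onehot(codes[None, :], g), sizes)[0])
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        f_obs = math.inf
    else:
        f_obs = float(f_stat(np.array([ss_within]))[0])

    n_exact = _n_distinct_relabelings(sizes)
    if n_exact <= n_permutations:
        perm_labels = np.array(list(_distinct_relabelings(codes)), dtype=int)
        ssw = _ss_within_batch(d2, _labels_to_onehot(perm_labels, g), sizes)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_perm = np.where(ssw > 0, f_stat(ssw), np.inf)
        p = float(np.count_nonzero(f_perm >= f_obs - 1e-12) / len(f_perm))
        return PermanovaResult(
            f_obs, p, g - 1, n - g, len(f_perm), ss_among, ss_within, ss_total, "exact"
        )

    rng = np.random.default_rng(seed)
    count = 0
    for start in range(0, n_permutations, 512):
        b = min(512, n_permutations - start)
        perm = rng.permuted(np.broadcast_to(codes, (b, n)), axis=1)
        ssw = _ss_within_batch(d2, _labels_to_onehot(perm, g), sizes)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_perm = np.where(ssw > 0, f_stat(ssw), np.inf)
        count += int(np.count_nonzero(f_perm >= f_obs - 1e-12))
    p = (1 + count) / (1 + n_permutations)
    return PermanovaResult(
        f_obs, p, g - 1, n - g, n_permutations, ss_among, ss_within, ss_total, "monte-carlo"
    )


def _n_distinct_relabelings(sizes: np.ndarray) -> float:
    n = int(sizes.sum())
    out = math.factorial(n)
    for s in sizes:
        out //= math.factorial(int(s))
    return out


def _distinct_relabelings(codes: np.ndarray):
    """All distinct arrangements of the label multiset (lexicographic)."""
    from sympy.utilities.iterables import multiset_permutations

    yield from multiset_permutations(sorted(codes.tolist()))


def permanova_two_way(
    data,
    factor_a,
    factor_b,
    *,
    n_permutations: int = 9999,
    seed: int | None = None,
    interaction: bool = True,
) -> dict[str, PermanovaResult]:
    """Two-factor PERMANOVA with partial (Type III-style) sums of squares.

    Uses the Gower-centred inner-product matrix G of the squared Euclidean
    distances; the SS explained by a design is tr(HGH) with H its hat matrix,
    and each term's partial SS is the drop in explained SS when that term's
    columns are removed from the full design (sum-to-zero coding).
    Significance comes from free permutation of raw observations — the
    simplest defensible scheme; permutation of residuals is not implemented.
    """
    data = np.asarray(data, float)
    if data.ndim == 1:
        data = data[:, None]
    n = data.shape[0]
    d2 = _as_sq_distance(data, precomputed=False)
    j = np.eye(n) - np.ones((n, n)) / n
    gmat = -0.5 * j @ d2 @ j

    def _dummies(fac):
        codes, uniq = pd.factorize(np.asarray(fac))
        z = np.eye(len(uniq))[codes][:, :-1]  # drop last level
        return z - z.mean(axis=0), len(uniq) - 1  # centred ~ sum-to-zero

    za, dfa = _dummies(factor_a)
    zb, dfb = _dummies(factor_b)
    terms: dict[str, np.ndarray] = {"A": za, "B": zb}
    dfs = {"A": dfa, "B": dfb}
    if interaction:
        zab = np.einsum("ni,nj->nij", za, zb).reshape(n, -1)
        terms["A:B"] = zab - zab.mean(axis=0)
        dfs["A:B"] = dfa * dfb

    def explained(cols: list[np.ndarray], g_inner: np.ndarray) -> float:
        x = np.column_stack([np.ones(n)] + cols)
        q, _ = np.linalg.qr(x)
        h = q @ q.T
        return float(np.trace(h @ g_inner @ h))

    def partial_ss(g_inner: np.ndarray) -> tuple[dict[str, float], float]:
        full_cols = list(terms.values())
        ss_full = explained(full_cols, g_inner)
        ss_res = float(np.trace(g_inner)) - ss_full
        out = {}
        for name in terms:
            reduced = [v for t, v in terms.items() if t != name]
            out[name] = ss_full - explained(reduced, g_inner)
        return out, ss_res

    ss_obs, ss_res = partial_ss(gmat)
    df_res = n - 1 - sum(dfs.values())
    if df_res <= 0:
        raise MultivarError("no residual degrees of freedom")
    f_obs = {t: (ss_obs[t] / dfs[t]) / (ss_res / df_res) for t in terms}

    rng = np.random.default_rng(seed)
    exceed = {t: 0 for t in terms}
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        gp = gmat[np.ix_(perm, perm)]
        ss_p, ss_res_p = partial_ss(gp)
        for t in terms:
            fp = (ss_p[t] / dfs[t]) / (ss_res_p / df_res) if ss_res_p > 0 else np.inf
            if fp >= f_obs[t] - 1e-12:
                exceed[t] += 1
    ss_total = float(np.trace(gmat))
    return {
        t: PermanovaResult(
            f_obs[t],
            (1 + exceed[t]) / (1 + n_permutations),
            dfs[t],
            df_res,
            n_permutations,
            ss_obs[t],
            ss_res,
            ss_total,
        )
        for t in terms
    }


def benjamini_yekutieli(p_values) -> np.ndarray:
    """Benjamini–Yekutieli adjusted p-values (FDR under arbitrary dependence).

    With m tests and c(m) = Σ_{i=1..m} 1/i, the sorted raw p_(j) maps to
    min(1, min_{j' >= j} m·c(m)·p_(j')/j'), returned in the input order.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise MultivarError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def pairwise_permanova(
    data,
    labels,
    *,
    n_permutations: int = 9999,
    seed: int | None = None,
    precomputed: bool = False,
) -> pd.DataFrame:
    """PERMANOVA for every group pair, with BY-adjusted p-values.

    Returns a table with columns group_a, group_b, pseudo_f, p_value,
    p_adjusted, n_permutations, method.
    """
    labels = np.asarray(labels)
    data = np.asarray(data, float)
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise MultivarError("need at least 2 groups")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(groups) * (len(groups) - 1) // 2)
    rows = []
    for (a, b), child in zip(itertools.combinations(groups, 2), child_seeds):
        mask = (labels == a) | (labels == b)
        if precomputed:
            sub = data[np.ix_(mask, mask)]
        else:
            sub = data[mask]
        res = permanova(
            sub,
            labels[mask],
            n_permutations=n_permutations,
            seed=child.generate_state(1)[0],
            precomputed=precomputed,
        )
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "pseudo_f": res.pseudo_f,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
                "method": res.method,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = benjamini_yekutieli(out["p_value"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimperResult:
    """Per-variable contributions to average between-group dissimilarity.

    ``table`` is sorted by decreasing contribution with columns variable,
    contribution, pct, cum_pct; ``cutoff_set`` is the minimal descending
    variable set whose cumulative share reaches the cutoff.
    """

    table: pd.DataFrame
    total_dissimilarity: float
    cutoff: float
    cutoff_set: tuple[str, ...]
    mode: str = "sq_euclidean"


def simper(
    data,
    labels,
    pair: tuple,
    *,
    cutoff: float = 0.70,
    mode: str = "sq_euclidean",
    variable_names: list[str] | None = None,
) -> SimperResult:
    """Similarity-percentage decomposition for one group pair.

    ``mode="sq_euclidean"`` (default) decomposes the mean squared Euclidean
    distance between groups additively per variable, matching the
    Euclidean-distance PERMANOVA; ``mode="bray_curtis"`` is the classical
    percent decomposition for non-negative abundance data.
    """
    if isinstance(data, pd.DataFrame):
        variable_names = variable_names or list(data.columns)
        data = data.to_numpy(float)
    data = np.asarray(data, float)
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[1] < 1:
        raise MultivarError("need at least one variable")
    labels = np.asarray(labels)
    a, b = pair
    for grp in (a, b):
        if not np.any(labels == grp):
            raise MultivarError(f"unknown group label {grp!r}")
    xa = data[labels == a]  # (na, p)
    xb = data[labels == b]
    diff = xa[:, None, :] - xb[None, :, :]  # (na, nb, p)
    if mode == "sq_euclidean":
        contrib = (diff**2).mean(axis=(0, 1))
    elif mode == "bray_curtis":
        if (data < 0).any():
            raise MultivarError("bray_curtis mode requires non-negative data")
        denom = (xa[:, None, :] + xb[None, :, :]).sum(axis=2, keepdims=True)
        contrib = (np.abs(diff) / np.where(denom > 0, denom, np.nan)).mean(axis=(0, 1))
    else:
        raise MultivarError(f"unknown SIMPER mode {mode!r}")
    total = float(contrib.sum())
    names = variable_names or [f"v{i}" for i in range(data.shape[1])]
    order = np.argsort(-contrib, kind="stable")
    pct = contrib[order] / total if total > 0 else np.zeros_like(contrib)
    table = pd.DataFrame(
        {
            "variable": [names[i] for i in order],
            "contribution": contrib[order],
            "pct": pct,
            "cum_pct": np.cumsum(pct),
        }
    )
    n_cut = int(np.searchsorted(table["cum_pct"].to_numpy(), cutoff) + 1) if total > 0 else 0
    return SimperResult(
        table=table,
        total_dissimilarity=total,
        cutoff=cutoff,
        cutoff_set=tuple(table["variable"].head(n_cut)),
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Prey merging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FunctionalGroup:
    """A merged set of prey units treated as one mixing source."""

    name: str
    members: tuple[str, ...]


def merge_sources(
    units: list[str],
    pairwise: pd.DataFrame,
    ecology: dict[str, str],
    alpha: float = 0.05,
) -> list[FunctionalGroup]:
    """Merge prey units that are statistically indistinguishable *and*
    ecologically compatible.

    Two units are mergeable iff their BY-adjusted p exceeds ``alpha`` and
    they share an ecology guild tag; transitive conflicts (a merged component
    containing a significantly different pair) are resolved by single linkage
    over the mergeable relation, with a logged note.  Region-split units stay
    separate whenever their between-region test is significant.
    """
    required = {frozenset(p) for p in itertools.combinations(units, 2)}
    seen = {
        frozenset((r.group_a, r.group_b))
        for r in pairwise.itertuples()
        if r.group_a in units and r.group_b in units
    }
    if required - seen:
        missing = sorted(tuple(sorted(p)) for p in required - seen)
        raise MultivarError(f"pairwise table does not cover all unit pairs: {missing[:3]}...")

    parent = {u: u for u in units}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    mergeable = set()
    for r in pairwise.itertuples():
        if r.group_a not in parent or r.group_b not in parent:
            continue
        if r.p_adjusted > alpha and ecology.get(r.group_a) == ecology.get(r.group_b) and ecology.get(r.group_a) not in (None, ""):
            mergeable.add(frozenset((r.group_a, r.group_b)))
            ra, rb = find(r.group_a), find(r.group_b)
            if ra != rb:
                parent[ra] = rb

    components: dict[str, list[str]] = {}
    for u in units:
        components.setdefault(find(u), []).append(u)
    for root, members in components.items():
        for a, b in itertools.combinations(members, 2):
            if frozenset((a, b)) not in mergeable:
                logger.info(
                    "transitive merge: %s and %s joined via single linkage despite a "
                    "significant (or ecology-blocked) pairwise test",
                    a,
                    b,
                )
    out = []
    for members in components.values():
        members = sorted(members)
        name = members[0] if len(members) == 1 else "+".join(members)
        out.append(FunctionalGroup(name=name, members=tuple(members)))
    return sorted(out, key=lambda fg: fg.name)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterTree:
    """A hierarchical clustering of standardised observations."""

    z: np.ndarray  # scipy linkage matrix
    data: np.ndarray  # (standardised) feature matrix used
    method: str

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def cut(self, k: int) -> np.ndarray:
        """Labels 1..k at a k-cluster cut."""
        return fcluster(self.z, t=k, criterion="maxclust")


@dataclass
class ClusterSolution:
    """A selected flat clustering with its quality metrics."""

    labels: np.ndarray
    k: int
    dunn: float
    linkage: str
    validation_accuracy: float | None = None
    low_dunn: bool = False
    dunn_by_k: dict[int, float] = field(default_factory=dict)


def hierarchical_cluster(data, method: str = "ward", standardize: bool = True) -> ClusterTree:
    """Ward (default) hierarchical clustering on Euclidean distances.

    Features are z-standardised by default so tracers on different scales
    contribute equally.  Deterministic: scipy's linkage breaks ties by
    observation order.
    """
    data = np.asarray(data, float)
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[0] < 3:
        raise MultivarError("need at least 3 observations to cluster")
    x = data
    if standardize:
        sd = x.std(axis=0, ddof=1)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    return ClusterTree(z=linkage(x, method=method), data=x, method=method)


def dunn_index(data, labels) -> float:
    """Dunn index: min between-cluster point distance / max cluster diameter.

    Singleton clusters have diameter 0; if every cluster is a singleton the
    index is infinite (degenerate).
    """
    data = np.asarray(data, float)
    if data.ndim == 1:
        data = data[:, None]
    labels = np.asarray(labels)
    d = squareform(pdist(data))
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise MultivarError("Dunn index needs at least 2 clusters")
    min_between = np.inf
    max_diam = 0.0
    for i, a in enumerate(uniq):
        ia = labels == a
        da = d[np.ix_(ia, ia)]
        if ia.sum() > 1:
            max_diam = max(max_diam, float(da.max()))
        for b in uniq[i + 1 :]:
            ib = labels == b
            min_between = min(min_between, float(d[np.ix_(ia, ib)].min()))
    if max_diam == 0.0:
        return np.inf
    return min_between / max_diam


def select_k_dunn(tree: ClusterTree, k_range=range(2, 7)) -> ClusterSolution:
    """Pick the cut with the largest Dunn index (ties → smallest k).

    All-singleton partitions give an infinite Dunn index and are excluded
    with a flag.  A best Dunn below 1 (clusters closer than they are wide)
    sets ``low_dunn`` and emits a warning rather than failing: the data may
    simply not be clustered.
    """
    ks = [k for k in k_range if 2 <= k <= tree.n - 1]
    if not ks:
        raise MultivarError(f"k_range {list(k_range)} outside [2, n-1] for n={tree.n}")
    scores: dict[int, float] = {}
    labels_by_k = {}
    for k in ks:
        labels = tree.cut(k)
        score = dunn_index(tree.data, labels)
        if np.isinf(score):
            warnings.warn(f"k={k}: all-singleton partition (infinite Dunn) excluded")
            continue
        scores[k] = score
        labels_by_k[k] = labels
    if not scores:
        raise MultivarError("no non-degenerate partition in k_range")
    best_k = min(scores, key=lambda k: (-scores[k], k))
    low = scores[best_k] < 1.0
    if low:
        warnings.warn(
            f"best Dunn index {scores[best_k]:.3f} < 1: weak cluster separation; "
            "the selected k is unreliable"
        )
    return ClusterSolution(
        labels=labels_by_k[best_k],
        k=best_k,
        dunn=scores[best_k],
        linkage=tree.method,
        low_dunn=low,
        dunn_by_k=scores,
    )


def lda_validate(data, labels, ridge: float = 1e-6) -> float:
    """Leave-one-out linear-discriminant classification accuracy in [0, 1].

    A singular within-class covariance (collinear or constant features) falls
    back to a ridge-regularised estimator with a logged epsilon.
    """
    data = np.asarray(data, float)
    if data.ndim == 1:
        data = data[:, None]
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise MultivarError("need at least 2 classes")
    if counts.min() < 2:
        raise MultivarError("every class needs at least 2 members")
    n = data.shape[0]
    correct = 0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        train_y = labels[mask]
        if len(np.unique(train_y)) < 2:
            continue
        clf = LinearDiscriminantAnalysis(solver="svd")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(data[mask], train_y)
        except np.linalg.LinAlgError:
            logger.info("singular within-class covariance; ridge eps=%g", ridge)
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=ridge)
            clf.fit(data[mask], train_y)
        correct += int(clf.predict(data[i][None, :])[0] == labels[i])
    return correct / n


def pearson_screen(data: pd.DataFrame, coords: np.ndarray, threshold: float = 0.6) -> pd.DataFrame:
    """Reporting helper: variables whose Pearson correlation with any
    ordination/cluster axis exceeds ``threshold`` in absolute value."""
    coords = np.asarray(coords, float)
    if coords.ndim == 1:
        coords = coords[:, None]
    rows = []
    for col in data.columns:
        x = data[col].to_numpy(float)
        if x.std() == 0:
            continue
        for ax in range(coords.shape[1]):
            y = coords[:, ax]
            if y.std() == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            if abs(r) >= threshold:
                rows.append({"variable": col, "axis": ax, "r": r})
    return pd.DataFrame(rows, columns=["variable", "axis", "r"])
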