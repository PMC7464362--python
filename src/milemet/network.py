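"""Consensus weighted correlation networks for metabolomics.

Implements, from first principles: signed soft-threshold adjacency on
Spearman correlations, the topological overlap matrix (TOM), consensus
dissimilarity across sex strata, average-linkage clustering with a
dynamic tree cut, module eigengenes (first right-singular vector of the
standardized module submatrix), kME membership scores, and a
connectivity-based outlier-sample screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .config import NetworkConfig

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def spearman_correlation(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Spearman rank correlation between columns (average ranks for ties)."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for rank correlations")
    if np.isnan(X).any():
        raise ValueError("missing values; preprocess the matrix first")
    constant = np.ptp(X, axis=0) == 0
    if constant.any():
        raise ValueError(f"constant metabolite columns at indices "
                         f"{np.flatnonzero(constant)[:5].tolist()}")
    ranks = np.apply_along_axis(rankdata, 0, X)
    rho = np.corrcoef(ranks, rowvar=False)
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def signed_adjacency(rho: np.ndarray, beta: float = 10.0) -> np.ndarray:
    """Signed weighted adjacency a_ij = ((1 + rho_ij) / 2) ** beta."""
    a = ((1.0 + np.asarray(rho, dtype=float)) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM: omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj over u != i, j and k_i = sum_u a_iu over u != i.

    Computed with matrix products (no triple loops); unit diagonal.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    omega = (l + a) / denom
    np.fill_diagonal(omega, 1.0)
    return omega


def tom_dissimilarity(omega: np.ndarray) -> np.ndarray:
    d = 1.0 - omega
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


def consensus_tom(tom_by_stratum: dict[str, np.ndarray],
                  calibration_quantile: float | None = 0.95) -> np.ndarray:
    """Element-wise minimum of (optionally quantile-calibrated) stratum TOMs.

    Calibration rescales each stratum's off-diagonal TOM so its configured
    quantile matches the across-strata mean of those quantiles, preventing
    one stratum's overall connectivity level from dominating the minimum.
    """
    toms = list(tom_by_stratum.values())
    if len(toms) < 2:
        raise ValueError("consensus requires at least 2 strata")
    shape = toms[0].shape
    if any(t.shape != shape for t in toms):
        raise ValueError("metabolite sets differ across strata")
    if calibration_quantile is not None:
        mask = ~np.eye(shape[0], dtype=bool)
        qs = np.array([np.quantile(t[mask], calibration_quantile)
                       for t in toms])
        ref = qs.mean()
        toms = [np.clip(t * (ref / q), 0.0, 1.0)
                for t, q in zip(toms, qs)]
        toms = [t + np.eye(shape[0]) * (1.0 - t.diagonal()) for t in toms]
    consensus = np.minimum.reduce(toms)
    np.fill_diagonal(consensus, 1.0)
    return consensus


def detect_outlier_samples(matrix: pd.DataFrame,
                           z_threshold: float = -2.5) -> pd.Index:
    """Flag samples with anomalously low standardized network connectivity.

    Connectivity is each sample's mean absolute correlation with its
    strongest decile of partner samples in the sample-sample correlation
    network.  On column-centred data a sample that does not participate in
    the shared correlation structure (e.g. a corrupted profile) has no
    strong partners at all, whereas even weakly-scoring genuine samples
    retain some; the tail mean separates the two far better than total
    connectivity.  Samples with standardized connectivity Z below
    ``z_threshold`` are flagged.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples for outlier detection")
    r = np.corrcoef(X)
    np.fill_diagonal(r, 0.0)
    n_top = max(5, int(0.1 * (n - 1)))
    k = np.sort(np.abs(r), axis=1)[:, -n_top:].mean(axis=1)
    z = (k - k.mean()) / k.std(ddof=1)
    flagged = matrix.index[z < z_threshold]
    if len(flagged):
        logger.info("outlier screen: flagged %d samples %s", len(flagged),
                    list(flagged))
    return flagged


def scale_free_fit_table(rho: np.ndarray,
                         powers=(1, 2, 4, 6, 8, 10, 12, 14)) -> pd.DataFrame:
    """Diagnostic R^2 of the log-log degree distribution per soft power.

    Reported for QC only; the pipeline fixes the power rather than choosing
    it automatically.
    """
    rows = []
    for beta in powers:
        a = signed_adjacency(rho, beta)
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        hist, edges = np.histogram(k, bins=10)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ok = (hist > 0) & (centers > 0)
        if ok.sum() < 3:
            rows.append((beta, np.nan, float(k.mean())))
            continue
        x, yv = np.log10(centers[ok]), np.log10(hist[ok])
        slope, intercept = np.polyfit(x, yv, 1)
        resid = yv - (slope * x + intercept)
        r2 = 1.0 - resid.var() / yv.var() if yv.var() > 0 else np.nan
        rows.append((beta, float(np.sign(-slope) * r2), float(k.mean())))
    return pd.DataFrame(rows, columns=["power", "sft_r2", "mean_connectivity"])


# ---------------------------------------------------------------------------
# dynamic tree cut
# ---------------------------------------------------------------------------

def _branches_below(node, cut):
    """Maximal subtrees whose merge height is <= cut."""
    out = []
    stack = [node]
    while stack:
        nd = stack.pop()
        if nd.is_leaf() or nd.dist <= cut:
            out.append(nd)
        else:
            stack.extend([nd.left, nd.right])
    return out


def _subtree_heights(node):
    heights = []
    stack = [node]
    while stack:
        nd = stack.pop()
        if not nd.is_leaf():
            heights.append(nd.dist)
            stack.extend([nd.left, nd.right])
    return np.asarray(heights)


def _cohesion(omega: np.ndarray, members: np.ndarray) -> float:
    """Median within-branch topological overlap over mean branch-to-rest
    overlap.  A coherent module is markedly more overlapping internally;
    the median makes a branch fail when a tight core is padded with loosely
    attached members (the majority of internal pairs must cohere)."""
    n = omega.shape[0]
    inside = np.zeros(n, dtype=bool)
    inside[members] = True
    if inside.all():
        return np.inf
    sub = omega[np.ix_(members, members)]
    within = np.median(sub[~np.eye(len(members), dtype=bool)])
    between = omega[np.ix_(members, ~inside)].mean()
    if between <= 0:
        return np.inf
    return float(within / between)


def _choose_cut(heights: np.ndarray, config: NetworkConfig) -> float:
    """Cut height for branch decomposition.

    'gap': midpoint of the largest jump between consecutive sorted merge
    heights, searched in the upper half of the merge order -- coherent
    branches complete well below the near-ceiling merges that attach
    background metabolites, and the largest gap separates the two regimes
    regardless of how many metabolites are in modules.
    'quantile': fixed quantile of the merge heights.
    """
    hs = np.sort(heights)
    if config.cut_method == "quantile" or hs.size < 3:
        return float(np.quantile(hs, config.cut_height_quantile))
    start = hs.size // 2
    gaps = np.diff(hs)[start - 1:]
    i = int(np.argmax(gaps)) + start - 1
    return float(0.5 * (hs[i] + hs[i + 1]))


def detect_modules(dissimilarity: np.ndarray,
                   config: NetworkConfig | None = None) -> np.ndarray:
    """Average-linkage clustering + dynamic tree cut on a TOM dissimilarity.

    The dendrogram is cut statically (largest-gap rule by default, see
    ``_choose_cut``); each branch is recursively decomposed at its own
    internal cut while the decomposition keeps producing at least two
    acceptable sub-branches.  A branch is accepted as a module when it has
    at least ``min_module_size`` members and its cohesion (median internal
    TOM over mean TOM to the rest of the network) exceeds
    ``min_cohesion``; everything else is unassigned (label 0).  Labels are
    contiguous 1..k in decreasing module size.
    """
    import sys

    config = config or NetworkConfig()
    config.validate()
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    labels = np.zeros(n, dtype=int)
    if n < config.min_module_size:
        return labels
    omega = 1.0 - d
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    root = hierarchy.to_tree(Z)

    def acceptable(members: np.ndarray) -> bool:
        return (len(members) >= config.min_module_size
                and _cohesion(omega, members) >= config.min_cohesion)

    def decompose(node) -> list[np.ndarray]:
        heights = _subtree_heights(node)
        if heights.size < 2:
            members = np.asarray(node.pre_order(lambda x: x.id))
            return [members] if acceptable(members) else []
        cut = _choose_cut(heights, config)
        branches = [b for b in _branches_below(node, cut) if b is not node]
        if not branches:
            members = np.asarray(node.pre_order(lambda x: x.id))
            return [members] if acceptable(members) else []
        clusters: list[np.ndarray] = []
        for branch in branches:
            members = np.asarray(branch.pre_order(lambda x: x.id))
            if len(members) < config.min_module_size:
                continue
            sub = decompose(branch)
            if len(sub) >= 2:
                clusters.extend(sub)
            elif acceptable(members):
                clusters.append(members)
            elif sub:
                clusters.extend(sub)
        return clusters

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * n + 1000))
    try:
        clusters = decompose(root)
    finally:
        sys.setrecursionlimit(old_limit)
    clusters.sort(key=lambda m: (-len(m), int(m.min())))
    for lbl, members in enumerate(clusters, start=1):
        labels[members] = lbl
    return labels


# ---------------------------------------------------------------------------
# eigengenes and membership
# ---------------------------------------------------------------------------

def module_eigengene(submatrix: np.ndarray) -> tuple[np.ndarray, float]:
    """First right-singular-vector summary of a sample x member matrix.

    Columns are z-scored, the first left-singular component gives the
    per-sample score, which is itself z-scored; returns (score, proportion
    of variance explained).  Sign is oriented so the mean correlation with
    the members is positive.
    """
    X = np.asarray(submatrix, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant member column in module submatrix")
    Xs = (X - mu) / sd
    u, s, _ = np.linalg.svd(Xs, full_matrices=False)
    score = u[:, 0]
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    score = (score - score.mean()) / score.std(ddof=1)
    kme = _columnwise_correlation(Xs, score)
    if kme.mean() < 0:
        score = -score
    return score, var_explained


def _columnwise_correlation(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=0) * (yc ** 2).sum())
    return (Xc.T @ yc) / denom


@dataclass
class EigengeneSet:
    """Per-stratum eigengene scores, variance explained, and kME table."""

    eigengenes: dict[str, pd.DataFrame]          # stratum -> samples x ME
    variance_explained: dict[str, dict[int, float]]
    kme: dict[str, pd.DataFrame]                 # stratum -> metabolites x ME


def eigengene_scores(matrix_by_stratum: dict[str, pd.DataFrame],
                     labels: np.ndarray) -> EigengeneSet:
    """Module eigengenes and all-metabolite kME per stratum.

    ``labels`` are module assignments over the (shared) metabolite columns;
    label 0 (unassigned) gets no eigengene.
    """
    modules = [m for m in sorted(set(labels)) if m != 0]
    eig, varex, kmes = {}, {}, {}
    for stratum, matrix in matrix_by_stratum.items():
        X = np.asarray(matrix, dtype=float)
        scores = {}
        varex[stratum] = {}
        for m in modules:
            members = np.flatnonzero(labels == m)
            score, ve = module_eigengene(X[:, members])
            scores[f"ME{m}"] = score
            varex[stratum][m] = ve
        eig[stratum] = pd.DataFrame(scores, index=matrix.index)
        # kME: correlation of every metabolite with every eigengene
        kme = pd.DataFrame(
            {f"ME{m}": _columnwise_correlation(X, scores[f"ME{m}"])
             for m in modules},
            index=matrix.columns)
        kmes[stratum] = kme
    return EigengeneSet(eigengenes=eig, variance_explained=varex, kme=kmes)


def membership_report(eigengenes: EigengeneSet, labels: np.ndarray,
                      meta: pd.DataFrame | None = None,
                      threshold: float = 0.6, top_n: int = 10
                      ) -> pd.DataFrame:
    """Rank metabolites by own-module kME per stratum.

    Returns rows for the union of the top ``top_n`` members and all
    metabolites with |kME| above ``threshold``, with pathway metadata
    attached when available.
    """
    rows = []
    meta_idx = (meta.set_index("metabolite_id")
                if meta is not None else None)
    for stratum, kme in eigengenes.kme.items():
        met_ids = kme.index.to_numpy()
        for m in sorted({l for l in labels if l != 0}):
            col = kme[f"ME{m}"]
            own = col[labels == m].sort_values(key=np.abs, ascending=False)
            selected = set(own.index[:top_n]) | set(
                own.index[np.abs(own) > threshold])
            for rank, mid in enumerate(own.index, start=1):
                if mid not in selected:
                    continue
                row = {"stratum": stratum, "module": m, "metabolite_id": mid,
                       "kme": float(col[mid]), "rank": rank,
                       "top10": rank <= top_n}
                if meta_idx is not None and mid in meta_idx.index:
                    row["super_pathway"] = meta_idx.loc[mid, "super_pathway"]
                    row["sub_pathway"] = meta_idx.loc[mid, "sub_pathway"]
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class ConsensusNetwork:
    """Consensus metabolite network estimator (scikit-learn style).

    ``fit(matrix, strata)`` takes a preprocessed sample x metabolite matrix
    and a per-sample stratum label series; it removes outlier samples,
    builds per-stratum signed-Spearman adjacencies at ``soft_power``,
    transforms to TOM, combines strata by calibrated element-wise minimum,
    clusters 1-TOM, cuts modules, and computes eigengenes and kME.

    Fitted attributes: ``labels_`` (module per metabolite, 0 = unassigned),
    ``eigengenes_`` (EigengeneSet), ``outliers_``, ``qc_``.
    """

    def __init__(self, config: NetworkConfig | None = None):
        self.config = config or NetworkConfig()

    def get_params(self, deep=True):
        return {"config": self.config}

    def set_params(self, **params):
        for key, val in params.items():
            setattr(self, key, val)
        return self

    def fit(self, matrix: pd.DataFrame, strata: pd.Series):
        self.config.validate()
        strata = strata.reindex(matrix.index)
        if strata.isna().any():
            raise ValueError("stratum labels missing for some samples")
        outliers = detect_outlier_samples(matrix,
                                          self.config.outlier_z_threshold)
        self.outliers_ = list(outliers)
        kept = matrix.drop(index=outliers)
        strata = strata.drop(index=outliers)

        toms, qc_sft = {}, {}
        for stratum in sorted(strata.unique()):
            sub = kept[strata == stratum]
            rho = spearman_correlation(sub)
            toms[stratum] = topological_overlap(
                signed_adjacency(rho, self.config.soft_power))
            qc_sft[stratum] = scale_free_fit_table(rho).to_dict("records")
        if len(toms) >= 2:
            omega = consensus_tom(toms, self.config.calibration_quantile)
        else:
            omega = next(iter(toms.values()))
        self.consensus_tom_ = omega
        self.labels_ = detect_modules(tom_dissimilarity(omega), self.config)
        self.module_labels_ = pd.Series(self.labels_, index=matrix.columns,
                                        name="module")
        self.eigengenes_ = eigengene_scores(
            {s: kept[strata == s] for s in sorted(strata.unique())},
            self.labels_)
        self.qc_ = {"outlier_samples": self.outliers_,
                    "n_modules": int(self.labels_.max()),
                    "n_unassigned": int((self.labels_ == 0).sum()),
                    "scale_free_fit": qc_sft}
        return self

    def fit_predict(self, matrix: pd.DataFrame, strata: pd.Series):
        return self.fit(matrix, strata).labels_
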