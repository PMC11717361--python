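"""Functional sub-type discovery.

Calcium path: per-stimulus sparse PCA compresses chirp and moving-bar
response averages into 30 interpretable features (20 chirp + 10 bar); the
sparsity penalty alpha is chosen so each component loads on one contiguous
piece of the stimulus (a localization score formalizes this). Cells are then
clustered with a full-covariance Gaussian mixture; the number of components
is selected by a cross-validated BIC whose likelihood term is the k-fold
mean held-out log-likelihood. MEA path: PCA features of z-scored PSTHs
(80% variance) plus two temporal-STA PCs and the normalized RF ellipse
area, clustered agglomeratively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA, SparsePCA
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import KFold

__all__ = [
    "FeatureMatrix",
    "ClusterModel",
    "CoherenceReport",
    "extract_sparse_features",
    "fit_mixture_select_k",
    "cluster_coherence",
    "mea_feature_vector",
    "agglomerative_cluster",
    "reclean_cluster",
]


@dataclass
class FeatureMatrix:
    """Cells x features matrix with provenance and standardization record."""

    X: np.ndarray
    provenance: list                    # (stimulus, component index) per column
    mean: np.ndarray | None = None      # per-feature, pre-standardization
    sd: np.ndarray | None = None
    standardized: bool = False
    alphas: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]


@dataclass
class ClusterModel:
    """Mixture fit across k with the selection curve and final labels."""

    k_range: tuple
    bic: dict                           # k -> cross-validated BIC
    chosen_k: int
    labels: np.ndarray
    sizes: np.ndarray
    seed: int
    discarded: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self):
        if self.labels.min() < 0 or self.labels.max() >= self.chosen_k:
            raise ValueError("labels out of range [0, chosen_k)")
        if int(self.sizes.sum()) != len(self.labels):
            raise ValueError("cluster sizes do not sum to n cells")


@dataclass
class CoherenceReport:
    """Intra- vs inter-cluster correlation diagnostics."""

    intra: dict                          # cluster -> mean r with own mean
    inter: dict                          # cluster -> mean r with other means
    coherent: bool
    excluded: tuple = ()


def _localization_score(components: np.ndarray) -> float:
    """Mean fraction of absolute loading mass in each component's dominant
    contiguous nonzero run."""
    scores = []
    for comp in components:
        mass = np.abs(comp)
        total = mass.sum()
        if total == 0:
            continue
        nz = mass > 0
        best = 0.0
        run_mass, in_run = 0.0, False
        for m, on in zip(mass, nz):
            if on:
                run_mass = run_mass + m if in_run else m
                in_run = True
                best = max(best, run_mass)
            else:
                in_run = False
        scores.append(best / total)
    return float(np.mean(scores)) if scores else 0.0


def _sparse_pca_features(traces: np.ndarray, n_components: int,
                         alpha_grid, seed: int):
    best = None
    for alpha in alpha_grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spca = SparsePCA(n_components=n_components, alpha=alpha,
                                 random_state=seed, max_iter=500)
                scores = spca.fit_transform(traces)
        except Exception:
            continue
        loc = _localization_score(spca.components_)
        if best is None or loc > best[0]:
            best = (loc, alpha, scores, spca.components_)
    if best is None:
        raise ValueError("sparse PCA failed to converge for every alpha")
    return best


def extract_sparse_features(chirp_means: np.ndarray, bar_means: np.ndarray,
                            n_chirp: int = 20, n_bar: int = 10,
                            alpha_grid=(0.5, 1.0, 2.0),
                            seed: int = 0) -> FeatureMatrix:
    """Sparse-PCA featurization of chirp + bar response averages.

    Per stimulus, the sparsity penalty is selected from ``alpha_grid`` by
    maximizing the localization score (see :func:`_localization_score`).
    Columns are standardized to mean 0 / sd 1 across cells.
    """
    chirp_means = np.asarray(chirp_means, float)
    bar_means = np.asarray(bar_means, float)
    if chirp_means.shape[0] < 2 or chirp_means.shape[0] != bar_means.shape[0]:
        raise ValueError("need >= 2 cells with both chirp and bar traces")
    loc_c, alpha_c, feats_c, _ = _sparse_pca_features(
        chirp_means, n_chirp, alpha_grid, seed)
    loc_b, alpha_b, feats_b, _ = _sparse_pca_features(
        bar_means, n_bar, alpha_grid, seed)
    X = np.hstack([feats_c, feats_b])
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd
    provenance = ([("chirp", i) for i in range(n_chirp)]
                  + [("bar", i) for i in range(n_bar)])
    return FeatureMatrix(X=Xs, provenance=provenance, mean=mean, sd=sd,
                         standardized=True,
                         alphas={"chirp": alpha_c, "bar": alpha_b,
                                 "loc_chirp": loc_c, "loc_bar": loc_b})


def _gmm_n_params(k: int, d: int) -> int:
    return (k - 1) + k * d + k * d * (d + 1) // 2


def fit_mixture_select_k(features, k_range=tuple(range(1, 7)),
                         n_folds: int = 10, n_init: int = 20,
                         seed: int = 0, cross_validate: bool = True,
                         reg_covar: float = 1e-6) -> ClusterModel:
    """Full-covariance Gaussian-mixture clustering with CV-BIC selection.

    For each k the selection score is a BIC whose log-likelihood term is the
    summed held-out log-likelihood from seeded k-fold cross-validation
    (plain training BIC with ``cross_validate=False``); the chosen k is the
    argmin, with ties within 1 BIC unit between adjacent k resolved toward
    the smaller k. Labels come from a refit on all data at the chosen k.
    """
    X = features.X if isinstance(features, FeatureMatrix) else np.asarray(features)
    n, d = X.shape
    if n <= max(k_range) * 3:
        raise ValueError("too few cells for the requested k range")
    bic = {}
    for k in k_range:
        try:
            if cross_validate:
                kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
                ll = 0.0
                for train, test in kf.split(X):
                    gm = GaussianMixture(n_components=k, covariance_type="full",
                                         n_init=n_init, random_state=seed,
                                         reg_covar=reg_covar)
                    gm.fit(X[train])
                    ll += float(gm.score_samples(X[test]).sum())
            else:
                gm = GaussianMixture(n_components=k, covariance_type="full",
                                     n_init=n_init, random_state=seed,
                                     reg_covar=reg_covar)
                gm.fit(X)
                ll = float(gm.score_samples(X).sum())
        except Exception as err:  # singular covariance etc.
            warnings.warn(f"k={k} skipped: {err}", stacklevel=2)
            continue
        bic[k] = -2.0 * ll + _gmm_n_params(k, d) * np.log(n)
    if not bic:
        raise ValueError("no k produced a valid mixture fit")
    chosen = min(bic, key=bic.get)
    while chosen - 1 in bic and bic[chosen - 1] - bic[chosen] < 1.0:
        chosen -= 1
    gm = GaussianMixture(n_components=chosen, covariance_type="full",
                         n_init=n_init, random_state=seed, reg_covar=reg_covar)
    labels = gm.fit_predict(X)
    sizes = np.bincount(labels, minlength=chosen)
    return ClusterModel(k_range=tuple(k_range), bic=bic, chosen_k=chosen,
                        labels=labels, sizes=sizes, seed=seed)


def cluster_coherence(traces: np.ndarray, labels: np.ndarray
                      ) -> CoherenceReport:
    """Mean member-vs-cluster-mean Pearson correlations, own vs other.

    The clustering is coherent iff every cluster's intra correlation exceeds
    its inter correlation. Size-1 clusters are excluded with a warning.
    """
    traces = np.asarray(traces, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    valid = [u for u in uniq if np.sum(labels == u) >= 2]
    excluded = tuple(u for u in uniq if u not in valid)
    if excluded:
        warnings.warn(f"clusters of size 1 excluded: {excluded}", stacklevel=2)
    if len(valid) < 2:
        raise ValueError("need at least 2 clusters of size >= 2")
    means = {u: traces[labels == u].mean(axis=0) for u in valid}

    def corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        return float(a @ b / denom) if denom > 0 else 0.0

    intra, inter = {}, {}
    for u in valid:
        members = traces[labels == u]
        intra[u] = float(np.mean([corr(m, means[u]) for m in members]))
        others = [corr(m, means[v]) for v in valid if v != u
                  for m in members]
        inter[u] = float(np.mean(others))
    coherent = all(intra[u] > inter[u] for u in valid)
    return CoherenceReport(intra=intra, inter=inter, coherent=coherent,
                           excluded=excluded)


def mea_feature_vector(psths: np.ndarray, temporal_stas: np.ndarray,
                       ellipse_areas: np.ndarray,
                       var_psth: float = 0.80) -> FeatureMatrix:
    """Per-cell MEA feature vector: PSTH PCs (>= 80% variance), 2 temporal
    STA PCs, and the [0, 1]-normalized RF ellipse area (~15 columns)."""
    psths = np.asarray(psths, float)
    temporal_stas = np.asarray(temporal_stas, float)
    ellipse_areas = np.asarray(ellipse_areas, float)
    n = psths.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells")

    def zscore_rows(M):
        mu = M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (M - mu) / sd

    z_psth = zscore_rows(psths)
    pca_p = PCA(n_components=min(n - 1, z_psth.shape[1])).fit(z_psth)
    n_keep = int(np.searchsorted(np.cumsum(pca_p.explained_variance_ratio_),
                                 var_psth) + 1)
    psth_pcs = pca_p.transform(z_psth)[:, :n_keep]

    z_sta = zscore_rows(temporal_stas)
    sta_pcs = PCA(n_components=2).fit_transform(z_sta)

    rng_area = ellipse_areas.max() - ellipse_areas.min()
    area = ((ellipse_areas - ellipse_areas.min()) / rng_area
            if rng_area > 0 else np.zeros(n))

    X = np.hstack([psth_pcs, sta_pcs, area[:, None]])
    provenance = ([("psth_pc", i) for i in range(n_keep)]
                  + [("sta_pc", i) for i in range(2)]
                  + [("ellipse_area", 0)])
    return FeatureMatrix(X=X, provenance=provenance, standardized=False)


def agglomerative_cluster(features, distance: str = "correlation",
                          linkage: str = "average",
                          threshold: float = 0.5) -> np.ndarray:
    """Flat agglomerative clusters by cutting the dendrogram at a threshold.

    Deterministic; returns 0-based labels.
    """
    X = features.X if isinstance(features, FeatureMatrix) else np.asarray(features)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    d = pdist(X, metric=distance)
    Z = scipy_linkage(d, method=linkage)
    return fcluster(Z, t=threshold, criterion="distance") - 1


def reclean_cluster(traces: np.ndarray, labels: np.ndarray, cluster: int,
                    n_sub: int = 3, coherence_min: float = 0.5,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Optional second-stage cleanup: re-cluster one cluster and discard
    incoherent sub-clusters.

    Members of ``cluster`` are re-fit with an ``n_sub``-component mixture on
    their traces' top PCs; sub-clusters whose mean member-vs-mean
    correlation falls below ``coherence_min`` are discarded. Returns the
    updated labels (discarded cells set to -1) and the discarded indices.
    This step runs after model selection and never alters the chosen k.
    """
    traces = np.asarray(traces, float)
    labels = np.asarray(labels).copy()
    idx = np.where(labels == cluster)[0]
    if len(idx) < n_sub * 2:
        return labels, np.array([], int)
    sub_X = PCA(n_components=min(5, len(idx) - 1)).fit_transform(traces[idx])
    gm = GaussianMixture(n_components=n_sub, random_state=seed, n_init=10)
    sub = gm.fit_predict(sub_X)
    discarded = []
    for u in range(n_sub):
        members = traces[idx[sub == u]]
        if len(members) == 0:
            continue
        mean = members.mean(axis=0)
        rs = []
        for m in members:
            a, b = m - m.mean(), mean - mean.mean()
            denom = np.linalg.norm(a) * np.linalg.norm(b)
            rs.append(a @ b / denom if denom > 0 else 0.0)
        if float(np.mean(rs)) < coherence_min:
            discarded.extend(idx[sub == u].tolist())
    discarded = np.asarray(sorted(discarded), int)
    labels[discarded] = -1
    return labels, discarded
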