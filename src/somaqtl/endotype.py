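"""Proteome-based endotype discovery and clinical prediction.

The stratification chain for idiopathic patients: residualize the proteome
on age, sex and study center; build a weighted co-expression network
(adjacency = |Pearson correlation|^power, unsigned topological overlap);
detect modules by average-linkage clustering of the TOM dissimilarity with
a static height cut and a minimum module size; consensus-cluster patients
on the module analytes over subsampled replicates; characterize the
endotypes clinically (chi-squared / covariate-adjusted GLM / Mann-Whitney);
and train a cost-complexity-pruned CART predicting endotype from clinical
variables alone, with 10-fold cross-validated pruning on a 70% training
split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import average, cut_tree, fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier, export_text

from .datatypes import ProteinMatrix

__all__ = [
    "NetworkConfig", "residualize", "pick_soft_threshold", "tom_similarity",
    "detect_modules", "consensus_cluster", "ConsensusResult",
    "compare_endotypes_clinical", "protein_score", "train_endotype_tree",
    "EndotypeTree", "EndotypeModel", "EndotypeResults",
]

#: at full aptamer-panel scale (~4785 analytes) the minimum module size is
#: 500; synthetic runs scale it with the analyte count.
FULL_PANEL_MIN_MODULE = 500


@dataclass(frozen=True)
class NetworkConfig:
    """Weighted-network parameters (unsigned, Pearson, soft threshold 11).

    ``cut_height`` is the static dendrogram cut on the 1 - TOM scale; the
    default (None) scans the merge heights and places the cut in the middle
    of the widest height interval that maximizes the number of clusters of
    at least the minimum module size (final all-merging cut excluded), so
    tight modules separate from the near-unit-dissimilarity background
    without tuning.
    """

    power: float = 11.0
    min_module_size: int | None = None    # None: max(30, 0.12 * n_analytes)
    cut_height: float | None = None

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if self.min_module_size is not None and self.min_module_size < 2:
            raise ValueError("min module size must be >= 2")

    def resolved_min_size(self, n_analytes: int) -> int:
        if self.min_module_size is not None:
            return self.min_module_size
        return max(30, int(round(0.12 * n_analytes)))


def residualize(proteins: ProteinMatrix | pd.DataFrame,
                covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-analyte OLS residuals on age, sex and center (mean-zero columns).

    ``covariates`` needs columns ``age, sex, center``; center enters as a
    factor.  Samples with missing covariates are dropped with a warning.
    """
    values = proteins.values if isinstance(proteins, ProteinMatrix) else proteins
    cov = covariates.loc[values.index]
    ok = cov[["age", "sex", "center"]].notna().all(axis=1)
    if not ok.all():
        warnings.warn(f"dropping {(~ok).sum()} samples with missing covariates",
                      stacklevel=2)
        values, cov = values.loc[ok], cov.loc[ok]
    X = pd.concat([
        pd.Series(1.0, index=cov.index, name="intercept"),
        cov["age"].astype(float), cov["sex"].astype(float),
        pd.get_dummies(cov["center"], prefix="center", drop_first=True).astype(float),
    ], axis=1).to_numpy()
    Y = values.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return pd.DataFrame(resid, index=values.index, columns=values.columns)


def _adjacency(residuals: pd.DataFrame | np.ndarray, power: float) -> np.ndarray:
    R = np.corrcoef(np.asarray(residuals, dtype=float), rowvar=False)
    if np.isnan(R).any():
        const = np.where(np.isnan(R).all(axis=0))[0]
        raise ValueError(f"constant analytes at positions {list(const)}")
    A = np.abs(R) ** power
    np.fill_diagonal(A, 0.0)
    return A


def pick_soft_threshold(residuals: pd.DataFrame, powers=(1, 3, 5, 7, 9, 11, 13, 15),
                        n_bins: int = 10) -> pd.DataFrame:
    """Scale-free-topology fit per candidate power.

    For each power, the connectivity ``k_i = sum_u a_iu`` is binned into
    ``n_bins`` equal-occupancy (quantile) bins; the R^2 of the
    ``log10 p(k) ~ log10 k`` regression over the occupied bins (density
    corrected for bin width) is reported alongside the mean connectivity
    and the fitted slope (negative for scale-free-like topologies).
    Powers whose connectivity distribution has fewer than ``n_bins``
    distinct values yield fewer than ``n_bins`` occupied bins and are
    flagged unfit.
    """
    if residuals.shape[1] < 20:
        raise ValueError("need at least 20 analytes")
    rows = []
    for power in powers:
        A = _adjacency(residuals, power)
        k_all = A.sum(axis=0)
        entry = {"power": power, "mean_k": k_all.mean(), "r2": np.nan,
                 "slope": np.nan, "fit_ok": False}
        k = k_all[k_all > 0]
        if np.unique(k).size >= n_bins:
            edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
            edges[-1] += 1e-9
            idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
            xs, ys = [], []
            for b in range(n_bins):
                kk = k[idx == b]
                width = edges[b + 1] - edges[b]
                if kk.size and width > 0:
                    xs.append(np.log10(kk.mean()))
                    ys.append(np.log10(kk.size / (k.size * width)))
            if len(xs) >= n_bins:
                sl, _, r, *_ = stats.linregress(xs, ys)
                entry.update(r2=r**2, slope=sl, fit_ok=True)
        rows.append(entry)
    return pd.DataFrame(rows)


def tom_similarity(residuals: pd.DataFrame | np.ndarray,
                   config: NetworkConfig = NetworkConfig()) -> np.ndarray:
    """Unsigned topological overlap matrix.

    ``a_ij = |cor|^power`` (diagonal zero); ``TOM_ij = (sum_u a_iu a_uj +
    a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with unit diagonal; entries lie
    in [0, 1].
    """
    A = _adjacency(residuals, config.power)
    k = A.sum(axis=0)
    num = A @ A + A
    den = np.minimum.outer(k, k) + 1.0 - A
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(tom: np.ndarray, config: NetworkConfig = NetworkConfig(),
                   analyte_ids=None) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters smaller than the minimum module size dissolve to label 0
    ("unassigned"); surviving modules are renumbered 1, 2, ... by
    decreasing size.
    """
    n = tom.shape[0]
    ids = analyte_ids if analyte_ids is not None else pd.RangeIndex(n)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    Z = average(squareform(diss, checks=False))
    min_size = config.resolved_min_size(n)
    if config.cut_height is not None:
        height = config.cut_height
    else:
        hs = np.unique(Z[:, 2])
        mids = 0.5 * (hs[:-1] + hs[1:])       # candidate cuts between merges
        if mids.size == 0:
            height = hs[-1]
        else:
            counts = np.array([
                int((pd.Series(fcluster(Z, t=h, criterion="distance"))
                     .value_counts() >= min_size).sum()) for h in mids])
            best = counts.max()
            ok = counts == best
            # widest contiguous plateau of best cuts, take its midpoint
            runs, start = [], None
            for i, flag in enumerate(ok):
                if flag and start is None:
                    start = i
                if (not flag or i == len(ok) - 1) and start is not None:
                    end = i if flag else i - 1
                    runs.append((hs[end + 1] - hs[start], start, end))
                    start = None
            _, s, e = max(runs)
            height = 0.5 * (hs[s] + hs[e + 1])
    raw = fcluster(Z, t=height, criterion="distance")
    counts = pd.Series(raw).value_counts()
    big = counts[counts >= min_size].index
    order = {lab: i + 1 for i, lab in
             enumerate(sorted(big, key=lambda lb: -counts[lb]))}
    labels = np.array([order.get(lb, 0) for lb in raw])
    if (labels == 0).all():
        warnings.warn("no module reached the minimum size; all unassigned",
                      stacklevel=2)
    return pd.Series(labels, index=ids, name="module")


@dataclass
class ConsensusResult:
    """Consensus-clustering output across k = 2..k_max."""

    consensus: dict[int, np.ndarray]     # per-k consensus matrices
    labels: dict[int, np.ndarray]        # per-k final labels (1-based)
    cdf_area: pd.DataFrame               # per-k area and delta-area
    chosen_k: int
    sample_ids: pd.Index

    def tracking(self) -> pd.DataFrame:
        """Patient assignments across k (the tracking-plot table)."""
        return pd.DataFrame({f"k={k}": v for k, v in self.labels.items()},
                            index=self.sample_ids)


def _hclust_labels(X: np.ndarray, k: int, method: str = "ward") -> np.ndarray:
    Z = linkage(pdist(X, metric="euclidean"), method=method)
    return cut_tree(Z, n_clusters=k).ravel() + 1


def consensus_cluster(
    features: pd.DataFrame,
    k_max: int = 6,
    n_reps: int = 100,
    subsample: float = 0.8,
    seed: int | np.random.Generator = 0,
    method: str = "ward",
) -> ConsensusResult:
    """Subsampled consensus clustering (hierarchical, Euclidean).

    For each replicate a fraction of patients is subsampled and clustered
    into k groups with agglomerative linkage (``method``, Ward by default;
    ``"average"`` available); ``consensus_ij`` = co-clustered count /
    co-sampled count.  Final per-k labels come from average-linkage
    clustering of 1 - consensus; the chosen k maximizes the delta-area of
    the consensus CDF.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    n = len(features)
    if n < 2 * k_max:
        raise ValueError("need at least 2*k_max patients")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(features, dtype=float)
    m_sub = max(int(round(subsample * n)), k_max)

    idx_sets = [rng.choice(n, size=m_sub, replace=False) for _ in range(n_reps)]
    co_sampled = np.zeros((n, n))
    for idx in idx_sets:
        co_sampled[np.ix_(idx, idx)] += 1

    consensus, labels = {}, {}
    areas = []
    triu = np.triu_indices(n, k=1)
    for k in range(2, k_max + 1):
        co_clust = np.zeros((n, n))
        for idx in idx_sets:
            lab = _hclust_labels(X[idx], k, method)
            same = lab[:, None] == lab[None, :]
            co_clust[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(co_sampled > 0, co_clust / np.maximum(co_sampled, 1), 0.0)
        np.fill_diagonal(M, 1.0)
        M = 0.5 * (M + M.T)
        consensus[k] = M
        Zf = average(squareform(1.0 - M, checks=False))
        labels[k] = cut_tree(Zf, n_clusters=k).ravel() + 1
        vals = np.sort(M[triu])
        cdf_x = np.concatenate([[0.0], vals, [1.0]])
        cdf_y = np.concatenate([[0.0], np.arange(1, vals.size + 1) / vals.size, [1.0]])
        areas.append(np.trapezoid(cdf_y, cdf_x))

    ks = list(range(2, k_max + 1))
    delta = [areas[0]]
    for i in range(1, len(areas)):
        delta.append((areas[i] - areas[i - 1]) / areas[i - 1])
    cdf_area = pd.DataFrame({"k": ks, "area": areas, "delta_area": delta})
    chosen = int(cdf_area.loc[cdf_area["delta_area"].idxmax(), "k"])
    index = features.index if isinstance(features, pd.DataFrame) else pd.RangeIndex(n)
    return ConsensusResult(consensus, labels, cdf_area, chosen, index)


def compare_endotypes_clinical(
    labels: pd.Series,
    clinical: pd.DataFrame,
    categorical: tuple[str, ...] = ("sex",),
    quantitative: tuple[str, ...] = ("ptau", "abeta", "total_tau", "asyn",
                                     "updrs1", "moca"),
) -> pd.DataFrame:
    """Per-variable endotype comparison.

    Categorical variables: two-sided chi-squared (exact fallback when an
    expected count drops below 1).  Quantitative variables: Gaussian GLM of
    the variable on endotype + age + sex, endotype coefficient tested.
    Age: two-sided Mann-Whitney U.  Directions are endotype-2 minus
    endotype-1 effects.
    """
    lab = labels.loc[clinical.index]
    groups = sorted(lab.unique())
    if len(groups) < 2 or any((lab == g).sum() < 5 for g in groups):
        raise ValueError("need >= 2 endotypes with >= 5 patients each")
    e2 = (lab == groups[-1]).astype(float)
    rows = []

    a1 = clinical.loc[e2 == 0, "age"]
    a2 = clinical.loc[e2 == 1, "age"]
    u, p = stats.mannwhitneyu(a2, a1, alternative="two-sided")
    rows.append({"variable": "age", "test": "mannwhitney", "p": p,
                 "effect": a2.median() - a1.median()})

    for var in categorical:
        if var not in clinical:
            continue
        ct = pd.crosstab(lab, clinical[var])
        chi2, p, dof, expected = stats.chi2_contingency(ct)
        note = ""
        if (expected < 1).any() and ct.shape == (2, 2):
            _, p = stats.fisher_exact(ct)
            note = "fisher-exact fallback"
        rows.append({"variable": var, "test": "chi2", "p": p,
                     "effect": np.nan, "note": note})

    for var in quantitative:
        if var not in clinical:
            continue
        X = sm.add_constant(pd.DataFrame({
            "endotype2": e2,
            "age": clinical["age"].astype(float),
            "sex": clinical["sex"].astype(float),
        }))
        fit = sm.GLM(clinical[var].astype(float), X).fit()
        rows.append({"variable": var, "test": "glm", "p": fit.pvalues["endotype2"],
                     "effect": fit.params["endotype2"]})
    out = pd.DataFrame(rows)
    out["direction"] = np.where(out["effect"] > 0, "higher for endotype 2",
                                np.where(out["effect"] < 0,
                                         "lower for endotype 2", ""))
    return out


def protein_score(weights: dict[str, float] | pd.Series,
                  proteins: ProteinMatrix | pd.DataFrame) -> pd.Series:
    """Linear protein score per sample (weights supplied externally)."""
    w = pd.Series(weights, dtype=float)
    if w.empty:
        raise ValueError("empty weight set")
    values = proteins.values if isinstance(proteins, ProteinMatrix) else proteins
    missing = w.index.difference(values.columns)
    if len(missing):
        raise ValueError(f"weighted analytes missing from matrix: {list(missing)}")
    return values.loc[:, w.index] @ w


@dataclass
class EndotypeTree:
    """Pruned partition tree predicting endotype from clinical variables."""

    tree: DecisionTreeClassifier
    features: list[str]
    ccp_alpha: float
    cv_errors: pd.DataFrame
    train_idx: np.ndarray
    test_idx: np.ndarray
    train_accuracy: float
    test_accuracy: float
    test_auc: float
    full_tree_cv_error: float = np.nan
    chosen_cv_error: float = np.nan

    @property
    def n_splits(self) -> int:
        return int((self.tree.tree_.children_left >= 0).sum())

    def root_split(self) -> tuple[str, float] | None:
        """Variable and threshold of the root split (None for a stump)."""
        t = self.tree.tree_
        if t.children_left[0] < 0:
            return None
        return self.features[t.feature[0]], float(t.threshold[0])

    def as_text(self) -> str:
        return export_text(self.tree, feature_names=self.features)

    def as_dict(self, node: int = 0) -> dict:
        t = self.tree.tree_
        if t.children_left[node] < 0:
            cls = int(np.argmax(t.value[node]))
            return {"leaf": True, "class": self.tree.classes_[cls].item(),
                    "n": int(t.n_node_samples[node])}
        return {
            "leaf": False,
            "variable": self.features[t.feature[node]],
            "threshold": float(t.threshold[node]),
            "left": self.as_dict(t.children_left[node]),
            "right": self.as_dict(t.children_right[node]),
        }


def train_endotype_tree(
    clinical: pd.DataFrame,
    labels: pd.Series,
    features: tuple[str, ...] = ("ptau", "abeta", "total_tau", "asyn",
                                 "updrs1", "moca", "age", "sex"),
    train_frac: float = 0.7,
    cv_folds: int = 10,
    seed: int = 0,
    one_se_rule: bool = True,
) -> EndotypeTree:
    """CART with cost-complexity pruning chosen by 10-fold cross-validation.

    Stratified ``train_frac``/(1 - train_frac) split; the pruning strength
    is, by default, the largest alpha whose CV misclassification error lies
    within one standard error of the minimum (the conventional 1-SE rule,
    which prunes label-independent predictors back to the root);
    ``one_se_rule=False`` takes the strict CV minimum.  Reports train/test
    accuracy and the test AUC from leaf class-probability scores.
    """
    feats = [f for f in features if f in clinical.columns]
    X = clinical.loc[labels.index, feats].to_numpy(dtype=float)
    y = labels.to_numpy()
    if len(np.unique(y)) < 2:
        warnings.warn("single-class labels: returning a no-split tree", stacklevel=2)
        stump = DecisionTreeClassifier(max_depth=1).fit(X, y)
        idx = np.arange(len(y))
        return EndotypeTree(stump, feats, 0.0, pd.DataFrame(), idx, idx,
                            1.0, 1.0, np.nan)
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, train_size=train_frac, stratify=y,
                              random_state=seed)
    path = DecisionTreeClassifier(criterion="gini", random_state=seed) \
        .cost_complexity_pruning_path(X[tr], y[tr])
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X[tr], y[tr]))
    err = np.zeros((len(alphas), cv_folds))
    for ai, alpha in enumerate(alphas):
        for fi, (ftr, fte) in enumerate(folds):
            clf = DecisionTreeClassifier(criterion="gini", ccp_alpha=alpha,
                                         random_state=seed)
            clf.fit(X[tr][ftr], y[tr][ftr])
            err[ai, fi] = 1.0 - clf.score(X[tr][fte], y[tr][fte])
    mean_err = err.mean(axis=1)
    se_err = err.std(axis=1, ddof=1) / np.sqrt(cv_folds)
    best = int(np.argmin(mean_err))
    if one_se_rule:
        within = mean_err <= mean_err[best] + se_err[best]
        best = int(np.max(np.flatnonzero(within)))
    alpha = float(alphas[best])

    tree = DecisionTreeClassifier(criterion="gini", ccp_alpha=alpha,
                                  random_state=seed).fit(X[tr], y[tr])
    train_acc = tree.score(X[tr], y[tr])
    test_acc = tree.score(X[te], y[te])
    proba = tree.predict_proba(X[te])
    if proba.shape[1] == 2 and len(np.unique(y[te])) == 2:
        auc = roc_auc_score(y[te] == tree.classes_[1], proba[:, 1])
    else:
        auc = np.nan
    cv_tab = pd.DataFrame({"ccp_alpha": alphas, "cv_error": mean_err,
                           "cv_se": se_err})
    return EndotypeTree(tree, feats, alpha, cv_tab, tr, te,
                        float(train_acc), float(test_acc), float(auc),
                        full_tree_cv_error=float(mean_err[0]),
                        chosen_cv_error=float(mean_err[best]))


@dataclass
class EndotypeResults:
    """Everything the stratification pipeline produces."""

    residuals: pd.DataFrame
    tom: np.ndarray
    modules: pd.Series
    consensus: ConsensusResult
    labels: pd.Series
    clinical_comparison: pd.DataFrame | None = None
    tree: EndotypeTree | None = None

    def summary(self) -> pd.DataFrame:
        sizes = self.labels.value_counts().sort_index()
        mod_sizes = self.modules[self.modules > 0].value_counts().sort_index()
        return pd.DataFrame({
            "n_patients": [len(self.labels)],
            "n_modules": [int(mod_sizes.size)],
            "module_sizes": [list(mod_sizes)],
            "chosen_k": [self.consensus.chosen_k],
            "endotype_sizes": [list(sizes)],
            "tree_test_accuracy": [self.tree.test_accuracy if self.tree else np.nan],
            "tree_test_auc": [self.tree.test_auc if self.tree else np.nan],
        })


class EndotypeModel:
    """Hypothesis-free stratification of idiopathic patients.

    ``proteins``/``meta`` should already be restricted to the idiopathic
    patient subset; ``fit`` runs residualization, TOM module detection,
    consensus clustering on the module analytes (k fixed to ``k_use``,
    default 2, for downstream steps), clinical characterization and the
    clinical partition tree.
    """

    def __init__(self, proteins: ProteinMatrix, meta: pd.DataFrame,
                 network: NetworkConfig = NetworkConfig(), k_max: int = 6,
                 k_use: int = 2, n_reps: int = 100, subsample: float = 0.8,
                 linkage_method: str = "ward", fit_tree: bool = True):
        self.proteins = proteins
        self.meta = meta.loc[proteins.sample_ids]
        self.network = network
        self.k_max = k_max
        self.k_use = k_use
        self.n_reps = n_reps
        self.subsample = subsample
        self.linkage_method = linkage_method
        self.fit_tree = fit_tree

    def fit(self, seed: int = 0) -> EndotypeResults:
        resid = residualize(self.proteins, self.meta)
        tom = tom_similarity(resid, self.network)
        modules = detect_modules(tom, self.network, resid.columns)
        in_module = modules.index[modules > 0]
        feats = resid.loc[:, in_module] if len(in_module) else resid
        # z-score module analytes so no single analyte dominates the metric
        feats = (feats - feats.mean()) / feats.std(ddof=0).replace(0.0, 1.0)
        cons = consensus_cluster(feats, self.k_max, self.n_reps,
                                 self.subsample, np.random.default_rng(seed),
                                 self.linkage_method)
        labels = pd.Series(cons.labels[self.k_use], index=resid.index,
                           name="endotype")
        clin = None
        tree = None
        if self.fit_tree:
            try:
                clin = compare_endotypes_clinical(labels, self.meta)
            except (ValueError, KeyError):
                clin = None
            try:
                tree = train_endotype_tree(self.meta, labels, seed=seed)
            except (ValueError, KeyError):
                tree = None
        return EndotypeResults(resid, tom, modules, cons, labels, clin, tree)
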