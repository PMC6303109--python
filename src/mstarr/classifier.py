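"""Random-forest classification of MD versus non-MD enhancers.

The classifier contrasts methylation-suppressed MD enhancers against
enhancers with strong evidence *against* methylation dependence
(interaction q-value above a floor, 0.5 by default). The forest is grown
as explicit bagging over decision trees so that each tree's out-of-bag
(OOB) rows are known: OOB votes give an unbiased accuracy estimate, and
permutation of each feature within the OOB rows yields the mean decrease
in accuracy (MDA). Feature significance is assessed empirically by
re-running the whole forest on label-permuted data and comparing observed
MDA and Gini importances against the permutation distributions; a feature
is significant only if both measures pass the empirical FDR threshold.

Rows and columns are canonicalized (sorted by content/name) before any
random draw, so OOB results depend on the data, not on its ordering.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .core import ConfigurationError, rng_for
from .fdr import storey_qvalue

MD = "MD"
NON_MD = "non-MD"
UNCLASSIFIED = "unclassified"


def build_training_set(results_frame: pd.DataFrame, features: pd.DataFrame,
                       nonmd_q_floor: float = 0.5) -> pd.DataFrame:
    """Assemble the labelled, complete-case classifier table.

    The MD class is restricted to MD enhancers more active when
    unmethylated (the methylation-suppressed class); the non-MD class is
    enhancers whose interaction q-value exceeds ``nonmd_q_floor`` (strong
    evidence against methylation dependence). Rows with any missing
    feature are dropped; pre- and post-removal class counts are stored in
    ``.attrs``.
    """
    res = results_frame
    md_rows = res.index[(res["is_md"]) & (res["md_direction"] == "unmeth_higher")]
    non_rows = res.index[(res["is_enhancer"]) & (res["q_txc"] > nonmd_q_floor)]
    feat_cols = [c for c in features.columns if c != "is_md"]
    table = features.loc[features.index.intersection(md_rows.union(non_rows)), feat_cols].copy()
    labels = pd.Series(NON_MD, index=table.index, name="label")
    labels[table.index.isin(md_rows)] = MD
    pre_counts = labels.value_counts().to_dict()
    complete = table.notna().all(axis=1)
    table, labels = table[complete], labels[complete]
    post_counts = labels.value_counts().to_dict()
    for cls in (MD, NON_MD):
        if post_counts.get(cls, 0) < 10:
            raise ConfigurationError(
                f"class {cls!r} has {post_counts.get(cls, 0)} rows (< 10)")
    out = table.copy()
    out.insert(0, "label", labels)
    out.attrs["pre_removal_counts"] = pre_counts
    out.attrs["post_removal_counts"] = post_counts
    return out


@dataclass
class ForestModel:
    """A bagged classification forest with per-tree OOB bookkeeping."""

    trees: list
    inbag: list                 # per-tree bootstrap row indices (canonical order)
    oob_votes: pd.DataFrame     # per-row vote fractions for the MD class
    oob_accuracy: float
    classes: tuple
    feature_names: list
    row_order: np.ndarray       # canonical order -> original position
    X: np.ndarray               # canonicalized feature matrix
    y: np.ndarray               # canonicalized 0/1 labels


def _canonicalize(table: pd.DataFrame):
    feat_cols = sorted(c for c in table.columns if c != "label")
    X = table[feat_cols].to_numpy(dtype=float)
    y = (table["label"].to_numpy() == MD).astype(int)
    # sort rows lexicographically by feature content then label
    order = np.lexsort(tuple(X[:, j] for j in reversed(range(X.shape[1]))) + (y,))
    return X[order], y[order], feat_cols, order


def train_rf(table: pd.DataFrame, n_trees: int = 1000, seed: int = 0) -> ForestModel:
    """Grow a bagging forest and collect out-of-bag votes.

    Each tree trains on a bootstrap sample of the rows (about 2/3 unique);
    the held-out third votes out-of-bag. mtry = floor(sqrt(#features)),
    minimum node size 1, no class weighting.
    """
    if table["label"].nunique() < 2:
        raise ConfigurationError("training table has a single class")
    X, y, feat_cols, order = _canonicalize(table)
    n, F = X.shape
    mtry = max(1, int(np.floor(np.sqrt(F))))
    rng = rng_for(seed, "rf")
    trees, inbag = [], []
    votes = np.zeros(n)
    n_votes = np.zeros(n)
    for t in range(n_trees):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(
            max_features=mtry, min_samples_leaf=1,
            random_state=int(rng.integers(0, 2**31 - 1)))
        tree.fit(X[idx], y[idx])
        oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        if oob.size:
            pred = tree.predict(X[oob])
            votes[oob] += pred
            n_votes[oob] += 1
        trees.append(tree)
        inbag.append(idx)
    with np.errstate(invalid="ignore"):
        frac = votes / n_votes
    voted = n_votes > 0
    oob_pred = (frac > 0.5).astype(int)
    acc = float((oob_pred[voted] == y[voted]).mean())
    # map votes back to the original row order
    frame = pd.DataFrame({"vote_md": frac}, index=table.index[order])
    frame = frame.loc[table.index]
    return ForestModel(trees=trees, inbag=inbag, oob_votes=frame,
                       oob_accuracy=acc, classes=(NON_MD, MD),
                       feature_names=feat_cols, row_order=order, X=X, y=y)


def classify(votes, threshold: float = 0.5) -> pd.Series:
    """Majority vote with an explicit tie marker at exactly the threshold."""
    v = votes["vote_md"] if isinstance(votes, pd.DataFrame) else pd.Series(votes)
    out = pd.Series(UNCLASSIFIED, index=v.index, dtype=object, name="predicted")
    out[v > threshold] = MD
    out[(1.0 - v) > threshold] = NON_MD
    return out


def vote_tradeoff(votes: pd.DataFrame, truth: pd.Series,
                  thresholds=None) -> pd.DataFrame:
    """True/false positive rates over a sweep of vote thresholds."""
    if thresholds is None:
        thresholds = np.round(np.arange(0.05, 0.96, 0.05), 2)
    y = (truth == MD).to_numpy() if truth.dtype == object else truth.to_numpy(bool)
    v = votes["vote_md"].to_numpy()
    rows = []
    for thr in thresholds:
        pred = v > thr
        tp = (pred & y).sum()
        fp = (pred & ~y).sum()
        rows.append({"threshold": thr,
                     "tpr": tp / max(y.sum(), 1),
                     "fpr": fp / max((~y).sum(), 1)})
    return pd.DataFrame(rows)


def _tree_predict(tree, X32: np.ndarray) -> np.ndarray:
    """Class predictions via the fitted tree structure (no re-validation)."""
    proba = tree.tree_.predict(X32)
    proba = proba.reshape(proba.shape[0], -1)
    return tree.classes_[np.argmax(proba, axis=1)]


def _forest_importances(model: ForestModel, rng: np.random.Generator):
    """randomForest-style importances: scaled MDA and mean Gini decrease."""
    X, y = model.X, model.y
    n, F = X.shape
    n_trees = len(model.trees)
    diffs = np.zeros((n_trees, F))
    gini = np.zeros(F)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    for t, (tree, idx) in enumerate(zip(model.trees, model.inbag)):
        oob = np.setdiff1d(np.arange(n), idx)
        gini += tree.feature_importances_
        if oob.size == 0:
            continue
        Xo = X32[oob]
        yo = y[oob]
        base = (_tree_predict(tree, Xo) == yo).mean()
        used = np.unique(tree.tree_.feature)
        Xp = Xo.copy()
        for f in range(F):
            if f not in used:
                diffs[t, f] = 0.0  # feature unused by this tree
                continue
            perm = rng.permutation(oob.size)
            Xp[:, f] = Xo[perm, f]
            acc = (_tree_predict(tree, Xp) == yo).mean()
            Xp[:, f] = Xo[:, f]
            diffs[t, f] = base - acc
    gini /= n_trees
    mean_d = diffs.mean(axis=0)
    sd_d = diffs.std(axis=0, ddof=1)
    se = sd_d / np.sqrt(n_trees)
    with np.errstate(invalid="ignore", divide="ignore"):
        mda = np.where(se > 0, mean_d / se, mean_d)
    return mda, gini


@dataclass
class ImportanceResult:
    """Per-feature importances with permutation p-values and FDR flags."""

    frame: pd.DataFrame
    n_perm: int
    fdr: float

    @property
    def significant(self) -> pd.Index:
        return self.frame.index[self.frame["significant"]]


def permutation_feature_fdr(table: pd.DataFrame, n_perm: int = 1000,
                            fdr: float = 0.10, n_trees: int = 1000,
                            seed: int = 0) -> ImportanceResult:
    """Empirical feature significance by whole-forest label permutation.

    For each permutation, the class labels are shuffled and the forest and
    both importance measures are recomputed. The permutation p-value of a
    feature is (1 + #{perm >= observed}) / (n_perm + 1) for each measure;
    q-values are computed per measure and a feature is significant iff both
    pass the FDR threshold.
    """
    if n_perm < 20:
        raise ConfigurationError(
            f"n_perm={n_perm} is too small for stable p-values (need >= 20)")
    model = train_rf(table, n_trees=n_trees, seed=seed)
    rng = rng_for(seed, "rf_perm")
    mda_obs, gini_obs = _forest_importances(model, rng)
    F = len(model.feature_names)
    exceed_mda = np.zeros(F)
    exceed_gini = np.zeros(F)
    labels = table["label"].to_numpy()
    for b in range(n_perm):
        perm_table = table.copy()
        perm_table["label"] = labels[rng.permutation(len(labels))]
        pm = train_rf(perm_table, n_trees=n_trees, seed=int(rng.integers(0, 2**31 - 1)))
        mda_b, gini_b = _forest_importances(pm, rng)
        exceed_mda += mda_b >= mda_obs
        exceed_gini += gini_b >= gini_obs
    p_mda = (1.0 + exceed_mda) / (n_perm + 1.0)
    p_gini = (1.0 + exceed_gini) / (n_perm + 1.0)
    q_mda = storey_qvalue(p_mda).qvalues if F >= 2 else p_mda
    q_gini = storey_qvalue(p_gini).qvalues if F >= 2 else p_gini
    frame = pd.DataFrame({
        "mda": mda_obs, "gini": gini_obs,
        "p_mda": p_mda, "p_gini": p_gini,
        "q_mda": q_mda, "q_gini": q_gini,
        "significant": (q_mda < fdr) & (q_gini < fdr),
    }, index=pd.Index(model.feature_names, name="feature"))
    return ImportanceResult(frame=frame, n_perm=n_perm, fdr=fdr)
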