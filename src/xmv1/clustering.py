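"""Functional response-type discovery.

Strategy: over-cluster trial-averaged deconvolved profiles (Ward linkage,
Euclidean metric), drop clusters whose homogeneity — mean pairwise Pearson
correlation of member profiles — is not above 0.4 into a non-responsive
pool (label 0), then re-aggregate pooled cells whose correlation with some
kept-cluster centroid exceeds 0.4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, ward
from scipy.optimize import linear_sum_assignment

DEFAULT_HOM_THRESHOLD = 0.4
DEFAULT_REAGG_THRESHOLD = 0.4
N_OVER_AC = 100   # default over-cluster count for auditory-cortex-like data
N_OVER_V1 = 25    # default for V1-like data
POOL_LABEL = 0


@dataclass
class ClusterModel:
    """Cluster assignment; label 0 is the non-responsive pool."""

    labels: np.ndarray
    centroids: dict = field(default_factory=dict)  # label -> mean profile
    homogeneity: dict = field(default_factory=dict)
    linkage_tree: np.ndarray = None

    @property
    def kept_labels(self):
        return sorted(k for k in self.centroids if k != POOL_LABEL)


def _safe_corr(profiles: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation; zero-variance rows correlate at 0."""
    p = np.asarray(profiles, dtype=float)
    sd = p.std(axis=1)
    zerovar = sd == 0
    if zerovar.any():
        warnings.warn("zero-variance profile(s); correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(p)
    c = np.atleast_2d(c)
    c[zerovar, :] = 0.0
    c[:, zerovar] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.nan_to_num(c)


def cluster_profiles(profiles: np.ndarray, n_over: int) -> ClusterModel:
    """Agglomerative Ward clustering cut at ``n_over`` clusters.

    Deterministic given input order.  Labels are 1..n_over (no pool yet).
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2:
        raise ValueError("profiles must be 2-D (neurons x features)")
    bad = np.where(~np.isfinite(profiles).all(axis=1))[0]
    if bad.size:
        raise ValueError(f"non-finite profile(s) for neuron(s) {bad.tolist()}")
    n = profiles.shape[0]
    if n < n_over:
        raise ValueError(f"need >= {n_over} neurons, got {n}")

    tree = ward(profiles)
    raw = fcluster(tree, t=n_over, criterion="maxclust")
    # renumber by first occurrence for order-determinism
    remap, labels = {}, np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[i] = remap[lab]

    model = ClusterModel(labels=labels, linkage_tree=tree)
    for lab in np.unique(labels):
        model.centroids[int(lab)] = profiles[labels == lab].mean(axis=0)
    model.homogeneity = homogeneity(profiles, labels)
    return model


def homogeneity(profiles: np.ndarray, labels: np.ndarray) -> dict:
    """Mean pairwise Pearson correlation per cluster (singletons -> 1)."""
    profiles = np.asarray(profiles, dtype=float)
    labels = np.asarray(labels)
    out = {}
    for lab in np.unique(labels):
        if lab == POOL_LABEL:
            continue
        members = profiles[labels == lab]
        m = members.shape[0]
        if m < 2:
            out[int(lab)] = 1.0
            continue
        c = _safe_corr(members)
        iu = np.triu_indices(m, k=1)
        out[int(lab)] = float(c[iu].mean())
    return out


def prune(model: ClusterModel, profiles: np.ndarray,
          hom_threshold: float = DEFAULT_HOM_THRESHOLD,
          manual_exclusions=()) -> ClusterModel:
    """Merge clusters with homogeneity <= threshold into the pool (label 0).

    ``manual_exclusions`` lists additional cluster ids to pool (e.g. clusters
    capturing correlated noise).  Kept clusters are renumbered 1..K in order
    of their original ids.
    """
    labels = model.labels.copy()
    drop = {lab for lab, h in model.homogeneity.items()
            if h <= hom_threshold or lab in set(manual_exclusions)}
    for lab in drop:
        labels[model.labels == lab] = POOL_LABEL

    kept = sorted(set(labels.tolist()) - {POOL_LABEL})
    renum = {old: new for new, old in enumerate(kept, start=1)}
    new_labels = np.array([renum.get(l, POOL_LABEL) for l in labels])

    pruned = ClusterModel(labels=new_labels, linkage_tree=model.linkage_tree)
    for old, new in renum.items():
        pruned.centroids[new] = model.centroids[old]
    pruned.homogeneity = {renum[old]: model.homogeneity[old] for old in kept}
    return pruned


def reaggregate(model: ClusterModel, profiles: np.ndarray,
                corr_threshold: float = DEFAULT_REAGG_THRESHOLD) -> ClusterModel:
    """Reassign pooled neurons to their best-correlated centroid.

    A pooled neuron joins the argmax-correlation cluster if that correlation
    exceeds the threshold; centroids are deliberately not recomputed.
    """
    labels = model.labels.copy()
    kept = model.kept_labels
    if not kept:
        return model
    cents = np.stack([model.centroids[k] for k in kept])
    pool_idx = np.where(labels == POOL_LABEL)[0]
    for i in pool_idx:
        p = profiles[i]
        if p.std() == 0:
            continue
        cors = [_pearson(p, c) for c in cents]
        j = int(np.argmax(cors))
        if cors[j] > corr_threshold:
            labels[i] = kept[j]
    out = ClusterModel(labels=labels, centroids=dict(model.centroids),
                       homogeneity=dict(model.homogeneity),
                       linkage_tree=model.linkage_tree)
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def explained_variance(profiles: np.ndarray, model: ClusterModel) -> float:
    """Percent variance of clustered (non-pool) profiles captured by centroids."""
    mask = model.labels != POOL_LABEL
    if not mask.any():
        return 0.0
    p = np.asarray(profiles, dtype=float)[mask]
    labs = model.labels[mask]
    cents = np.stack([model.centroids[l] for l in labs])
    ss_res = float(((p - cents) ** 2).sum())
    ss_tot = float(((p - p.mean(axis=0)) ** 2).sum())
    if ss_tot == 0:
        return 100.0
    return 100.0 * (1.0 - ss_res / ss_tot)


def type_fractions(labels: np.ndarray, type_map: dict) -> dict:
    """Fractions of clustered neurons per functional label (pool excluded)."""
    labels = np.asarray(labels)
    clustered = labels[labels != POOL_LABEL]
    if clustered.size == 0:
        return {}
    missing = sorted(set(clustered.tolist()) - set(type_map))
    if missing:
        raise ValueError(f"type_map missing cluster id(s) {missing}")
    out = {}
    for lab in clustered:
        t = type_map[lab]
        out[t] = out.get(t, 0) + 1
    return {t: c / clustered.size for t, c in out.items()}


def label_clusters_by_template(centroids: dict, reference_profiles: dict) -> dict:
    """Rule-based functional labelling: each centroid takes the label of the
    best-correlated reference profile (e.g. canonical type signatures)."""
    ref_labels = list(reference_profiles)
    refs = np.stack([reference_profiles[k] for k in ref_labels])
    out = {}
    for cid, cent in centroids.items():
        if cid == POOL_LABEL:
            continue
        cors = [_pearson(cent, ref) for ref in refs]
        out[cid] = ref_labels[int(np.argmax(cors))]
    return out


def fit(profiles: np.ndarray, n_over: int = N_OVER_V1,
        hom_threshold: float = DEFAULT_HOM_THRESHOLD,
        reagg_threshold: float = DEFAULT_REAGG_THRESHOLD,
        manual_exclusions=()) -> ClusterModel:
    """Over-cluster, prune, re-aggregate."""
    model = cluster_profiles(profiles, n_over)
    model = prune(model, profiles, hom_threshold, manual_exclusions)
    return reaggregate(model, profiles, reagg_threshold)


def best_match_accuracy(truth_labels, cluster_labels,
                        pool_truth: str = "nonresponsive") -> float:
    """Accuracy under the optimal one-to-many cluster -> truth-type mapping.

    Each cluster (and the pool) is mapped to the truth type most common among
    its members; the pool maps to ``pool_truth``.  Returns the fraction of
    neurons whose mapped type matches their truth label.
    """
    truth = np.asarray(truth_labels)
    labs = np.asarray(cluster_labels)
    correct = 0
    for lab in np.unique(labs):
        members = truth[labs == lab]
        if lab == POOL_LABEL:
            mapped = pool_truth
        else:
            vals, counts = np.unique(members, return_counts=True)
            mapped = vals[np.argmax(counts)]
        correct += int((members == mapped).sum())
    return correct / truth.size


def contingency_assignment(truth_labels, cluster_labels):
    """Optimal one-to-one cluster/type matching (Hungarian) — diagnostic."""
    truth = np.asarray(truth_labels)
    labs = np.asarray(cluster_labels)
    t_vals = np.unique(truth)
    c_vals = np.unique(labs)
    M = np.zeros((len(c_vals), len(t_vals)))
    for i, c in enumerate(c_vals):
        for j, t in enumerate(t_vals):
            M[i, j] = np.sum((labs == c) & (truth == t))
    ri, ci = linear_sum_assignment(-M)
    return {int(c_vals[i]): str(t_vals[j]) for i, j in zip(ri, ci)}
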