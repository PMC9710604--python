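"""Batch-mixing and biology-retention metrics, plus simple baseline correctors.

All metrics take the log-expression matrix and per-sample labels.  Scored
against *batch* labels, good correction means scores near chance / full
mixing; scored against *Zero-Hop* (shared experimental design) labels, good
correction means biology stays separable.  Every report carries the exact
settings it was computed with, so scores are comparable across runs.

Distances are plain Euclidean on the expression matrix; no dimensionality
reduction is applied unless the caller does it first.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .data_io import ExpressionMatrix
from .design import EncodedDesign

__all__ = [
    "MetricReport",
    "classifier_score",
    "knn_entropy",
    "cluster_scores",
    "minimum_separation_number",
    "distance_scores",
    "baseline_correct",
]


@dataclass
class MetricReport:
    """A metric value with full provenance: settings, per-group values, summary."""

    metric_name: str
    target_labels: str
    values: list[float]
    summary: dict[str, float]
    params: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric_name,
            "target": self.target_labels,
            "values": [float(v) for v in self.values],
            "summary": {k: float(v) for k, v in self.summary.items()},
            "params": self.params,
            **({"extra": self.extra} if self.extra else {}),
        }


def _summarize(values: np.ndarray) -> dict[str, float]:
    return {"mean": float(np.mean(values)), "std": float(np.std(values, ddof=0))}


def classifier_score(
    Y: ExpressionMatrix,
    labels: list[str],
    kind: str = "logistic",
    folds: int = 10,
    seed: int = 0,
    target: str = "custom",
) -> MetricReport:
    """Cross-validated label predictability from expression.

    Stratified k-fold balanced accuracy (and macro-F1 for the logistic
    classifier).  High batch predictability means a residual batch effect;
    high Zero-Hop predictability means biology is retained.  Singleton
    label classes are dropped; classes smaller than the fold count are
    merged into an ``"other"`` stratum.  The classifier regularization is
    fixed (L2, strength 1.0) so the score reflects the data, not tuning.
    """
    if kind not in ("lda", "logistic"):
        raise ValueError(f"unknown classifier kind {kind!r}")
    labels = [str(l) for l in labels]
    counts = Counter(labels)
    singletons = {l for l, c in counts.items() if c == 1}
    if singletons:
        warnings.warn(
            f"excluding singleton label classes: {sorted(singletons)}", stacklevel=2
        )
    keep = np.array([l not in singletons for l in labels])
    y = np.array([l for l in labels if l not in singletons])
    X = Y.values[keep]
    counts = Counter(y)
    small = {l for l, c in counts.items() if c < folds}
    if small:
        warnings.warn(
            f"merging classes smaller than {folds} into 'other': {sorted(small)}",
            stacklevel=2,
        )
        y = np.array(["other" if l in small else l for l in y])
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 label classes after filtering")
    n_splits = min(folds, min(Counter(y).values()))
    if n_splits < folds:
        warnings.warn(
            f"reducing folds from {folds} to {n_splits} (smallest class size)",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    bal_acc, macro_f1 = [], []
    for train, test in skf.split(X, y):
        if kind == "lda":
            clf = LinearDiscriminantAnalysis()
        else:
            clf = LogisticRegression(C=1.0, max_iter=2000)  # default l2 penalty
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        bal_acc.append(balanced_accuracy_score(y[test], pred))
        if kind == "logistic":
            macro_f1.append(f1_score(y[test], pred, average="macro"))
    report = MetricReport(
        metric_name=f"{kind}_balanced_accuracy",
        target_labels=target,
        values=[float(v) for v in bal_acc],
        summary=_summarize(np.array(bal_acc)),
        params={
            "kind": kind,
            "folds": n_splits,
            "requested_folds": folds,
            "seed": seed,
            "n_classes": len(classes),
            "chance_level": 1.0 / len(classes),
        },
    )
    if macro_f1:
        report.extra["macro_f1"] = {
            "values": [float(v) for v in macro_f1],
            **_summarize(np.array(macro_f1)),
        }
    return report


def knn_entropy(
    Y: ExpressionMatrix, labels: list[str], k: int = 15, target: str = "custom"
) -> MetricReport:
    """Per-sample Shannon entropy (base 2) of labels among k nearest neighbors.

    Self is excluded; the result is normalized by log2(#classes) so 1 means
    perfectly mixed neighborhoods and 0 fully separated ones.  Distance
    ties straddling the k-th neighbor are resolved by fractional weights,
    so the score is independent of sample ordering.
    """
    labels = [str(l) for l in labels]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("kNN entropy is undefined for a single label class")
    n = Y.n_samples
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples {n}")
    lab_idx = np.array([classes.index(l) for l in labels])
    D = squareform(pdist(Y.values))
    entropies = np.empty(n)
    log_nc = np.log2(len(classes))
    for i in range(n):
        dist = np.delete(D[i], i)
        lab = np.delete(lab_idx, i)
        order = np.argsort(dist, kind="stable")
        dist, lab = dist[order], lab[order]
        kth = dist[k - 1]
        weights = np.zeros(len(dist))
        strictly_in = dist < kth
        weights[strictly_in] = 1.0
        tied = dist == kth
        weights[tied] = (k - strictly_in.sum()) / tied.sum()
        p = np.bincount(lab, weights=weights, minlength=len(classes)) / k
        nz = p > 0
        entropies[i] = -(p[nz] * np.log2(p[nz])).sum() / log_nc
    return MetricReport(
        metric_name="knn_entropy",
        target_labels=target,
        values=[float(e) for e in entropies],
        summary=_summarize(entropies),
        params={"k": k, "n_classes": len(classes), "normalized": True},
    )


def cluster_scores(
    Y: ExpressionMatrix,
    labels: list[str],
    n_clusters: int,
    seed: int = 0,
    target: str = "custom",
) -> MetricReport:
    """k-means cluster purity and Gini impurity with respect to labels.

    purity = sum_c (|c|/n) max_l p_cl  (1 when clusters are label-pure);
    gini   = sum_c (|c|/n) (1 - sum_l p_cl^2)  (0 when pure).  High purity
    w.r.t. batch labels means a residual batch effect.
    """
    labels = [str(l) for l in labels]
    n = Y.n_samples
    if n_clusters < 2:
        raise ValueError("n_clusters must be at least 2")
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds sample count {n}")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    assign = km.fit_predict(Y.values)
    purities, ginis, weights = [], [], []
    for c in range(n_clusters):
        members = [labels[i] for i in range(n) if assign[i] == c]
        if not members:
            continue
        fr = np.array(list(Counter(members).values()), dtype=float) / len(members)
        purities.append(fr.max())
        ginis.append(1.0 - (fr**2).sum())
        weights.append(len(members) / n)
    w = np.array(weights)
    purity = float((w * np.array(purities)).sum())
    gini = float((w * np.array(ginis)).sum())
    return MetricReport(
        metric_name="cluster_purity_gini",
        target_labels=target,
        values=[float(p) for p in purities],
        summary={"purity": purity, "gini": gini},
        params={"n_clusters": n_clusters, "n_init": 10, "seed": seed},
        extra={"per_cluster_gini": [float(g) for g in ginis]},
    )


def minimum_separation_number(
    Y: ExpressionMatrix,
    group_a: set[str],
    group_b: set[str],
    k_max: int = 10,
    seed: int = 0,
) -> int | None:
    """Smallest k for which k-means puts two sample groups in disjoint clusters.

    Returns the smallest k in 2..k_max such that no cluster contains members
    of both groups, or None if no such k exists ("not separated").  A small
    k means the groups are strongly separated — a batch effect, when the
    groups are two batches inside one Zero-Hop.
    """
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if group_a & group_b:
        raise ValueError(f"groups overlap: {sorted(group_a & group_b)}")
    pos = {s: i for i, s in enumerate(Y.sample_ids)}
    ia = [pos[s] for s in sorted(group_a)]
    ib = [pos[s] for s in sorted(group_b)]
    k_max = min(k_max, Y.n_samples)
    for k in range(2, k_max + 1):
        assign = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(
            Y.values
        )
        if not (set(assign[ia]) & set(assign[ib])):
            return k
    return None


def distance_scores(
    Y: ExpressionMatrix,
    batch_labels: list[str],
    zero_hop_labels: list[str],
) -> MetricReport:
    """Distance ratio score (DRS) and median pairwise distance per Zero-Hop.

    Within each Zero-Hop spanning at least two batches, DRS is the mean
    Euclidean distance between samples in different batches divided by the
    mean distance between samples in the same batch.  DRS near 1 means
    batches are mixed inside the Zero-Hop.  Zero within-batch distance
    makes DRS undefined; such Zero-Hops are reported as degenerate.
    """
    batch_labels = [str(b) for b in batch_labels]
    zero_hop_labels = [str(z) for z in zero_hop_labels]
    hops = sorted(set(zero_hop_labels))
    drs_values, medians, hop_names, degenerate = [], [], [], []
    for hop in hops:
        idx = [i for i, z in enumerate(zero_hop_labels) if z == hop]
        batches_here = {batch_labels[i] for i in idx}
        if len(idx) < 2 or len(batches_here) < 2:
            continue
        sub = Y.values[idx]
        D = squareform(pdist(sub))
        same = np.zeros_like(D, dtype=bool)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                same[a, b] = batch_labels[idx[a]] == batch_labels[idx[b]]
        upper = np.triu(np.ones_like(D, dtype=bool), 1)
        within = D[upper & same]
        between = D[upper & ~same]
        medians.append(float(np.median(D[upper])))
        hop_names.append(hop)
        if within.size == 0 or within.mean() == 0 or between.size == 0:
            degenerate.append(hop)
            drs_values.append(float("nan"))
        else:
            drs_values.append(float(between.mean() / within.mean()))
    if not hop_names:
        raise ValueError(
            "no Zero-Hop spans multiple batches; DRS is undefined on this data"
        )
    finite = [v for v in drs_values if np.isfinite(v)]
    summary = _summarize(np.array(finite)) if finite else {"mean": float("nan"), "std": float("nan")}
    return MetricReport(
        metric_name="distance_ratio_score",
        target_labels="batch",
        values=drs_values,
        summary=summary,
        params={"metric": "euclidean"},
        extra={
            "zero_hops": hop_names,
            "median_pairwise_distance": medians,
            "degenerate_zero_hops": degenerate,
        },
    )


def baseline_correct(
    Y: ExpressionMatrix,
    d: EncodedDesign,
    method: str,
    q: int = 0,
    p: int = 0,
) -> ExpressionMatrix:
    """Simple comparison correctors: z-scoring, marker-gene or PC elimination.

    * ``standardize``: per-gene global z-score.
    * ``marker_gene_elimination``: drop the ``q`` genes most associated with
      batch by one-way ANOVA F-statistic.
    * ``pc_elimination``: remove the ``p`` principal components whose sample
      scores have the highest R^2 against the batch one-hots, and
      reconstruct the matrix without them.
    """
    if d.n_batches < 2:
        raise ValueError("baseline correction requires at least 2 batches")
    X = Y.values
    if method == "standardize":
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        out = (X - X.mean(axis=0)) / sd
        return ExpressionMatrix(out, list(Y.sample_ids), list(Y.gene_ids))
    idx = d.batch_index
    if method == "marker_gene_elimination":
        if q >= Y.n_genes:
            raise ValueError(f"q={q} must be smaller than the gene count {Y.n_genes}")
        if q == 0:
            return Y.copy()
        f = _batch_f_statistic(X, idx, d.n_batches)
        drop = np.argsort(f)[::-1][:q]
        keep = np.setdiff1d(np.arange(Y.n_genes), drop)
        return ExpressionMatrix(
            X[:, keep], list(Y.sample_ids), [Y.gene_ids[i] for i in keep]
        )
    if method == "pc_elimination":
        r = min(Y.n_samples, Y.n_genes)
        if p >= r:
            raise ValueError(f"p={p} must be smaller than min(n, g)={r}")
        if p == 0:
            return Y.copy()
        mu = X.mean(axis=0)
        U, sv, Vt = np.linalg.svd(X - mu, full_matrices=False)
        scores = U * sv
        r2 = np.array(
            [_batch_r_squared(scores[:, j], idx, d.n_batches) for j in range(scores.shape[1])]
        )
        drop = np.argsort(r2)[::-1][:p]
        recon = (X - mu).copy()
        for j in drop:
            recon -= np.outer(scores[:, j], Vt[j])
        return ExpressionMatrix(recon + mu, list(Y.sample_ids), list(Y.gene_ids))
    raise ValueError(
        f"unknown baseline method {method!r}; choose standardize, "
        "marker_gene_elimination or pc_elimination"
    )


def _batch_f_statistic(X: np.ndarray, idx: np.ndarray, nb: int) -> np.ndarray:
    """One-way ANOVA F per gene for batch-group mean differences."""
    n = X.shape[0]
    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for i in range(nb):
        rows = X[idx == i]
        mi = rows.mean(axis=0)
        ss_between += rows.shape[0] * (mi - grand) ** 2
        ss_within += ((rows - mi) ** 2).sum(axis=0)
    df1, df2 = nb - 1, n - nb
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    return np.nan_to_num(f, nan=0.0, posinf=np.finfo(float).max)


def _batch_r_squared(score: np.ndarray, idx: np.ndarray, nb: int) -> float:
    """R^2 of a PC score vector explained by batch membership (group means)."""
    grand = score.mean()
    ss_tot = ((score - grand) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    ss_res = 0.0
    for i in range(nb):
        vals = score[idx == i]
        ss_res += ((vals - vals.mean()) ** 2).sum()
    return float(1.0 - ss_res / ss_tot)
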