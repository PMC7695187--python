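"""Infection time-course expression: TPM, scaling, timing classes, enrichment.

Read counts per gene and timepoint (hours post-infection) are normalized to
TPM (transcripts per million: length-normalized rates scaled to sum to 1e6
per sample), log-transformed with a +1 pseudocount, and row-scaled.  Genes are
partitioned into three timing classes (early / intermediate / late) by
k-means clustering under a rank-correlation (Spearman) distance; a cluster is
labelled by when its mean profile peaks: early clusters peak at <= 2 h pi,
late clusters peak at >= 4 h pi with sustained expression through the end of
the cycle, intermediate otherwise.

Spearman-distance k-means is realized exactly as Euclidean k-means on
z-scored rank vectors (1 - rho is proportional to the squared Euclidean
distance between standardized ranks), so the centroid update is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from . import stats as cstats
from .region_density import RegionPartition

DEFAULT_TIMEPOINTS = (0, 1, 2, 4, 5, 6, 8, 10, 12)


class ExpressionError(ValueError):
    pass


def read_counts(tsv_path) -> pd.DataFrame:
    """Counts TSV: rows genes, columns timepoints (header = hours pi)."""
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    df.columns = [float(c) for c in df.columns]
    return df


def compute_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """TPM per timepoint: 1e6 * (c_g/l_g) / sum_h (c_h/l_h).

    An all-zero sample column stays all zero.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index[:3])
        raise ExpressionError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ExpressionError("gene lengths must be positive")
    if (counts.values < 0).any():
        raise ExpressionError("counts must be nonnegative")
    rate = counts.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    tpm = rate * 0.0
    nz = colsum > 0
    tpm.loc[:, nz] = rate.loc[:, nz].div(colsum[nz], axis=1) * 1e6
    return tpm


def scale_profiles(tpm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene scaled log profiles: x = log(tpm + 1), centered by the gene
    mean and divided by the gene sd; constant rows map to zeros."""
    if tpm.shape[1] < 2:
        raise ExpressionError("need at least 2 timepoints")
    x = np.log(tpm.values + 1.0)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    scaled = np.zeros_like(x)
    ok = sd[:, 0] > 0
    scaled[ok] = (x[ok] - mu[ok]) / sd[ok]
    return pd.DataFrame(scaled, index=tpm.index, columns=tpm.columns)


@dataclass
class ExpressionClasses:
    classes: pd.Series  # gene -> early / intermediate / late
    cluster_means: pd.DataFrame  # class x timepoint mean scaled profile
    k: int
    seed: int


def _label_clusters(means: np.ndarray, hours: np.ndarray) -> list[str]:
    """Map cluster mean profiles to early/intermediate/late by peak timing."""
    labels = []
    for prof in means:
        peak_t = hours[int(np.argmax(prof))]
        sustained = prof[-1] >= prof.max() - 0.5 * (prof.max() - prof.min())
        if peak_t <= 2:
            labels.append("early")
        elif peak_t >= 4 and sustained:
            labels.append("late")
        else:
            labels.append("intermediate")
    # guarantee distinct labels when k = 3: break conflicts by peak order
    if len(labels) == 3 and len(set(labels)) < 3:
        order = np.argsort([hours[int(np.argmax(p))] + 1e-3 * p[-1] for p in means])
        names = ["early", "intermediate", "late"]
        labels = [""] * 3
        for rank, idx in enumerate(order):
            labels[idx] = names[rank]
    return labels


def assign_classes(
    scaled: pd.DataFrame, k: int = 3, seed: int = 0, n_restarts: int = 50
) -> ExpressionClasses:
    """Cluster scaled profiles into k timing classes with Spearman-distance
    k-means (k-means++ seeding, ``n_restarts`` restarts, fixed seed).

    Genes whose profile is all zero (unexpressed / constant) are excluded from
    clustering and labelled ``unclassified``.
    """
    hours = np.asarray(scaled.columns, dtype=float)
    expressed = scaled.index[(scaled.values != 0).any(axis=1)]
    if len(expressed) < k:
        raise ExpressionError(f"need at least k={k} expressed genes")
    X = scaled.loc[expressed].values
    ranks = np.apply_along_axis(rankdata, 1, X)
    ranks = (ranks - ranks.mean(axis=1, keepdims=True)) / ranks.std(axis=1, keepdims=True)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    assign = km.fit_predict(ranks)
    means = np.vstack(
        [X[assign == c].mean(axis=0) for c in range(k)]
    )
    names = _label_clusters(means, hours)
    classes = pd.Series("unclassified", index=scaled.index, dtype=object)
    classes.loc[expressed] = [names[c] for c in assign]
    cluster_means = pd.DataFrame(means, index=names, columns=scaled.columns)
    return ExpressionClasses(classes=classes, cluster_means=cluster_means, k=k, seed=seed)


def timing_enrichment(
    classes: pd.Series,
    labels: pd.Series,
    class_order: tuple[str, ...] = ("early", "intermediate", "late"),
    use_fisher: bool = False,
) -> dict:
    """Contingency table of region/category labels x timing classes with a
    Pearson chi-square (or Fisher for 2x2) test.

    ``labels`` maps gene -> group (e.g. core_region / other_region); only
    genes present in both inputs with a known class are counted.
    """
    common = classes.index.intersection(labels.index)
    cls = classes.loc[common]
    grp = labels.loc[common]
    keep = cls.isin(class_order)
    table = pd.crosstab(grp[keep], cls[keep]).reindex(columns=list(class_order), fill_value=0)
    counts = table.values
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        zero_rows = [str(i) for i, s in zip(table.index, counts.sum(axis=1)) if s == 0]
        zero_cols = [str(c) for c, s in zip(table.columns, counts.sum(axis=0)) if s == 0]
        raise ExpressionError(f"zero margin in contingency table: rows {zero_rows} cols {zero_cols}")
    if use_fisher and counts.shape == (2, 2):
        res = cstats.fisher_exact(counts)
    else:
        res = cstats.chi_square(counts)
    freq = table.div(table.sum(axis=1), axis=0)
    return {"table": table, "frequencies": freq, "statistic": res.statistic, "p_value": res.p_value, "method": res.method}


def summarize_expression(tpm: pd.DataFrame, partition: RegionPartition | None = None) -> dict:
    """Per-gene total and maximal log(TPM + 1) expression, plus (optionally)
    two-sided pooled-variance t-tests of both summaries between regions."""
    logx = np.log(tpm.values + 1.0)
    summaries = pd.DataFrame(
        {"total_expression": logx.sum(axis=1), "max_expression": logx.max(axis=1)},
        index=tpm.index,
    )
    out = {"summaries": summaries}
    if partition is not None:
        for col in ("total_expression", "max_expression"):
            a = summaries.loc[
                [g for g in summaries.index if partition.labels.get(g) == "core_region"], col
            ]
            b = summaries.loc[
                [g for g in summaries.index if partition.labels.get(g) == "other_region"], col
            ]
            if len(a) < 2 or len(b) < 2:
                raise ExpressionError("each region needs at least 2 genes")
            res = cstats.t_test(a, b)
            out[col] = {
                "core_region_mean": float(a.mean()),
                "core_region_sd": float(a.std(ddof=1)),
                "other_region_mean": float(b.mean()),
                "other_region_sd": float(b.std(ddof=1)),
                "t_p_value": res.p_value,
            }
    return out
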