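"""Expression-methylation correlation, direction calling, and clustering.

Per gene, Pearson's r is computed between (log-transformed) expression and
proximal-promoter mean methylation over the matched samples, pooling all
tissues so that tissue-driven contrast is the signal. Genes are classified
``negative`` (r <= -threshold), ``positive`` (r >= threshold, boundary
inclusive) or ``none``. Row-scaled methylation patterns of selected genes
are grouped by K-means (k=5 by default) with hierarchical ordering inside
each cluster (average linkage on 1 - Pearson distance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

__all__ = [
    "correlate_expression_methylation",
    "classify_correlations",
    "ClusterResult",
    "cluster_methylation",
]

R_THRESHOLD_DEFAULT = 0.3
MIN_PAIRS_DEFAULT = 10


def correlate_expression_methylation(
    expr: pd.DataFrame,
    meth: pd.DataFrame,
    min_pairs: int = MIN_PAIRS_DEFAULT,
) -> pd.DataFrame:
    """Per-gene Pearson r between expression and methylation.

    Parameters
    ----------
    expr, meth
        gene x sample frames sharing a sample namespace; expression is
        expected log-transformed (caller's choice). Missing methylation
        cells are dropped pairwise per gene.
    min_pairs
        minimum complete sample pairs; below it r is reported NaN.

    Returns a DataFrame indexed by the genes present in both frames, with
    columns ``r``, ``n_pairs`` and ``undefined`` (True when r could not be
    computed: too few pairs or zero variance in either variable).
    """
    shared_samples = [s for s in expr.columns if s in set(meth.columns)]
    if not shared_samples:
        raise ValueError("no overlapping samples between expression and methylation")
    genes = [g for g in expr.index if g in set(meth.index)]

    e = expr.loc[genes, shared_samples].to_numpy(dtype=float)
    m = meth.loc[genes, shared_samples].to_numpy(dtype=float)
    rs = np.full(len(genes), np.nan)
    ns = np.zeros(len(genes), dtype=int)
    for i in range(len(genes)):
        ok = ~(np.isnan(e[i]) | np.isnan(m[i]))
        ns[i] = int(ok.sum())
        if ns[i] < max(min_pairs, 2):
            continue
        x, y = e[i, ok], m[i, ok]
        if x.std() == 0 or y.std() == 0:
            continue
        rs[i] = np.corrcoef(x, y)[0, 1]
    return pd.DataFrame(
        {"r": rs, "n_pairs": ns, "undefined": np.isnan(rs)}, index=pd.Index(genes, name="gene_id")
    )


def classify_correlations(
    records: pd.DataFrame, threshold: float = R_THRESHOLD_DEFAULT
) -> pd.DataFrame:
    """Attach a ``direction`` column: negative / positive / none.

    The boundary |r| == threshold counts as significant (inclusive).
    Undefined r maps to ``none``.
    """
    r = records["r"]
    direction = np.where(
        r <= -threshold, "negative", np.where(r >= threshold, "positive", "none")
    )
    direction = np.where(r.isna(), "none", direction)
    out = records.copy()
    out["direction"] = direction
    return out


@dataclass
class ClusterResult:
    """K-means assignment plus a display row order for heatmap rendering."""

    assignments: pd.Series      # gene -> cluster index (1..k)
    row_order: list[str]        # genes ordered by cluster, then linkage leaves
    scaled: pd.DataFrame        # per-gene z-scaled methylation rows
    dropped: list[str]          # genes excluded (missing cells / zero variance)


def cluster_methylation(
    meth: pd.DataFrame, k: int = 5, seed: int | None = None, n_init: int = 10
) -> ClusterResult:
    """K-means clustering of row-scaled promoter methylation patterns.

    Rows are z-scaled (mean 0, sd 1 per gene) before clustering, so
    assignments are invariant to per-gene affine transforms of the raw
    values. Genes with any missing cell or zero variance are dropped with a
    warning. Within each cluster, rows are ordered by the leaf order of an
    average-linkage dendrogram on 1 - Pearson correlation distance.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible K-means")
    complete = meth.dropna(axis=0)
    nonconstant = complete.std(axis=1, ddof=0) > 0
    dropped = sorted(set(meth.index) - set(complete.index[nonconstant]))
    if dropped:
        warnings.warn(f"excluded from clustering (missing/constant): {dropped}", stacklevel=2)
    usable = complete.loc[nonconstant]
    k_eff = min(k, len(usable))
    if k_eff == 0:
        raise ValueError("no usable rows to cluster")

    x = usable.to_numpy(dtype=float)
    scaled = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    km = KMeans(n_clusters=k_eff, n_init=n_init, random_state=seed)
    labels = km.fit_predict(scaled) + 1

    scaled_df = pd.DataFrame(scaled, index=usable.index, columns=usable.columns)
    row_order: list[str] = []
    for c in range(1, k_eff + 1):
        members = scaled_df.index[labels == c].tolist()
        if len(members) > 2:
            d = pdist(scaled_df.loc[members].to_numpy(), metric="correlation")
            leaves = leaves_list(average(d))
            members = [members[i] for i in leaves]
        row_order.extend(members)

    return ClusterResult(
        assignments=pd.Series(labels, index=usable.index, name="cluster"),
        row_order=row_order,
        scaled=scaled_df,
        dropped=dropped,
    )
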