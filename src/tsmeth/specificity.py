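"""Tau tissue-specificity statistic and tissue-specific gene (TSG) calling.

For a gene with per-tissue mean expression x_1..x_n (n tissues),

    tau = sum_i (1 - x_i / max_j x_j) / (n - 1)

Tau is 0 for a perfectly ubiquitous gene (equal expression everywhere) and 1
for a gene expressed in exactly one tissue. A gene is called tissue-specific
when tau >= threshold (default 0.8, inclusive), and it is assigned to the
tissue with the highest mean expression; argmax ties keep the first tissue
in the fixed tissue order and set ``tie_flag``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = ["tissue_means", "compute_tau", "tau_profile_matrix", "call_tsgs"]

TAU_THRESHOLD_DEFAULT = 0.8


def tissue_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene arithmetic mean TPM per tissue (genes x tissues).

    Tissue column order follows first appearance in the sample sheet and is
    the fixed order used for argmax tie-breaking downstream.
    """
    order = matrix.tissue_order
    if not order:
        raise ValueError("no tissues in sample sheet")
    means = matrix.values.T.groupby(matrix.tissues).mean().T
    return means[order]


def compute_tau(x) -> float:
    """Tau for one per-tissue mean profile (vector of length n >= 2)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a vector of length >= 2")
    if (x < 0).any():
        raise ValueError("negative expression in profile")
    m = x.max()
    if m == 0:
        raise ValueError("all-zero profile: Tau normalization undefined")
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def tau_profile_matrix(profiles: pd.DataFrame) -> pd.Series:
    """Vectorized Tau over a genes x tissues mean-expression frame."""
    x = profiles.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need >= 2 tissues")
    if (x < 0).any():
        raise ValueError("negative expression in profiles")
    m = x.max(axis=1)
    if (m == 0).any():
        bad = profiles.index[m == 0].tolist()
        raise ValueError(f"all-zero profiles (Tau undefined): {bad}")
    tau = (1.0 - x / m[:, None]).sum(axis=1) / (x.shape[1] - 1)
    return pd.Series(tau, index=profiles.index, name="tau")


def call_tsgs(
    profiles: pd.DataFrame, tau_threshold: float = TAU_THRESHOLD_DEFAULT
) -> pd.DataFrame:
    """Call TSGs from per-tissue mean profiles.

    Parameters
    ----------
    profiles
        genes x tissues mean TPM; rows should already be restricted to genes
        with max TPM >= 1 (see ``expression.filter_expressed(mode="max_ge_one")``).
    tau_threshold
        inclusive Tau cutoff for the TSG call.

    Returns
    -------
    DataFrame indexed by gene with columns ``tau``, ``assigned_tissue``,
    ``is_tsg``, ``tie_flag`` plus the per-tissue means.
    """
    tau = tau_profile_matrix(profiles)
    x = profiles.to_numpy(dtype=float)
    argmax = x.argmax(axis=1)  # first occurrence wins ties
    tie = (x == x.max(axis=1)[:, None]).sum(axis=1) > 1
    out = pd.DataFrame(
        {
            "tau": tau,
            "assigned_tissue": [profiles.columns[i] for i in argmax],
            "is_tsg": tau >= tau_threshold,
            "tie_flag": tie,
        },
        index=profiles.index,
    )
    return pd.concat([out, profiles.add_prefix("mean_")], axis=1)
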