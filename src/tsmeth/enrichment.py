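"""Gene-set over-representation testing against GMT collections.

A query list is tested per set with the one-sided upper-tail hypergeometric
probability P[X >= k] for the overlap k, given the background universe, and
p-values are Benjamini-Hochberg adjusted across sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetCollection", "read_gmt", "overrepresentation_test"]


@dataclass
class GeneSetCollection:
    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(stream: IO[str] | Iterable[str]) -> GeneSetCollection:
    """Parse GMT lines (name, description, members...); members deduplicated."""
    coll = GeneSetCollection()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line {lineno}: expected >= 3 fields, got {len(parts)}")
        name, desc, members = parts[0], parts[1], parts[2:]
        coll.sets[name] = frozenset(m for m in members if m)
        coll.descriptions[name] = desc
    return coll


def overrepresentation_test(
    query: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each set.

    With N = |background|, K = |set ∩ background|, n = |query|, the p-value
    is P[X >= k] for the observed overlap k (one-sided upper tail).
    BH adjustment runs across all sets; results are sorted by raw p.

    Raises if any query gene lies outside the background.
    """
    query = set(query)
    background = set(background)
    offenders = sorted(query - background)
    if offenders:
        raise ValueError(f"query genes outside background: {offenders}")
    n, N = len(query), len(background)

    rows = []
    for name, members in collection.sets.items():
        K = len(members & background)
        k = len(query & members & background)
        # P[X >= k]; sf(k-1) is the upper tail including k
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, p))
    result = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    if len(result):
        result["p"] = result["p"].clip(upper=1.0)
        result["p_adj"] = multipletests(result["p"], method="fdr_bh")[1]
        result = result.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    else:
        result["p_adj"] = []
    return result
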