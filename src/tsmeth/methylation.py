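"""Per-CpG methylation calls and promoter-region aggregation.

Calls come from whole-genome bisulfite sequencing as per-cytosine records
(chromosome, 1-based position, strand, methylated fraction in [0,1],
effective coverage). Records below the coverage cutoff (default depth >= 10)
are discarded at read time. Region methylation is the unweighted arithmetic
mean of the ratios of CpGs falling inside the region; a coverage-weighted
mean is available behind a flag. Calls on '+' and '-' strands are kept as
independent records (no CpG-dyad merging).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .gene_model import PromoterRegion

__all__ = [
    "read_cpg_calls",
    "RegionMethylationMatrix",
    "aggregate_region_methylation",
    "promoter_methylation_summary",
]

MIN_DEPTH_DEFAULT = 10

_CALL_COLUMNS = ["chrom", "pos", "strand", "ratio", "depth"]
_DEPTH_ALIASES = ("depth", "eff_CT_count", "eff_ct_count", "coverage")


def _read_bedgraph(lines: list[str], min_depth: int) -> pd.DataFrame:
    if min_depth > 0:
        warnings.warn(
            "bedGraph input carries no coverage column; depth filter skipped",
            stacklevel=3,
        )
    rows = []
    for lineno, line in lines:
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"line {lineno}: bedGraph needs 4 columns")
        chrom, start, _end, ratio = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        if not 0.0 <= ratio <= 1.0:
            raise ValueError(f"line {lineno}: methylation ratio {ratio} outside [0,1]")
        rows.append((chrom, start + 1, ".", ratio, np.nan))
    return pd.DataFrame(rows, columns=_CALL_COLUMNS)


def read_cpg_calls(
    stream: IO[str] | Iterable[str], min_depth: int = MIN_DEPTH_DEFAULT
) -> pd.DataFrame:
    """Read per-CpG calls from a headered TSV or a 4-column bedGraph.

    The TSV must carry a header naming at least ``chrom``, ``pos``,
    ``ratio`` and a coverage column (``depth`` or ``eff_CT_count``); extra
    columns (e.g. ``context``) are tolerated. bedGraph rows are 0-based
    half-open single-base intervals holding the ratio only, so the depth
    filter cannot apply (a warning is issued).

    Returns a DataFrame with columns chrom, pos (1-based), strand, ratio,
    depth, sorted by (chrom, pos); records with depth < ``min_depth`` are
    excluded. A ratio outside [0,1] raises with the offending line number.
    """
    lines = [
        (i, raw.rstrip("\n"))
        for i, raw in enumerate(stream, start=1)
        if raw.strip() and not raw.startswith(("track", "#"))
    ]
    if not lines:
        return pd.DataFrame(columns=_CALL_COLUMNS).astype(
            {"pos": int, "ratio": float, "depth": float}
        )

    header_fields = lines[0][1].split("\t")
    lowered = [f.lower() for f in header_fields]
    if "chrom" in lowered or "pos" in lowered:
        name_map = {f.lower(): f for f in header_fields}
        depth_col = next((a for a in _DEPTH_ALIASES if a.lower() in name_map), None)
        needed = {"chrom", "pos", "ratio"}
        if not needed.issubset(name_map):
            raise ValueError(f"call TSV header must name columns {sorted(needed)}")
        idx = {k: lowered.index(k.lower()) for k in name_map}
        rows = []
        for lineno, line in lines[1:]:
            parts = line.split("\t")
            if len(parts) < len(header_fields):
                raise ValueError(f"line {lineno}: truncated record")
            ratio = float(parts[idx["ratio"]])
            if not 0.0 <= ratio <= 1.0:
                raise ValueError(
                    f"line {lineno}: methylation ratio {ratio} outside [0,1]"
                )
            depth = float(parts[idx[depth_col.lower()]]) if depth_col else np.nan
            strand = parts[idx["strand"]] if "strand" in idx else "."
            rows.append((parts[idx["chrom"]], int(parts[idx["pos"]]), strand, ratio, depth))
        calls = pd.DataFrame(rows, columns=_CALL_COLUMNS)
        if depth_col is None:
            warnings.warn("no coverage column found; depth filter skipped", stacklevel=2)
        else:
            calls = calls[calls["depth"] >= min_depth]
    elif len(header_fields) >= 4:
        calls = _read_bedgraph(lines, min_depth)
    else:
        raise ValueError("unrecognized call format: need a headered TSV or bedGraph")

    return calls.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


@dataclass
class RegionMethylationMatrix:
    """Region (gene_id, kind) x sample mean methylation with CpG counts.

    ``values`` holds means in [0,1] or NaN where fewer than ``min_cpgs``
    CpGs contributed; ``n_cpgs`` holds the contributing counts.
    """

    values: pd.DataFrame   # index: MultiIndex (gene_id, kind); columns: samples
    n_cpgs: pd.DataFrame

    def for_kind(self, kind: str) -> pd.DataFrame:
        """Gene x sample values for one promoter kind."""
        return self.values.xs(kind, level="kind")


def aggregate_region_methylation(
    calls_by_sample: Mapping[str, pd.DataFrame],
    regions: Iterable[PromoterRegion],
    min_cpgs: int = 1,
    weighted: bool = False,
) -> RegionMethylationMatrix:
    """Mean promoter methylation per region per sample.

    A CpG at 1-based position p belongs to a 0-based half-open region
    [start, end) iff start < p <= end. The cell value is the unweighted mean
    of the member ratios (or the coverage-weighted mean when ``weighted``);
    cells with fewer than ``min_cpgs`` members are NaN. A region on a
    chromosome absent from a sample's calls is simply missing.
    """
    regions = list(regions)
    samples = list(calls_by_sample)
    index = pd.MultiIndex.from_tuples(
        [(r.gene_id, r.kind) for r in regions], names=["gene_id", "kind"]
    )
    values = np.full((len(regions), len(samples)), np.nan)
    counts = np.zeros((len(regions), len(samples)), dtype=int)

    for j, sample in enumerate(samples):
        calls = calls_by_sample[sample]
        if "depth" not in calls.columns:
            alias = next((a for a in _DEPTH_ALIASES if a in calls.columns), None)
            calls = calls.rename(columns={alias: "depth"}) if alias else calls.assign(depth=np.nan)
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in calls.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            order = np.argsort(pos, kind="mergesort")
            by_chrom[chrom] = (
                pos[order],
                grp["ratio"].to_numpy()[order],
                grp["depth"].to_numpy()[order],
            )
        for i, r in enumerate(regions):
            if r.chrom not in by_chrom:
                continue
            pos, ratio, depth = by_chrom[r.chrom]
            lo = np.searchsorted(pos, r.start, side="right")  # first p > start
            hi = np.searchsorted(pos, r.end, side="right")    # last p <= end
            n = hi - lo
            counts[i, j] = n
            if n >= min_cpgs and n > 0:
                if weighted:
                    w = depth[lo:hi]
                    if np.isnan(w).any() or w.sum() == 0:
                        values[i, j] = ratio[lo:hi].mean()
                    else:
                        values[i, j] = float(np.average(ratio[lo:hi], weights=w))
                else:
                    values[i, j] = ratio[lo:hi].mean()

    return RegionMethylationMatrix(
        values=pd.DataFrame(values, index=index, columns=samples),
        n_cpgs=pd.DataFrame(counts, index=index, columns=samples),
    )


def promoter_methylation_summary(
    matrix_proximal: pd.DataFrame, matrix_typical: pd.DataFrame
) -> dict[str, float]:
    """Grand mean methylation per promoter kind, in percent.

    The mean is over all non-missing gene x sample cells of each matrix.
    """
    out = {}
    for kind, m in (("proximal", matrix_proximal), ("typical", matrix_typical)):
        vals = m.to_numpy(dtype=float)
        if np.isnan(vals).all():
            raise ValueError(f"all cells missing in {kind} matrix")
        out[kind] = float(np.nanmean(vals)) * 100.0
    return out
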