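"""Region-restricted EWAS: probe selection, association, discovery/replication.

Array probes (beta values in [0,1]) falling inside expanded promoter regions
of tissue-specific genes are tested for association with a binary phenotype
by linear regression of methylation on the outcome indicator plus covariates
(the dominant EWAS convention; a logistic model with status as response is
available behind a flag). Discovery significance uses the Bonferroni
threshold alpha/m over the probes actually tested; replication requires a
nominal p < 0.05 in independent data and, by default, a concordant effect
sign.
"""

from __future__ import annotations

import warnings
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_model import PromoterRegion

__all__ = [
    "load_probe_matrix",
    "load_manifest",
    "load_phenotypes",
    "select_probes_in_regions",
    "dmp_association",
    "bonferroni_threshold",
    "discovery_replication",
]

SEX_CODES = {"F": 0.0, "M": 1.0}


def load_probe_matrix(stream: IO[str] | str) -> pd.DataFrame:
    """Probe x sample beta-value TSV (header = samples, first column = probe)."""
    betas = pd.read_csv(stream, sep="\t", index_col=0)
    arr = betas.to_numpy(dtype=float)
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise ValueError("beta values must lie in [0, 1]")
    return betas.astype(float)


def load_manifest(stream: IO[str] | str) -> pd.DataFrame:
    """Probe manifest TSV with columns probe, chrom, pos (1-based)."""
    mf = pd.read_csv(stream, sep="\t", dtype={"probe": str, "chrom": str})
    required = {"probe", "chrom", "pos"}
    if not required.issubset(mf.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return mf.set_index("probe")


def load_phenotypes(stream: IO[str] | str) -> pd.DataFrame:
    """Phenotype TSV: sample, status (case/control), age, sex (F/M), bmi, t2d."""
    ph = pd.read_csv(stream, sep="\t", dtype={"sample": str})
    if "sample" not in ph.columns or "status" not in ph.columns:
        raise ValueError("phenotype table must have columns sample, status")
    return ph.set_index("sample")


def select_probes_in_regions(
    manifest: pd.DataFrame, regions: Iterable[PromoterRegion]
) -> pd.DataFrame:
    """Probes whose 1-based position lies inside any 0-based half-open region.

    Returns one row per (probe, gene) hit, deduplicated; a probe inside the
    regions of several genes appears once per gene but only once in
    ``result.index.unique()``.
    """
    hits: list[tuple[str, str, str]] = []
    by_chrom: dict[str, list[PromoterRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for probe, row in manifest.iterrows():
        for r in by_chrom.get(str(row["chrom"]), ()):
            if r.contains_1based(int(row["pos"])):
                hits.append((probe, r.gene_id, r.kind))
    out = pd.DataFrame(hits, columns=["probe", "gene_id", "kind"]).drop_duplicates()
    return out.set_index("probe")


def dmp_association(
    betas: pd.DataFrame,
    pheno: pd.DataFrame,
    outcome: str = "obesity",
    covariates: Sequence[str] = ("age", "sex"),
    model: str = "linear",
    use_mvalues: bool = False,
) -> pd.DataFrame:
    """Per-probe association between methylation and a binary outcome.

    Linear model (default): beta_value ~ outcome + covariates, with the
    effect the outcome coefficient and p a two-sided Wald test on it.
    Samples missing the outcome or any covariate are dropped listwise.
    With ``use_mvalues`` betas are logit-transformed, M = log2(b/(1-b)),
    clipped to [1e-3, 1-1e-3] first. ``model="logistic"`` instead regresses
    the outcome on each probe's methylation plus covariates (statsmodels
    Logit), reporting the methylation coefficient.

    Returns a DataFrame indexed by probe with columns effect, se, p, n and
    ``constant`` (True where the probe had zero variance; its p is NaN).
    """
    status_col = "status" if outcome == "obesity" else outcome
    if status_col not in pheno.columns:
        raise ValueError(f"phenotype table lacks outcome column {status_col!r}")
    shared = [s for s in betas.columns if s in pheno.index]
    if not shared:
        raise ValueError("no overlapping samples between betas and phenotypes")
    ph = pheno.loc[shared]

    y01 = ph[status_col].map({"case": 1.0, "control": 0.0})
    cols = {"outcome": y01}
    for c in covariates:
        if c not in ph.columns:
            raise ValueError(f"phenotype table lacks covariate {c!r}")
        v = ph[c]
        cols[c] = v.map(SEX_CODES) if c == "sex" else pd.to_numeric(v, errors="coerce")
    design = pd.DataFrame(cols, index=ph.index)
    complete = design.notna().all(axis=1)
    design = design.loc[complete]

    class_counts = design["outcome"].value_counts()
    if len(class_counts) < 2 or class_counts.min() < 2:
        raise ValueError("need >= 2 samples in each outcome class")

    samples = design.index.tolist()
    Y = betas[samples].to_numpy(dtype=float)
    if use_mvalues:
        clipped = np.clip(Y, 1e-3, 1 - 1e-3)
        Y = np.log2(clipped / (1 - clipped))

    X = np.column_stack(
        [np.ones(len(samples)), design["outcome"].to_numpy()]
        + [design[c].to_numpy(dtype=float) for c in covariates]
    )
    n, p = X.shape
    if n <= p:
        raise ValueError("more parameters than samples")

    constant = Y.std(axis=1, ddof=0) == 0

    if model == "logistic":
        import statsmodels.api as sm

        eff = np.full(len(Y), np.nan)
        se = np.full(len(Y), np.nan)
        pv = np.full(len(Y), np.nan)
        Xcov = X[:, [0] + list(range(2, p))]  # intercept + covariates
        for i in range(len(Y)):
            if constant[i]:
                continue
            Xi = np.column_stack([Xcov[:, :1], Y[i], Xcov[:, 1:]])
            try:
                fit = sm.Logit(X[:, 1], Xi).fit(disp=0)
                eff[i], se[i], pv[i] = fit.params[1], fit.bse[1], fit.pvalues[1]
            except Exception:  # separation etc.
                pass
    elif model == "linear":
        xtx_inv = np.linalg.inv(X.T @ X)
        coef = Y @ X @ xtx_inv.T          # probes x p
        resid = Y - coef @ X.T
        dof = n - p
        sigma2 = (resid**2).sum(axis=1) / dof
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        eff = coef[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = eff / se
        pv = 2.0 * stats.t.sf(np.abs(tstat), dof)
        pv = np.where(constant | (se == 0), np.nan, pv)
        eff = np.where(constant, np.nan, eff)
        se = np.where(constant, np.nan, se)
    else:
        raise ValueError(f"unknown model: {model!r}")

    return pd.DataFrame(
        {"effect": eff, "se": se, "p": pv, "n": n, "constant": constant},
        index=pd.Index(betas.index, name="probe"),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m for m tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def discovery_replication(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    alpha: float = 0.05,
    nominal: float = 0.05,
    require_sign_concordance: bool = True,
) -> pd.DataFrame:
    """Two-stage validation of association results.

    A probe is ``discovery_pass`` when its discovery p <= alpha / m, with m
    the number of probes actually tested (non-missing p) in discovery. It is
    ``validated`` when it additionally shows replication p < ``nominal``
    and, unless disabled, an effect of the same sign in both stages.
    Probes present only in replication are ignored with a warning.
    """
    extra = sorted(set(replication.index) - set(discovery.index))
    if extra:
        warnings.warn(f"probes only in replication ignored: {extra}", stacklevel=2)

    m = int(discovery["p"].notna().sum())
    if m == 0:
        raise ValueError("no tested probes in discovery")
    threshold = bonferroni_threshold(alpha, m)

    out = discovery.copy()
    out["m_tested"] = m
    out["bonferroni_p"] = threshold
    out["discovery_pass"] = out["p"].le(threshold).fillna(False)

    rep = replication.reindex(discovery.index)
    out["replication_p"] = rep["p"]
    out["replication_effect"] = rep["effect"]
    rep_pass = rep["p"].lt(nominal).fillna(False)
    if require_sign_concordance:
        concordant = (np.sign(out["effect"]) == np.sign(rep["effect"])).fillna(False)
        rep_pass &= concordant
    out["replication_pass"] = rep_pass
    out["validated"] = out["discovery_pass"] & out["replication_pass"]
    return out
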