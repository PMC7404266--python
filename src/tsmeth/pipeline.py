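"""End-to-end orchestration: annotation -> expression -> Tau -> methylation
-> integration -> (enrichment) -> EWAS, from a single YAML config.

Every stage writes its table under the output directory together with a
provenance JSON (package version, thresholds, seed, input digests). A stage
failure aborts the run with the stage name; outputs of completed stages are
retained.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import ewas as ewas_mod
from .enrichment import overrepresentation_test, read_gmt
from .expression import filter_expressed, load_expression, log_transform
from .gene_model import derive_promoters, read_gene_model, write_bed
from .integration import (
    classify_correlations,
    cluster_methylation,
    correlate_expression_methylation,
)
from .methylation import (
    aggregate_region_methylation,
    promoter_methylation_summary,
    read_cpg_calls,
)
from .specificity import call_tsgs, tissue_means

__all__ = [
    "PipelineConfig",
    "StageError",
    "AnalysisReport",
    "run_pipeline",
    "direction_count_summary",
    "fraction_pct",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


@dataclass
class PipelineConfig:
    gtf: str = ""
    expression: str = ""
    sample_sheet: str = ""
    calls_dir: str = ""
    gmt: str | None = None
    ewas_betas: str | None = None
    ewas_manifest: str | None = None
    ewas_pheno: str | None = None
    ewas_replication_betas: str | None = None
    ewas_replication_pheno: str | None = None
    ewas_tissue: str | None = None      # default: tissue with the most TSGs
    tau_threshold: float = 0.8
    r_threshold: float = 0.3
    min_depth: int = 10
    min_cpgs: int = 1
    min_pairs: int = 10
    alpha: float = 0.05
    k: int = 5
    seed: int | None = None
    out_dir: str = "tsmeth_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not 0 < self.tau_threshold <= 1 or not 0 < self.r_threshold <= 1:
            raise ValueError("tau/r thresholds must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.seed is None:
            raise ValueError("a seed is required (K-means stage is stochastic)")


@dataclass
class AnalysisReport:
    n_genes: int
    n_expressed: int
    n_tau_eligible: int
    n_tsg: int
    n_tsg_per_tissue: dict[str, int]
    n_correlated: int
    n_negative: int
    n_positive: int
    direction_counts: pd.DataFrame = field(repr=False)   # tissue x direction
    methylation_summary_pct: dict[str, float] = field(default_factory=dict)
    n_discovery_pass: int | None = None
    n_validated: int | None = None
    enrichment_top: list[str] = field(default_factory=list)

    def summary_dict(self) -> dict:
        d = {
            "n_genes": self.n_genes,
            "n_expressed": self.n_expressed,
            "n_tau_eligible": self.n_tau_eligible,
            "n_tsg": self.n_tsg,
            "n_tsg_per_tissue": self.n_tsg_per_tissue,
            "methylation_summary_pct": self.methylation_summary_pct,
            **direction_count_summary(self.direction_counts),
        }
        if self.n_discovery_pass is not None:
            d["n_discovery_pass"] = self.n_discovery_pass
            d["n_validated"] = self.n_validated
        return d


def fraction_pct(part: float, whole: float) -> float:
    """part / whole as a percentage."""
    if whole == 0:
        raise ValueError("whole must be nonzero")
    return 100.0 * part / whole


def direction_count_summary(counts: pd.DataFrame) -> dict:
    """Accounting summary of a tissue x direction count table.

    ``counts`` has one row per tissue and columns ``negative`` and
    ``positive``. Column sums give the per-direction totals, their sum the
    total number of correlated genes, and the negative share is reported as
    a percentage.
    """
    n_negative = int(counts["negative"].sum())
    n_positive = int(counts["positive"].sum())
    n_correlated = n_negative + n_positive
    return {
        "n_negative": n_negative,
        "n_positive": n_positive,
        "n_correlated": n_correlated,
        "pct_negative": fraction_pct(n_negative, n_correlated) if n_correlated else float("nan"),
        "pct_positive": fraction_pct(n_positive, n_correlated) if n_correlated else float("nan"),
        "per_tissue": {
            t: {"negative": int(r["negative"]), "positive": int(r["positive"])}
            for t, r in counts.iterrows()
        },
    }


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(stage: str, path: str | None, what: str) -> Path:
    if not path:
        raise StageError(stage, f"missing {what} input")
    p = Path(path)
    if not p.exists():
        raise StageError(stage, f"{what} input not found: {p}")
    return p


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Run all stages; see module docstring. Returns the analysis report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs_seen: dict[str, str] = {}

    # ---- gene_model ----------------------------------------------------
    gtf_path = _require("gene_model", config.gtf, "GTF")
    inputs_seen["gtf"] = _digest(gtf_path)
    try:
        with open(gtf_path) as fh:
            model = read_gene_model(fh)
        promoters = {k: derive_promoters(model, k) for k in ("proximal", "typical", "expanded")}
        for kind, regs in promoters.items():
            with open(out / f"promoters_{kind}.bed", "w") as fh:
                write_bed(regs, fh)
    except StageError:
        raise
    except Exception as e:
        raise StageError("gene_model", str(e)) from e

    # ---- expression ----------------------------------------------------
    expr_path = _require("expression", config.expression, "expression matrix")
    sheet_path = _require("expression", config.sample_sheet, "sample sheet")
    inputs_seen["expression"] = _digest(expr_path)
    inputs_seen["sample_sheet"] = _digest(sheet_path)
    try:
        with open(expr_path) as mfh, open(sheet_path) as sfh:
            expr = load_expression(mfh, sfh)
        n_genes_in = len(expr.genes)
        expressed = filter_expressed(expr, "any_positive")
        logged = log_transform(expressed)
    except StageError:
        raise
    except Exception as e:
        raise StageError("expression", str(e)) from e

    # ---- specificity ---------------------------------------------------
    try:
        eligible = filter_expressed(expressed, "max_ge_one")
        profiles = tissue_means(eligible)
        tau = call_tsgs(profiles, config.tau_threshold)
        tau.to_csv(out / "tau.tsv", sep="\t")
        tsgs = tau[tau["is_tsg"]]
    except StageError:
        raise
    except Exception as e:
        raise StageError("specificity", str(e)) from e

    # ---- methylation ---------------------------------------------------
    calls_dir = _require("methylation", config.calls_dir, "CpG calls directory")
    try:
        calls_by_sample = {}
        for f in sorted(Path(calls_dir).glob("*.tsv")):
            with open(f) as fh:
                calls_by_sample[f.stem] = read_cpg_calls(fh, min_depth=config.min_depth)
        if not calls_by_sample:
            raise ValueError(f"no *.tsv call files in {calls_dir}")
        meth = aggregate_region_methylation(
            calls_by_sample,
            promoters["proximal"] + promoters["typical"],
            min_cpgs=config.min_cpgs,
        )
        meth.values.to_csv(out / "region_methylation.tsv", sep="\t")
        meth.n_cpgs.to_csv(out / "region_methylation_ncpgs.tsv", sep="\t")
        meth_summary = promoter_methylation_summary(
            meth.for_kind("proximal"), meth.for_kind("typical")
        )
    except StageError:
        raise
    except Exception as e:
        raise StageError("methylation", str(e)) from e

    # ---- integration ---------------------------------------------------
    try:
        prox = meth.for_kind("proximal")
        records = correlate_expression_methylation(
            logged.values.loc[logged.values.index.isin(tsgs.index)],
            prox,
            min_pairs=config.min_pairs,
        )
        records = classify_correlations(records, config.r_threshold)
        records["assigned_tissue"] = tsgs["assigned_tissue"].reindex(records.index)

        tissue_order = expr.tissue_order
        counts = pd.DataFrame(0, index=tissue_order, columns=["negative", "positive"])
        for direction in ("negative", "positive"):
            vc = records.loc[records["direction"] == direction, "assigned_tissue"].value_counts()
            for t, c in vc.items():
                counts.loc[t, direction] = int(c)

        negatives = records.index[records["direction"] == "negative"].tolist()
        if len(negatives) >= 2:
            clust = cluster_methylation(
                prox.loc[prox.index.isin(negatives)], k=config.k, seed=config.seed
            )
            records["cluster"] = clust.assignments.reindex(records.index)
        records.to_csv(out / "correlations.tsv", sep="\t")
    except StageError:
        raise
    except Exception as e:
        raise StageError("integration", str(e)) from e

    # ---- enrichment (optional) -----------------------------------------
    enrichment_top: list[str] = []
    if config.gmt:
        gmt_path = _require("enrichment", config.gmt, "GMT")
        inputs_seen["gmt"] = _digest(gmt_path)
        try:
            with open(gmt_path) as fh:
                coll = read_gmt(fh)
            background = set(expressed.genes)
            query = set(negatives) & background
            enr = overrepresentation_test(query, coll, background)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            enrichment_top = enr["set"].head(5).tolist()
        except StageError:
            raise
        except Exception as e:
            raise StageError("enrichment", str(e)) from e

    # ---- ewas (optional) -----------------------------------------------
    n_discovery_pass = n_validated = None
    if config.ewas_betas:
        betas_path = _require("ewas", config.ewas_betas, "beta matrix")
        manifest_path = _require("ewas", config.ewas_manifest, "probe manifest")
        pheno_path = _require("ewas", config.ewas_pheno, "phenotype table")
        inputs_seen["ewas_betas"] = _digest(betas_path)
        try:
            betas = ewas_mod.load_probe_matrix(str(betas_path))
            manifest = ewas_mod.load_manifest(str(manifest_path))
            pheno = ewas_mod.load_phenotypes(str(pheno_path))

            target = config.ewas_tissue
            if target is None:
                per_tissue = tsgs["assigned_tissue"].value_counts()
                if per_tissue.empty:
                    raise ValueError("no TSGs available to restrict the EWAS regions")
                target = per_tissue.index[0]
            target_genes = set(tsgs.index[tsgs["assigned_tissue"] == target])
            regions = [r for r in promoters["expanded"] if r.gene_id in target_genes]
            selected = ewas_mod.select_probes_in_regions(manifest, regions)
            probe_ids = selected.index.unique().tolist()
            if not probe_ids:
                raise ValueError(f"no probes fall in expanded promoters of {target} TSGs")

            disc = ewas_mod.dmp_association(betas.loc[probe_ids], pheno)
            if config.ewas_replication_betas:
                rep_betas = ewas_mod.load_probe_matrix(config.ewas_replication_betas)
                rep_pheno = ewas_mod.load_phenotypes(config.ewas_replication_pheno)
                rep = ewas_mod.dmp_association(rep_betas.loc[probe_ids], rep_pheno)
                result = ewas_mod.discovery_replication(disc, rep, alpha=config.alpha)
                n_validated = int(result["validated"].sum())
            else:
                thr = ewas_mod.bonferroni_threshold(config.alpha, int(disc["p"].notna().sum()))
                result = disc.copy()
                result["discovery_pass"] = result["p"].le(thr).fillna(False)
            gene_map = selected.groupby(level=0)["gene_id"].agg(",".join)
            result.insert(0, "gene", gene_map.reindex(result.index))
            result.to_csv(out / "ewas.tsv", sep="\t")
            n_discovery_pass = int(result["discovery_pass"].sum())
        except StageError:
            raise
        except Exception as e:
            raise StageError("ewas", str(e)) from e

    report = AnalysisReport(
        n_genes=n_genes_in,
        n_expressed=len(expressed.genes),
        n_tau_eligible=len(eligible.genes),
        n_tsg=int(tau["is_tsg"].sum()),
        n_tsg_per_tissue={
            t: int((tsgs["assigned_tissue"] == t).sum()) for t in expr.tissue_order
        },
        n_correlated=int((records["direction"] != "none").sum()),
        n_negative=int((records["direction"] == "negative").sum()),
        n_positive=int((records["direction"] == "positive").sum()),
        direction_counts=counts,
        methylation_summary_pct=meth_summary,
        n_discovery_pass=n_discovery_pass,
        n_validated=n_validated,
        enrichment_top=enrichment_top,
    )

    provenance = {
        "tsmeth_version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "input_sha256": inputs_seen,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    (out / "report.json").write_text(
        json.dumps(report.summary_dict(), indent=2, sort_keys=True)
    )
    return report
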