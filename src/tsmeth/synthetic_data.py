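"""Synthetic matched multi-omics and EWAS cohorts with planted truth.

Emulates the statistical structure the integration analysis assumes: five
tissues of matched samples; tissue-specific genes (TSGs) whose proximal
promoter methylation is coupled - negatively or positively - to expression;
a majority of null genes with hypomethylated promoters and no coupling; and
an obesity-style case/control methylation-array cohort (discovery plus an
independent replication set) with a handful of planted differentially
methylated probes.

Planted effects:

* TSG expression: high in the target tissue (log2(TPM+1) mean ``mu_on``),
  low elsewhere (``mu_off``); null genes are moderate everywhere.
* Coupled promoter methylation: levels drawn from Beta(2,18) (hypo) where
  expression is high under negative coupling and Beta(18,2) (hyper)
  elsewhere; reversed for positive coupling. Per-CpG values jitter around
  the region level.
* EWAS: per-probe baseline beta level with small within-group spread; true
  DMPs shift the case mean by ``delta_beta``.

Everything is deterministic given the seed: the same config and seed
produce byte-identical output files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "MultiomicsSim", "EwasSim", "simulate_multiomics", "simulate_ewas_cohort"]

DEFAULT_TISSUES = ("adipocyte", "fibroblast", "islet", "kidney", "smc")
CHROM = "chrS"
GENE_SPACING = 10_000
GENE_OFFSET = 10_000


@dataclass
class SimConfig:
    """Simulation parameters; all planted effects are exposed here."""

    # multi-tissue design
    n_tissues: int = 5
    samples_per_tissue: int = 10
    n_tsg_negative: int = 40
    n_tsg_positive: int = 20
    n_null_genes: int = 140
    single_exon_fraction: float = 0.05
    # expression on log2(TPM+1) scale
    mu_on: float = 6.0
    mu_off: float = 0.5
    mu_null: float = 3.0
    mu_null_sd: float = 1.5   # per-gene baseline spread of non-specific genes
    sigma: float = 0.5
    # methylation coupling
    beta_low: tuple[float, float] = (2.0, 18.0)
    beta_high: tuple[float, float] = (18.0, 2.0)
    beta_upstream: tuple[float, float] = (6.0, 14.0)
    cpg_jitter_sd: float = 0.03
    cpgs_per_promoter: int = 8
    depth_mean: float = 30.0
    # EWAS cohort
    n_cases: int = 200
    n_controls: int = 250
    rep_cases: int = 380
    rep_controls: int = 379
    n_probes: int = 500
    n_true_dmps: int = 3
    delta_beta: float = 0.08
    beta_sd: float = 0.03
    age_mean: float = 50.0
    age_sd: float = 8.0
    confound_age: bool = False
    age_slope: float = 0.002
    t2d_missing_rate: float = 0.05
    # mandatory
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.n_tissues < 2 or self.samples_per_tissue < 1:
            raise ValueError("need >= 2 tissues with >= 1 sample each")
        if min(self.n_tsg_negative, self.n_tsg_positive, self.n_null_genes) < 0:
            raise ValueError("gene counts must be >= 0")
        if self.n_true_dmps > self.n_probes:
            raise ValueError("n_true_dmps cannot exceed n_probes")
        for pair in (self.beta_low, self.beta_high, self.beta_upstream):
            if min(pair) <= 0:
                raise ValueError(f"invalid Beta parameters {pair}")

    @property
    def tissue_names(self) -> list[str]:
        if self.n_tissues == len(DEFAULT_TISSUES):
            return list(DEFAULT_TISSUES)
        return [f"tissue{i + 1}" for i in range(self.n_tissues)]


def _gene_layout(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Deterministic gene coordinates on one synthetic chromosome.

    Genes alternate strand; each has a 2-exon transcript (so proximal,
    typical and expanded promoters are all defined) except a planted
    fraction of single-exon genes exercising the degenerate expanded path.
    """
    n = cfg.n_tsg_negative + cfg.n_tsg_positive + cfg.n_null_genes
    classes = (
        ["tsg_negative"] * cfg.n_tsg_negative
        + ["tsg_positive"] * cfg.n_tsg_positive
        + ["null"] * cfg.n_null_genes
    )
    single = rng.random(n) < cfg.single_exon_fraction
    rows = []
    for i in range(n):
        base = GENE_OFFSET + i * GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        if single[i]:
            exons = ((base, base + 799),)
        elif strand == "+":
            exons = ((base, base + 199), (base + 1000, base + 1599))
        else:
            exons = ((base, base + 599), (base + 1400, base + 1599))
        tss = exons[0][0] if strand == "+" else exons[-1][1]
        target = cfg.tissue_names[i % cfg.n_tissues] if classes[i] != "null" else ""
        rows.append((f"G{i + 1:04d}", strand, tss, exons, classes[i], target))
    return pd.DataFrame(
        rows, columns=["gene_id", "strand", "tss", "exons", "class", "target_tissue"]
    )


def _gtf_text(layout: pd.DataFrame) -> str:
    buf = io.StringIO()
    for _, g in layout.iterrows():
        for k, (s, e) in enumerate(g["exons"], start=1):
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; exon_number "{k}";'
            buf.write(
                f"{CHROM}\tsim\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
    return buf.getvalue()


@dataclass
class MultiomicsSim:
    gtf_text: str
    expression: pd.DataFrame          # genes x samples, TPM
    sample_sheet: pd.DataFrame        # sample, tissue, batch
    calls_by_sample: dict[str, pd.DataFrame]
    truth_genes: pd.DataFrame         # gene_id, class, target_tissue
    config: SimConfig = field(repr=False, default=None)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "genes.gtf").write_text(self.gtf_text)
        self.expression.to_csv(out / "expression.tsv", sep="\t", float_format="%.4f")
        self.sample_sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
        calls_dir = out / "calls"
        calls_dir.mkdir(exist_ok=True)
        for sample, calls in self.calls_by_sample.items():
            calls.to_csv(calls_dir / f"{sample}.tsv", sep="\t", index=False,
                         float_format="%.6f")
        self.truth_genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)


def simulate_multiomics(config: SimConfig) -> MultiomicsSim:
    """Generate matched expression + per-CpG methylation data with truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tissues = config.tissue_names
    layout = _gene_layout(config, rng)
    n_genes = len(layout)

    samples, sheet_rows = [], []
    for t in tissues:
        for j in range(config.samples_per_tissue):
            s = f"{t}_{j + 1:02d}"
            samples.append(s)
            sheet_rows.append((s, t, f"b{j % 2 + 1}"))
    sample_sheet = pd.DataFrame(sheet_rows, columns=["sample", "tissue", "batch"])
    sample_tissue = np.array([sample_sheet.tissue[i] for i in range(len(samples))])

    # expression: log2(TPM+1)-scale means by class/tissue; non-specific genes
    # carry a per-gene baseline shared across tissues, as real transcriptomes do
    null_base = np.clip(
        rng.normal(config.mu_null, config.mu_null_sd, n_genes), 0.5, None
    )
    mu = np.empty((n_genes, len(samples)))
    for i, g in layout.iterrows():
        if g["class"] == "null":
            mu[i] = null_base[i]
        else:
            mu[i] = np.where(sample_tissue == g["target_tissue"], config.mu_on, config.mu_off)
    logexpr = rng.normal(mu, config.sigma)
    tpm = np.clip(np.exp2(logexpr) - 1.0, 0.0, None)
    expression = pd.DataFrame(tpm, index=pd.Index(layout.gene_id, name="gene_id"),
                              columns=samples)

    # region-level promoter methylation per gene x sample
    a_lo, b_lo = config.beta_low
    a_hi, b_hi = config.beta_high
    level = np.empty((n_genes, len(samples)))
    for i, g in layout.iterrows():
        if g["class"] == "tsg_negative":
            on = sample_tissue == g["target_tissue"]
            level[i] = np.where(on, rng.beta(a_lo, b_lo, len(samples)),
                                rng.beta(a_hi, b_hi, len(samples)))
        elif g["class"] == "tsg_positive":
            on = sample_tissue == g["target_tissue"]
            level[i] = np.where(on, rng.beta(a_hi, b_hi, len(samples)),
                                rng.beta(a_lo, b_lo, len(samples)))
        else:
            level[i] = rng.beta(a_lo, b_lo, len(samples))

    # CpG positions: coupled CpGs sit tight around the TSS (inside the
    # proximal window, outside the typical window); background CpGs sit in
    # the upstream typical window.
    m = config.cpgs_per_promoter
    prox_pos, up_pos = [], []
    for _, g in layout.iterrows():
        t = g["tss"]
        if g["strand"] == "+":
            prox_pos.append(np.linspace(t, t + 45, m).round().astype(int))
            up_pos.append(np.linspace(t - 1800, t - 300, m).round().astype(int))
        else:
            prox_pos.append(np.linspace(t - 45, t, m).round().astype(int))
            up_pos.append(np.linspace(t + 300, t + 1800, m).round().astype(int))

    a_up, b_up = config.beta_upstream
    calls_by_sample: dict[str, pd.DataFrame] = {}
    for j, sample in enumerate(samples):
        chunks = []
        for i, g in layout.iterrows():
            ratios_p = np.clip(
                level[i, j] + rng.normal(0.0, config.cpg_jitter_sd, m), 0.0, 1.0
            )
            ratios_u = np.clip(
                rng.beta(a_up, b_up, m) + rng.normal(0.0, config.cpg_jitter_sd, m),
                0.0, 1.0,
            )
            pos = np.concatenate([prox_pos[i], up_pos[i]])
            ratios = np.concatenate([ratios_p, ratios_u])
            depth = rng.poisson(config.depth_mean, 2 * m)
            chunks.append(pd.DataFrame({
                "chrom": CHROM,
                "pos": pos,
                "strand": np.where(np.arange(2 * m) % 2 == 0, "+", "-"),
                "context": "CG",
                "ratio": ratios,
                "eff_CT_count": depth,
            }))
        calls = pd.concat(chunks, ignore_index=True)
        calls_by_sample[sample] = calls.sort_values(
            ["chrom", "pos"], kind="mergesort"
        ).reset_index(drop=True)

    truth = layout[["gene_id", "class", "target_tissue"]].copy()
    return MultiomicsSim(_gtf_text(layout), expression, sample_sheet,
                         calls_by_sample, truth, config)


@dataclass
class EwasSim:
    discovery_betas: pd.DataFrame
    discovery_pheno: pd.DataFrame
    replication_betas: pd.DataFrame
    replication_pheno: pd.DataFrame
    manifest: pd.DataFrame            # probe, chrom, pos
    truth_probes: pd.DataFrame        # probe, is_dmp, delta
    config: SimConfig = field(repr=False, default=None)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.discovery_betas.to_csv(out / "discovery_betas.tsv", sep="\t",
                                    float_format="%.6f")
        self.discovery_pheno.to_csv(out / "discovery_pheno.tsv", sep="\t")
        self.replication_betas.to_csv(out / "replication_betas.tsv", sep="\t",
                                      float_format="%.6f")
        self.replication_pheno.to_csv(out / "replication_pheno.tsv", sep="\t")
        self.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        self.truth_probes.to_csv(out / "truth_probes.tsv", sep="\t", index=False)


def _beta_params(mean: np.ndarray, sd: float) -> tuple[np.ndarray, np.ndarray]:
    """Beta(a, b) matched to a target mean and common sd (moment matching)."""
    kappa = mean * (1 - mean) / sd**2 - 1
    kappa = np.maximum(kappa, 1.0)
    return mean * kappa, (1 - mean) * kappa


def _cohort(
    cfg: SimConfig,
    rng: np.random.Generator,
    n_cases: int,
    n_controls: int,
    prefix: str,
    probe_mu: np.ndarray,
    dmp_mask: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = n_cases + n_controls
    status = np.array(["case"] * n_cases + ["control"] * n_controls)
    if cfg.confound_age:
        age = np.where(status == "case",
                       rng.normal(cfg.age_mean + 4, cfg.age_sd, n),
                       rng.normal(cfg.age_mean - 4, cfg.age_sd, n))
    else:
        age = rng.normal(cfg.age_mean, cfg.age_sd, n)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    bmi = np.where(status == "case", rng.normal(30, 3, n), rng.normal(24, 3, n))
    t2d_p = 1.0 / (1.0 + np.exp(-0.3 * (bmi - 27)))
    t2d = np.where(rng.random(n) < t2d_p, "case", "control")
    t2d = np.where(rng.random(n) < cfg.t2d_missing_rate, "missing", t2d)

    is_case = (status == "case").astype(float)
    mean = probe_mu[:, None] + cfg.delta_beta * dmp_mask[:, None] * is_case[None, :]
    if cfg.confound_age:
        mean = mean + cfg.age_slope * (age - cfg.age_mean)[None, :]
    mean = np.clip(mean, 0.02, 0.98)
    a, b = _beta_params(mean, cfg.beta_sd)
    betas = rng.beta(a, b)

    sample_ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    probes = [f"cg{i + 1:06d}" for i in range(cfg.n_probes)]
    beta_df = pd.DataFrame(betas, index=pd.Index(probes, name="probe"),
                           columns=sample_ids)
    pheno = pd.DataFrame(
        {"status": status, "age": np.round(age, 2), "sex": sex,
         "bmi": np.round(bmi, 2), "t2d": t2d},
        index=pd.Index(sample_ids, name="sample"),
    )
    return beta_df, pheno


def simulate_ewas_cohort(config: SimConfig, regions=None) -> EwasSim:
    """Generate discovery + replication case/control beta matrices.

    ``regions`` (optional, a list of promoter regions) anchors probe
    positions inside given intervals so that region-restricted probe
    selection keeps every probe; otherwise probes are laid out sequentially
    on the synthetic chromosome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if config.seed is not None else None)

    probes = [f"cg{i + 1:06d}" for i in range(config.n_probes)]
    if regions:
        regs = list(regions)
        pos, chroms = [], []
        for i in range(config.n_probes):
            r = regs[i % len(regs)]
            pos.append(int(rng.integers(r.start + 1, r.end + 1)))  # 1-based in region
            chroms.append(r.chrom)
    else:
        pos = [1000 * (i + 1) for i in range(config.n_probes)]
        chroms = [CHROM] * config.n_probes
    manifest = pd.DataFrame({"probe": probes, "chrom": chroms, "pos": pos})

    probe_mu = rng.uniform(0.2, 0.8, config.n_probes)
    dmp_idx = rng.choice(config.n_probes, size=config.n_true_dmps, replace=False)
    dmp_mask = np.zeros(config.n_probes)
    dmp_mask[dmp_idx] = 1.0
    truth = pd.DataFrame({
        "probe": probes,
        "is_dmp": dmp_mask.astype(bool),
        "delta": dmp_mask * config.delta_beta,
    })

    disc_betas, disc_pheno = _cohort(
        config, rng, config.n_cases, config.n_controls, "D", probe_mu, dmp_mask
    )
    rep_betas, rep_pheno = _cohort(
        config, rng, config.rep_cases, config.rep_controls, "R", probe_mu, dmp_mask
    )
    return EwasSim(disc_betas, disc_pheno, rep_betas, rep_pheno, manifest, truth, config)
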