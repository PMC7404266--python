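import io
from pathlib import Path

import pytest

from tsmeth.gene_model import derive_promoters, read_gene_model
from tsmeth.pipeline import PipelineConfig, run_pipeline
from tsmeth.synthetic_data import SimConfig, simulate_ewas_cohort, simulate_multiomics

SEED = 11


@pytest.fixture(scope="session")
def sim():
    """Default-condition multi-omics simulation, fixed seed."""
    return simulate_multiomics(SimConfig(seed=SEED))


@pytest.fixture(scope="session")
def sim_model(sim):
    return read_gene_model(io.StringIO(sim.gtf_text))


@pytest.fixture(scope="session")
def ewas_sim(sim, sim_model):
    """EWAS cohorts with probes anchored in adipocyte TSG expanded promoters."""
    truth = sim.truth_genes
    adip = set(truth.gene_id[(truth["class"] != "null") & (truth.target_tissue == "adipocyte")])
    regions = [r for r in derive_promoters(sim_model, "expanded") if r.gene_id in adip]
    return simulate_ewas_cohort(SimConfig(seed=SEED), regions=regions)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, sim, ewas_sim):
    """Full pipeline executed once on the session simulation."""
    root = tmp_path_factory.mktemp("pipeline")
    mo, ew, out = root / "mo", root / "ew", root / "out"
    sim.write(mo)
    ewas_sim.write(ew)
    config = PipelineConfig(
        gtf=str(mo / "genes.gtf"),
        expression=str(mo / "expression.tsv"),
        sample_sheet=str(mo / "sample_sheet.tsv"),
        calls_dir=str(mo / "calls"),
        ewas_betas=str(ew / "discovery_betas.tsv"),
        ewas_manifest=str(ew / "manifest.tsv"),
        ewas_pheno=str(ew / "discovery_pheno.tsv"),
        ewas_replication_betas=str(ew / "replication_betas.tsv"),
        ewas_replication_pheno=str(ew / "replication_pheno.tsv"),
        ewas_tissue="adipocyte",
        seed=SEED,
        out_dir=str(out),
    )
    report = run_pipeline(config)
    return config, report, out
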