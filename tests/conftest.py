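import pathlib

import pandas as pd
import pytest

from panortho import (OrthogroupTable, PangenomeParams, PipelineConfig,
                      build_proteomes, generate_pangenome,
                      match_orfs_to_truth, read_genome_archive, run_pipeline)
from panortho.fixtures import write_pangenome

# Study conditions for the full-scale recovery run: 10 genomes x 100
# ancestral families, 10% gene loss, 2% per-site divergence.
FULL_PARAMS = PangenomeParams()
FULL_SEED = 7

SMALL_PARAMS = PangenomeParams(n_genomes=4, n_ancestral_genes=20)
SMALL_SEED = 11


@pytest.fixture(scope="session")
def small_pangenome():
    return generate_pangenome(SMALL_PARAMS, seed=SMALL_SEED)


@pytest.fixture(scope="session")
def small_archive(small_pangenome, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_pg")
    archive, truth = write_pangenome(small_pangenome, out)
    return archive


@pytest.fixture(scope="session")
def small_run(small_pangenome, small_archive, tmp_path_factory):
    """Pipeline results on the small synthetic pan-genome."""
    out = tmp_path_factory.mktemp("small_run")
    config = PipelineConfig(
        input_path=str(small_archive), output_dir=str(out / "results"), plots=True
    )
    result_dir = run_pipeline(config)
    return {
        "pangenome": small_pangenome,
        "archive": small_archive,
        "out": result_dir,
        "config": config,
    }


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """Full-scale synthetic recovery run (10 genomes x 100 families)."""
    pg = generate_pangenome(FULL_PARAMS, seed=FULL_SEED)
    out = tmp_path_factory.mktemp("full_pg")
    archive, _ = write_pangenome(pg, out)
    config = PipelineConfig(
        input_path=str(archive), output_dir=str(out / "results"), plots=True
    )
    result_dir = run_pipeline(config)
    genomes = read_genome_archive(archive)
    proteomes = build_proteomes(genomes)
    table = OrthogroupTable(
        pd.read_csv(
            result_dir / "iv_orthogroup_tables" / "orthogroups_table.csv",
            index_col=0,
        )
        .fillna("")
        .astype(str)
    )
    return {
        "pangenome": pg,
        "out": result_dir,
        "proteomes": proteomes,
        "table": table,
        "orf_to_gene": match_orfs_to_truth(proteomes, pg.truth),
    }
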