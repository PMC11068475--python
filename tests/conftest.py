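import numpy as np
import pandas as pd
import pytest

from gmebiome import synthetic_data as sd
from gmebiome import umi_amplicon as ua


@pytest.fixture(scope="session")
def tiny_design():
    return sd.StudyDesign(
        genotypes=("g1", "g2"), inoculants=("F5C", "F5S"),
        environments=("SALT", "CONTROL"),
        pots_per_combination=1, plants_per_pot=2,
    )


@pytest.fixture(scope="session")
def tiny_reference():
    return sd.generate_reference(n_taxa=8, seed=1)


@pytest.fixture(scope="session")
def clean_read_run(tmp_path_factory, tiny_design, tiny_reference):
    """Error-free, duplicate-free read simulation over a tiny design,
    processed through the UMI pipeline; used as an exactness oracle."""
    model = sd.default_community_model(n_taxa=8, seed=2)
    comp, meta = sd.simulate_communities(tiny_design, model, seed=3,
                                         samples_per_pot=1)
    cfg = sd.ReadSimConfig(per_base_error=0.0, mean_pcr_duplicates=0.0,
                           reads_per_sample=40, seed=4)
    outdir = tmp_path_factory.mktemp("clean_reads")
    r1, r2, log = sd.simulate_reads(comp, tiny_reference["reference"], cfg,
                                    outdir)
    records, plog = ua.process_fastq_pair(r1, r2, ua.AmpliconLayout())
    return {
        "composition": comp, "metadata": meta, "config": cfg,
        "r1": r1, "r2": r2, "log": log, "records": records, "plog": plog,
        "reference": tiny_reference,
    }


@pytest.fixture(scope="session")
def pheno_table():
    design = sd.StudyDesign()
    table = sd.simulate_phenotypes(design, sd.default_pheno_model(design),
                                   seed=7)
    return table[table["M"] != "NONE"].reset_index(drop=True)
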