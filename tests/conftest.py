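import numpy as np
import pandas as pd
import pytest

from regmeth.simulate import (
    SimulationConfig,
    generate_expression,
    generate_methylome,
    generate_region_sets,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11,
        n_cpgs=2000,
        n_genes=150,
        groups=(("A", 6), ("B", 6)),
        n_region_sets=20,
        region_set_size=200,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One small planted-effect data set shared by read-only tests."""
    beta, annotation, sheet, truth = generate_methylome(small_config)
    expression = generate_expression(beta, truth, annotation, small_config)
    regions = generate_region_sets(annotation, truth, small_config)
    return {
        "beta": beta,
        "annotation": annotation,
        "sheet": sheet,
        "truth": truth,
        "expression": expression,
        "regions": regions,
        "config": small_config,
    }


@pytest.fixture
def toy_trio(tmp_path):
    """Consistent 10-CpG x 4-sample beta/annotation/sheet file trio."""
    rng = np.random.default_rng(0)
    cpgs = [f"cg{i:03d}" for i in range(10)]
    samples = ["S1", "S2", "S3", "S4"]
    beta = pd.DataFrame(
        rng.uniform(0, 1, (10, 4)), index=cpgs, columns=samples
    )
    beta.index.name = "cpg_id"
    beta_path = tmp_path / "beta.tsv"
    beta.to_csv(beta_path, sep="\t")

    annot = pd.DataFrame(
        {
            "cpg_id": cpgs,
            "chrom": ["chr1"] * 10,
            "pos": np.arange(100, 1100, 100),
            "gene": ["GENE1"] * 5 + ["GENE1;GENE2"] * 2 + [""] * 3,
            "feature_group": ["TSS200"] * 5 + ["Body;TSS1500"] * 2 + [""] * 3,
            "cgi_relation": ["Island"] * 5 + ["OpenSea"] * 5,
        }
    )
    annot_path = tmp_path / "annotation.tsv"
    annot.to_csv(annot_path, sep="\t", index=False)

    sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "group": ["g1", "g1", "g2", "g2"],
            "condition": ["c", "c", "c", "c"],
            "patient_id": ["P1", "P2", "P1", "P2"],
        }
    )
    sheet_path = tmp_path / "samples.csv"
    sheet.to_csv(sheet_path, index=False)
    return {
        "beta": beta_path,
        "annotation": annot_path,
        "sheet": sheet_path,
        "dir": tmp_path,
        "beta_frame": beta,
    }
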