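import numpy as np
import pandas as pd
import pytest

from imprintase.simulate import SimulationConfig, simulate_cross_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Seeded 80-gene reciprocal-cross dataset shared across tests."""
    cfg = SimulationConfig(
        n_genes=80,
        snps_per_gene_mean=3.0,
        stock_divergence=0.3,
        shared_polymorphism_fraction=0.3,
        depth_mean=30.0,
        seed=11,
    )
    return cfg, simulate_cross_dataset(cfg)


@pytest.fixture()
def tiny_counts():
    """Hand-built 3-SNP count table with 2 parental + 4 F1 libraries."""
    meta = pd.DataFrame([
        dict(sample_id="LL1_1", role="parental", stock="LL1", dam_stock="LL1",
             sire_stock="LL1", tissue="fetal_brain", generation="P", sex="F"),
        dict(sample_id="LL2_1", role="parental", stock="LL2", dam_stock="LL2",
             sire_stock="LL2", tissue="fetal_brain", generation="P", sex="F"),
        *[
            dict(sample_id=f"F1_{dam}x{sire}_{i}", role="f1", stock="",
                 dam_stock=dam, sire_stock=sire, tissue="fetal_brain",
                 generation="F1", sex="F")
            for dam, sire in (("LL1", "LL2"), ("LL2", "LL1"))
            for i in (1, 2)
        ],
    ])
    rows = []
    rng = np.random.default_rng(5)
    for i, pos in enumerate((101, 205, 387)):
        row = {"chrom": "chr1", "pos": pos, "ref": "A", "alt": "G",
               "LL1_1:REF": 20, "LL1_1:ALT": 0, "LL2_1:REF": 0, "LL2_1:ALT": 18}
        for sid in meta.loc[meta["role"] == "f1", "sample_id"]:
            row[f"{sid}:REF"] = int(rng.integers(5, 15))
            row[f"{sid}:ALT"] = int(rng.integers(5, 15))
        rows.append(row)
    return pd.DataFrame(rows), meta
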