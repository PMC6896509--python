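import numpy as np
import pandas as pd
import pytest

import seqblup as sb
from seqblup.io_formats import GenotypeMatrix, SampleTable, VariantTable


@pytest.fixture(scope="session")
def small_pop():
    """One small three-group population shared by read-only tests."""
    cfg = sb.SimulationConfig(
        seed=42, n_per_group={"B0": 250, "B1": 150, "F1_B1xB0": 100},
        n_seq_variants=1000, n_hd_variants=500, n_array_variants=200,
        n_qtl=40, h2=0.35, n_chrom=3)
    return sb.simulate_population(cfg)


def make_genotypes(n, m, seed=0, missing_rate=0.0, chrom_count=1):
    """Random hard-call genotype matrix with valid variant metadata."""
    rng = np.random.default_rng(seed)
    dosage = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random((n, m)) < missing_rate
        # keep at least one observed entry per variant
        miss[0, :] = False
        dosage[miss] = -1
    per = m // chrom_count
    chrom, pos = [], []
    for c in range(chrom_count):
        k = per + (m % chrom_count if c == chrom_count - 1 else 0)
        chrom += [str(c + 1)] * k
        pos += sorted(rng.choice(10_000_000, size=k, replace=False) + 1)
    vt = VariantTable(pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "chrom": chrom, "pos_bp": pos,
        "allele_a1": "A", "allele_a2": "G"}))
    return GenotypeMatrix([f"s{i}" for i in range(n)], vt, dosage)


def make_samples(n, n_breeds=2, seed=0, phenotype=None):
    rng = np.random.default_rng(seed)
    props = np.zeros((n, n_breeds))
    props[np.arange(n), rng.integers(0, n_breeds, n)] = 1.0
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "sire_id": [f"sire{i % 7}" for i in range(n)],
        "dam_id": [f"dam{i}" for i in range(n)],
        "data_source": rng.choice(["a", "b"], n),
        "phenotype": rng.standard_normal(n) if phenotype is None else phenotype,
        "corrected_phenotype": np.nan,
        "role": "UNUSED",
    })
    for b in range(n_breeds):
        df[f"breed_{b}"] = props[:, b]
    return SampleTable(df)
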