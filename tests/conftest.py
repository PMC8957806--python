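import numpy as np
import pandas as pd
import pytest

from ctprs.genotypes import GenotypeMatrix


def make_gm(dosages, chrom="1", pos_start=1_000_000, pos_step=10_000,
            a1="A", a2="G", variant_ids=None, positions=None):
    """Small GenotypeMatrix from a samples x variants array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(m)]
    if positions is None:
        positions = pos_start + pos_step * np.arange(m)
    chroms = [chrom] * m if isinstance(chrom, str) else list(chrom)
    variants = pd.DataFrame({
        "variant_id": variant_ids,
        "chrom": chroms,
        "pos": np.asarray(positions, dtype=np.int64),
        "a1": [a1] * m if isinstance(a1, str) else list(a1),
        "a2": [a2] * m if isinstance(a2, str) else list(a2),
    })
    samples = np.array([f"s{i}" for i in range(n)])
    return GenotypeMatrix(samples, variants, dosages)


def hv_frame(gm, beta, p):
    """Harmonized-variant frame over all columns of ``gm``."""
    v = gm.variants
    return pd.DataFrame({
        "variant_id": v["variant_id"],
        "chrom": v["chrom"].astype(str),
        "pos": v["pos"],
        "col": np.arange(len(v)),
        "beta": np.asarray(beta, dtype=float),
        "p": np.asarray(p, dtype=float),
        "flip": False,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
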