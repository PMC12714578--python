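import numpy as np
import pandas as pd
import pytest

from cesscan.config import SyntheticConfig
from cesscan.synthetic import simulate_rate_table


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(seed=42, n_genes=30, sites_per_gene=800)


@pytest.fixture(scope="session")
def small_sites(small_config) -> pd.DataFrame:
    return simulate_rate_table(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def toy_site_table() -> pd.DataFrame:
    """Ten hand-annotated sites covering every filtering rule."""
    rows = [
        # chrom pos ref alt gene  consequence     lof_conf quality mu    am
        ("1", 10, "A", "G", "GA", "synonymous",    "none", "high", 1.0, np.nan),
        ("1", 11, "C", "T", "GA", "synonymous",    "none", "low",  2.0, np.nan),   # fails quality
        ("1", 12, "G", "A", "GA", "missense",      "none", "high", 1.5, 0.30),
        ("1", 13, "T", "C", "GA", "missense",      "none", "high", 0.5, 0.10),     # am == 0.1 excluded
        ("1", 14, "A", "C", "GB", "missense",      "none", "TFBS", 3.0, 0.95),
        ("1", 15, "C", "G", "GB", "missense",      "none", "high", 1.0, np.nan),   # no score
        ("1", 16, "G", "T", "GB", "stop_gained",   "high", "high", 4.0, np.nan),
        ("1", 17, "T", "A", "GB", "stop_gained",   "low",  "high", 1.0, np.nan),   # low confidence
        ("1", 18, "A", "T", "GC", "splice_donor",  "high", "TFBS", 2.0, np.nan),
        ("1", 19, "C", "A", "GC", "other",         "none", "high", 1.0, np.nan),
    ]
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "gene_id", "consequence",
        "lof_confidence", "quality", "mu", "am_score"])


@pytest.fixture()
def toy_sites() -> pd.DataFrame:
    return toy_site_table()
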