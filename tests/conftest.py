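import numpy as np
import pandas as pd
import pytest

from blockcnn.features import BlockFeatureMatrix


def make_matrix(
    block_id: str,
    X,
    label: int = 1,
    lead_index: int = 0,
    feature_prefix: str = "f",
) -> BlockFeatureMatrix:
    """Small helper: wrap a dense 0/1 array as a BlockFeatureMatrix."""
    X = np.asarray(X, dtype=np.int8)
    return BlockFeatureMatrix(
        block_id=block_id,
        snp_ids=[f"{block_id}_s{j}" for j in range(X.shape[1])],
        feature_ids=[f"{feature_prefix}{m}" for m in range(X.shape[0])],
        X=X,
        label=label,
        lead_index=lead_index,
    )


@pytest.fixture
def toy_stats() -> pd.DataFrame:
    """Five SNPs on one chromosome with distinct P values."""
    return pd.DataFrame(
        {
            "SNP": ["rs1", "rs2", "rs3", "rs4", "rs5"],
            "CHR": ["1"] * 5,
            "BP": [1_000_000, 1_500_000, 3_000_000, 3_100_000, 9_000_000],
            "P": [1e-8, 1e-9, 1e-7, 2e-4, 0.2],
        }
    )
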