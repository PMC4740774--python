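from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from snpsignal import GenotypeMatrix, SampleMetadata


def make_matrix(rows: list[list[int]], sample_ids=None, n_alts=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a list of per-sample code rows.

    ``n_alts`` optionally gives the ALT allele count per variant (default 1;
    use >1 for multiallelic toy variants).
    """
    calls = np.asarray(rows, dtype=np.int32)
    n_samples, n_variants = calls.shape
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    if n_alts is None:
        n_alts = [1] * n_variants
    alphabet = ["C", "G", "T", "AC", "AG"]
    variants = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_variants,
            "pos": list(range(100, 100 + n_variants)),
            "ref": ["A"] * n_variants,
            "alt": [tuple(alphabet[:na]) for na in n_alts],
        }
    )
    return GenotypeMatrix(sample_ids, variants, calls)


def make_metadata(index: list[str], multilabel=(), **columns) -> SampleMetadata:
    table = pd.DataFrame(dict(columns), index=pd.Index(index, name="sample"))
    for col in multilabel:
        table[col] = table[col].map(frozenset)
    return SampleMetadata(table, set(multilabel))


@pytest.fixture
def toy_matrix() -> GenotypeMatrix:
    # 5 samples x 4 variants; variant 3 has a missing call, variant 4 is monomorphic
    return make_matrix(
        [
            [0, 1, 0, 0],
            [0, 1, 1, 0],
            [1, 2, 1, 0],
            [1, 2, -1, 0],
            [2, 0, 1, 0],
        ]
    )
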