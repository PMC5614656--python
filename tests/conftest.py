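import numpy as np
import pandas as pd
import pytest

from splicestat.expression_io import GeneIsoformProfile


@pytest.fixture
def cufflinks_file(tmp_path):
    """Toy Cuffdiff-style isoforms.fpkm_tracking with three transcripts."""
    df = pd.DataFrame(
        {
            "tracking_id": ["T1", "T2", "T3"],
            "gene_id": ["G1", "G1", "G2"],
            "FPKM": [6.0, 3.0, 5.0],
            "FPKM_status": ["OK", "OK", "OK"],
        }
    )
    path = tmp_path / "isoforms.fpkm_tracking"
    df.to_csv(path, sep="\t", index=False)
    return path, df


@pytest.fixture
def salmon_file(tmp_path):
    """Toy Salmon quant.sf plus its transcript-to-gene map."""
    df = pd.DataFrame(
        {
            "Name": ["T1", "T2", "T3"],
            "Length": [1000, 800, 1200],
            "EffectiveLength": [800.0, 600.0, 1000.0],
            "TPM": [6.0, 3.0, 1.0],
            "NumReads": [30.0, 12.0, 6.0],
        }
    )
    path = tmp_path / "quant.sf"
    df.to_csv(path, sep="\t", index=False)
    return path, df, {"T1": "G1", "T2": "G1", "T3": "G1"}


def make_profile(gene, freqs, sample="s1", condition="rest", ids=None):
    freqs = np.asarray(freqs, dtype=float)
    ids = tuple(ids) if ids else tuple(f"{gene}.T{i + 1}" for i in range(len(freqs)))
    return GeneIsoformProfile(
        gene_id=gene,
        sample_id=sample,
        condition=condition,
        M=len(freqs),
        isoform_ids=ids,
        expressions=freqs,
        frequencies=freqs,
    )
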