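import numpy as np
import pandas as pd
import pytest

from protmr.sumstats import AssocRecord


@pytest.fixture
def small_sumstats_tsv(tmp_path):
    """Well-formed 3-row summary-statistics file."""
    path = tmp_path / "ss.tsv"
    pd.DataFrame({
        "rsid": ["rs1", "rs2", "rs3"],
        "chr": ["1"] * 3,
        "pos": [100, 200, 300],
        "ea": ["A", "C", "T"],
        "oa": ["G", "T", "C"],
        "eaf": [0.3, 0.4, 0.2],
        "beta": [0.1, -0.2, 0.05],
        "se": [0.02, 0.05, 0.01],
        "pval": [5.7e-7, 6.3e-5, 5.7e-7],
        "n": [35000] * 3,
    }).to_csv(path, sep="\t", index=False)
    return path


def make_record(rsid="rs1", ea="A", oa="G", beta=0.3, se=0.05, eaf=0.3,
                pos=100, chrom="1", **kw):
    return AssocRecord(rsid=rsid, chr=chrom, pos=pos, ea=ea, oa=oa,
                       beta=beta, se=se, eaf=eaf, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
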