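import numpy as np
import pandas as pd
import pytest

from divergene.twocolor import MASet
from divergene.variants import GeneModel


@pytest.fixture
def toy_model():
    """Two-exon plus-strand gene with 10 bp 5'UTR and CDS through exon 2."""
    return GeneModel(
        name="toy", chromosome="1", strand="+", tss_genomic=1000,
        promoter_bp=500, der_bp=300,
        exons=[(1, 100), (201, 300)],
        cds_mrna=(11, 190),
        cds_sequence="ATG" + "TCTGAAGGC" * 19 + "GAATAA",  # 180 nt, starts Met
    )


def make_maset(m, a=None, block=None, state="raw", orientation="HAB",
               array_id="t"):
    """Hand-construct an MASet around given M values."""
    m = np.asarray(m, float)
    a = np.full(m.shape, 10.0) if a is None else np.asarray(a, float)
    block = np.zeros(m.shape, int) if block is None else np.asarray(block, int)
    r = 2.0 ** (a + m / 2.0)
    g = 2.0 ** (a - m / 2.0)
    return MASet(
        probe_id=np.array([f"P{i}" for i in range(m.size)], dtype=object),
        block=block, R=r, G=g, M=m.copy(), A=a,
        usable=np.isfinite(m), orientation=orientation, array_id=array_id,
        state=state,
    )


@pytest.fixture
def de_table_factory():
    """Build a minimal per-region DE table from probe -> (fold_pct, p_adj)."""
    def build(entries):
        return pd.DataFrame(
            [(p, f, q) for p, (f, q) in entries.items()],
            columns=["probe_id", "fold_pct", "p_adj"],
        )
    return build
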