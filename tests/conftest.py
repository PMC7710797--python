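import numpy as np
import pandas as pd
import pytest

from mr2s import HarmonizedInstruments, SummaryTable


def make_h(gamma, Gamma, sigma_x=1e-6, sigma_y=0.01, eaf=0.3,
           n_exposure=None, n_outcome=None) -> HarmonizedInstruments:
    """Harmonized instruments from plain arrays, for estimator-level tests."""
    gamma = np.asarray(gamma, dtype=float)
    k = len(gamma)
    as_arr = lambda x: np.broadcast_to(np.asarray(x, dtype=float), (k,)).copy()
    return HarmonizedInstruments(
        snp_id=np.array([f"s{i:03d}" for i in range(k)], dtype=object),
        gamma=gamma, sigma_x=as_arr(sigma_x),
        Gamma=np.asarray(Gamma, dtype=float), sigma_y=as_arr(sigma_y),
        eaf=as_arr(eaf),
        flags=pd.DataFrame({"flipped": [False] * k, "palindromic": [False] * k,
                            "proxy": [""] * k}),
        drops=pd.DataFrame(columns=["snp_id", "reason"]),
        n_exposure=None if n_exposure is None else as_arr(n_exposure),
        n_outcome=None if n_outcome is None else as_arr(n_outcome),
    )


def make_table(rows, label="trait") -> SummaryTable:
    """SummaryTable from (snp_id, ea, oa, eaf, beta, se[, pvalue[, n]]) tuples."""
    recs = []
    for r in rows:
        rec = {"snp_id": r[0], "effect_allele": r[1], "other_allele": r[2],
               "eaf": r[3], "beta": r[4], "se": r[5]}
        rec["pvalue"] = r[6] if len(r) > 6 else 1e-10
        rec["n"] = r[7] if len(r) > 7 else 20000.0
        recs.append(rec)
    return SummaryTable(label, pd.DataFrame(recs))


@pytest.fixture
def toy3() -> HarmonizedInstruments:
    """Three instruments with equal Wald-ratio weights 100 and ratios
    (0.2, 0.25, 0.2): the hand-checkable IVW worked instance."""
    return make_h(gamma=[0.1, 0.1, 0.1], Gamma=[0.02, 0.025, 0.02],
                  sigma_x=1e-6, sigma_y=0.01)
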