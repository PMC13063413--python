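import numpy as np
import pandas as pd
import pytest

from kbench import RateMatrix


def make_matrix(rows: dict, sites=None) -> RateMatrix:
    """Build a RateMatrix from {chemical: [log10 k values]} with None = missing."""
    lengths = {len(v) for v in rows.values()}
    assert len(lengths) == 1
    n = lengths.pop()
    if sites is None:
        sites = [f"s{j + 1}" for j in range(n)]
    data = {c: [np.nan if v is None else float(v) for v in vals] for c, vals in rows.items()}
    return RateMatrix(pd.DataFrame.from_dict(data, orient="index", columns=sites))


@pytest.fixture
def parallel_pair() -> RateMatrix:
    """Two chemicals whose log k profiles differ by a constant offset.

    Values are exact binary fractions so the offset is exactly constant in
    floating point and the perfect-benchmark limit holds exactly.
    """
    return make_matrix({"A": [0.0, 1.0, 2.0, 0.5], "B": [0.5, 1.5, 2.5, 1.0]})


@pytest.fixture
def rate_table_csv(tmp_path):
    """A small well-formed long-format rate table on disk."""
    path = tmp_path / "rates.csv"
    path.write_text(
        "chemical_id,site_id,k,valid,pH,f_dissolved,toc,replicate_stddev\n"
        "DIU,s1,1.0,TRUE,7.0,1.0,2.0,0.1\n"
        "DIU,s2,10.0,TRUE,7.5,0.5,4.0,0.05\n"
        "FFA,s1,0.1,TRUE,7.0,1.0,2.0,\n"
        "FFA,s2,0.2,FALSE,7.5,1.0,4.0,\n"
    )
    return path


def random_gappy_logk(rng, n_chem, n_site, p_missing=0.25) -> dict:
    """Random {chemical: {site: value-or-None}} for oracle comparisons."""
    chems = [f"C{i}" for i in range(n_chem)]
    sites = [f"s{j}" for j in range(n_site)]
    return {
        c: {
            s: (None if rng.random() < p_missing else float(rng.normal(0, 1)))
            for s in sites
        }
        for c in chems
    }


def logk_dict_to_matrix(logk: dict) -> RateMatrix:
    sites = sorted(next(iter(logk.values())).keys())
    data = {
        c: [np.nan if row[s] is None else row[s] for s in sites]
        for c, row in logk.items()
    }
    return RateMatrix(pd.DataFrame.from_dict(data, orient="index", columns=sites))
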