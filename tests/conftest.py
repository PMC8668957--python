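import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from wheatdiv.matrix import ChromosomeTable, GenotypeMatrix, make_accession_frame

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

TOKEN = {"AA": 0, "AB": 1, "BB": 2, "NN": -1}


def build_gm(call_rows, chroms=None, positions=None, acc_ids=None, marker_ids=None,
             chrono_class="landrace", country=None, region=None, western_flag=False):
    """Small-panel builder: one row of AA/AB/BB/NN tokens per accession."""
    n = len(call_rows)
    m = len(call_rows[0])
    acc_ids = acc_ids or [f"acc{i}" for i in range(n)]
    marker_ids = marker_ids or [f"m{j}" for j in range(m)]
    chroms = chroms or ["1A"] * m
    positions = positions or [100 * (j + 1) for j in range(m)]
    markers = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "allele_a": "A", "allele_b": "G"},
        index=pd.Index(marker_ids, name="marker_id"),
    )
    acc = make_accession_frame(acc_ids, country=country, region=region,
                               chrono_class=chrono_class, western_flag=western_flag)
    calls = np.array([[TOKEN[t] for t in row] for row in call_rows], dtype=np.int8)
    return GenotypeMatrix(acc, markers, calls)


def tiny_chrom_table(length_bp=1000):
    """A 21-row chromosome table with uniform short lengths for hand examples."""
    rows = {
        f"{g}{s}": {"genome": s, "homoeo_group": g, "length_bp": length_bp}
        for g in range(1, 8)
        for s in "ABD"
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "name"
    return ChromosomeTable(df)


def random_gm(rng, n_acc=20, n_markers=30, missing_rate=0.05, het_rate=0.05,
              chroms=None, **meta):
    tokens = ["AA", "BB", "AB", "NN"]
    probs = [
        (1 - missing_rate - het_rate) / 2,
        (1 - missing_rate - het_rate) / 2,
        het_rate,
        missing_rate,
    ]
    rows = [
        [tokens[k] for k in rng.choice(4, size=n_markers, p=probs)] for _ in range(n_acc)
    ]
    positions = sorted(rng.choice(10**6, size=n_markers, replace=False).tolist())
    return build_gm(rows, chroms=chroms, positions=positions, **meta)


@pytest.fixture(scope="session")
def study_panel():
    """Scaled-down default-recipe panel shared by read-only tests."""
    from wheatdiv.simulate import default_panel_config, simulate_panel

    config = default_panel_config(seed=424)
    config.n_markers = 1200
    return simulate_panel(config)
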