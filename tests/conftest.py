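import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from linkbias.synthetic_data import ScenarioConfig, generate_gold_standard


@pytest.fixture(scope="session")
def small_gold():
    """A small shared gold-standard file pair (400 admissions, 25% match)."""
    cfg = ScenarioConfig(name="small", n_admissions=400, n_micro=400,
                         match_rate=0.25, error_rate=0.10, seed=17)
    adm, mic, truth = generate_gold_standard(cfg)
    return cfg, adm, mic, truth


def toy_pairs(rows):
    """Build a PairSet DataFrame from (admission_id, micro_id, weight[, extra]) rows.

    ``rows`` is a list of dicts; missing date columns get deterministic
    defaults so tie-break sorting is well defined.
    """
    from linkbias.linkage_core import PairSet
    df = pd.DataFrame(rows)
    if "admission_date" not in df:
        df["admission_date"] = pd.Timestamp("2005-01-01")
    if "specimen_date" not in df:
        df["specimen_date"] = pd.Timestamp("2005-01-05")
    if "pattern" not in df:
        df["pattern"] = "AAAAA"
    return PairSet(df=df, blocking="none")


@pytest.fixture
def make_pairs():
    return toy_pairs
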