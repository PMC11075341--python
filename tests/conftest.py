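import numpy as np
import pandas as pd
import pytest

from actipheno import behaviors as bh
from actipheno import patterns as pt
from actipheno import preprocess as pp
from actipheno import synthetic as syn

BEHAVIOR_NAME_MAP = {
    "AD_dom": "AD dominant",
    "M_dom": "M dominant",
    "ADM_dom": "AD+M dominant",
    "E_dom": "E dominant",
}


@pytest.fixture(scope="session")
def templates():
    return syn.default_templates()


@pytest.fixture(scope="session")
def recovery_run():
    """Full pipeline on the default synthetic cohort (n=200), run once.

    Returns truth tables plus the named day-pattern and behavior assignments,
    shared by the planted-recovery and behavior-property tests.
    """
    cfg = syn.SimConfig(seed=0)
    activity, cohort, truth = syn.simulate_cohort(cfg)
    std, report = pp.preprocess(activity)
    Z = std[pp.HOUR_COLUMNS].to_numpy(dtype=float)
    K = pt.compute_gram(Z)
    result = pt.kernel_kmeans(K, 5, seed=0, n_init=10)
    result = pt.name_pattern_clusters(result, Z, syn.default_templates())
    assign = std[["participant_id", "day_index"]].copy()
    assign["pattern_name"] = result.named_labels()
    profiles = bh.behavior_profiles(assign)
    behavior_df, b_assign = bh.cluster_behaviors(profiles, seed=0)
    return {
        "cfg": cfg,
        "truth": truth,
        "std": std,
        "Z": Z,
        "report": report,
        "pattern_result": result,
        "assignments": assign,
        "profiles": profiles,
        "behaviors": behavior_df,
        "behavior_assignment": b_assign,
    }


@pytest.fixture()
def week_df():
    """A tiny hand-built long activity table: 2 complete weeks + 1 incomplete."""
    rng = np.random.default_rng(42)
    frames = []
    for pid, days in [("A", 7), ("B", 7), ("C", 6)]:
        for d in range(1, days + 1):
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "day_index": d,
                        "minute_of_day": np.arange(1440),
                        "count": rng.poisson(5.0, 1440),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
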