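import numpy as np
import pandas as pd
import pytest

from fearcond.lmm import RandomInterceptLMM
from fearcond.synthetic import cumulative_logit_probs
from fearcond.task_design import default_protocol, make_schedule


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def acquisition_schedule(protocol):
    return make_schedule(protocol["acquisition"], rng_seed=1)


def make_lmm_dataset(n_subjects=40, n_trials=10, beta_cs=0.0, beta_trial=0.0,
                     beta_interaction=0.0, intercept=0.5, tau=0.2, sigma=0.25,
                     seed=0, groups=None, beta_group=0.0):
    """Balanced two-CS trial table from the LMM's own generative model."""
    rng = np.random.default_rng(seed)
    rows = []
    b = rng.normal(0, tau, n_subjects)
    for i in range(n_subjects):
        grp = groups[i % len(groups)] if groups else "adolescent"
        goff = beta_group if grp == "child" else 0.0
        for cs in ("CS+", "CS-"):
            iscs = 1.0 if cs == "CS+" else 0.0
            for t in range(1, n_trials + 1):
                mu = (intercept + beta_cs * iscs + beta_trial * t
                      + beta_interaction * iscs * t + goff + b[i])
                rows.append({
                    "subject": f"s{i:03d}", "group": grp, "phase": "acquisition",
                    "cs": cs, "trial": t,
                    "scr_sqrt": mu + rng.normal(0, sigma),
                })
    return pd.DataFrame(rows)


def draw_ordinal(eta, thresholds, rng):
    p = cumulative_logit_probs(eta, thresholds)
    return int(rng.choice(len(p), p=p)) + 1
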