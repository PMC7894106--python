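import numpy as np
import pandas as pd
import pytest

from mcbsurv.data_io import BetaMatrix, SurvivalTable


def make_surv(time, event, ids=None, covariates=None) -> SurvivalTable:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if ids is None:
        ids = [f"s{i}" for i in range(len(time))]
    df = pd.DataFrame({"time_days": time, "event": event}, index=pd.Index(ids, name="sample"))
    if covariates is not None:
        df = df.join(pd.DataFrame(covariates, index=ids))
    return SurvivalTable(df)


def random_beta(rng, n_probes, n_samples, probe_prefix="cg") -> BetaMatrix:
    vals = rng.uniform(0.0, 0.999, size=(n_probes, n_samples))
    return BetaMatrix(
        pd.DataFrame(
            vals,
            index=[f"{probe_prefix}{i:04d}" for i in range(n_probes)],
            columns=[f"s{i:03d}" for i in range(n_samples)],
        )
    )


def simulate_ph_cohort(rng, x, log_hr, baseline=1e-3, censor_frac=0.2):
    """Exponential proportional-hazards times driven by covariate x."""
    n = len(x)
    rate = baseline * np.exp(log_hr * (x - x.mean()))
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / (baseline * censor_frac * 2 + 1e-12), size=n) if censor_frac else np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_surv():
    return make_surv([100, 200, 300, 400, 500], [1, 1, 0, 1, 0])
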