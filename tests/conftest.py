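import numpy as np
import pandas as pd
import pytest

import validmr as v


@pytest.fixture(scope="session")
def small_cfg():
    return v.TrueModelConfig(n_individuals=600, n_snps=200, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """(panel, exposure_gwas, outcome_gwas, phenotypes) for a 600 x 200 cohort."""
    return v.simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_grid(small_cfg, small_cohort):
    panel, exp, out, _ = small_cohort
    return v.build_instrument_grid(exp, out, panel)


def make_panel_frame(values: dict, sex=None, site=None):
    """Build a minimal long-format phenotype panel from {wave: {col: vector}}."""
    waves = list(values)
    n = len(next(iter(next(iter(values.values())).values())))
    ids = [f"P{i:03d}" for i in range(n)]
    rows = []
    for w in waves:
        df = pd.DataFrame({"participant_id": ids, "wave": w})
        for col, vec in values[w].items():
            df[col] = np.asarray(vec, dtype=float)
        df["sex"] = sex if sex is not None else np.zeros(n, dtype=int)
        df["site"] = site if site is not None else ["site1"] * n
        df["present"] = True
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


@pytest.fixture
def panel_factory():
    return make_panel_frame
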