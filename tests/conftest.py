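import numpy as np
import pandas as pd
import pytest

from mrcausal import SimulationConfig, harmonize, select_instruments, simulate_two_sample


def sim_harmonized(cfg: SimulationConfig, select: bool = True):
    """Simulate one two-sample pair and run it through the standard pipeline."""
    exposure, outcome, truth = simulate_two_sample(cfg)
    if select:
        kept = select_instruments(exposure)
        exposure = exposure.loc[exposure["snp"].isin(kept)]
    return harmonize(exposure, outcome), truth


def gwas_table(snp, ea, oa, eaf, beta, se, n=10_000, pval=None):
    """Assemble a GWAS-dialect DataFrame from parallel lists."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if pval is None:
        from scipy import stats

        pval = np.clip(2 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    return pd.DataFrame(
        {
            "snp": snp,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
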