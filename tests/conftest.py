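import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dietmr import synthcohort as sc

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

logging.getLogger("dietmr.ivbuild").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_geno():
    """1,000 samples x 50 HWE variants, moderate MAF."""
    return sc.simulate_genotypes(1000, 50, (0.1, 0.5), hwe=True, seed=1)


@pytest.fixture(scope="session")
def study():
    """A mid-sized cohort with one heritable protective trait.

    n=6,000, M=600, fruit-like trait (h2=0.10, 25 causal variants,
    HR 0.8 per serving) plus a latent confounder shared with the hazard.
    """
    n, M = 6000, 600
    geno = sc.simulate_genotypes(n, M, (0.05, 0.5), seed=11)
    rng = np.random.default_rng(12)
    causal = list(rng.choice(geno.variants["id"], 25, replace=False))
    arch = sc.TrueArchitecture(
        traits={
            "total_fruit": sc.TraitArchitecture(
                causal, rng.normal(0, 1, 25), h2=0.10, log_hr=np.log(0.8), mean=2.25
            )
        }
    )
    kin = sc.make_families(n, block_size=4, icc=0.05)
    traits, covars, decomp = sc.simulate_traits(geno, arch, kin, seed=13)
    outcome = sc.simulate_outcome(traits, covars, arch, seed=14, target_event_fraction=0.10)
    return {
        "geno": geno,
        "arch": arch,
        "kin": kin,
        "traits": traits,
        "covars": covars,
        "decomp": decomp,
        "outcome": outcome,
    }
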