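"""End-to-end synthetic MR study orchestration.

Wires the modules together for one replicate: simulate a cohort, scan the
trait, clump loci into instruments, build the weighted allele score, and
estimate the causal hazard ratio by 2SLS-Cox alongside the observational
Cox fit.  Used by calibration/recovery experiments and the worked example.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import gwas, ivbuild, mrcore, obscox
from . import synthcohort as sc

__all__ = ["run_synthetic_study"]


def run_synthetic_study(
    n_samples: int = 20_000,
    n_variants: int = 2_000,
    n_causal: int = 60,
    h2: float = 0.08,
    hr_per_unit: float = 0.8,
    confounder_effect: float = 0.0,
    confounder_log_hr: float = 0.0,
    target_event_fraction: float = 0.10,
    trait_name: str = "total_fruit",
    p_threshold: float = 5e-8,
    family_block_size: int = 4,
    family_icc: float = 0.05,
    seed: int = 0,
    adjust_covariates: tuple[str, ...] = ("age", "sex"),
    with_observational: bool = True,
    allow_weak: bool = False,
) -> dict:
    """Run one synthetic one-sample MR replicate end to end.

    Returns a dict with the 2SLS-Cox estimate (``mr``), the univariate
    observational estimate (``observational``), instrument metadata and
    the intermediate tables.  Raises if no genome-wide-significant locus
    survives (no instrument can be built).
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(4)]
    geno = sc.simulate_genotypes(n_samples, n_variants, (0.05, 0.5), seed=seeds[0])
    rng = np.random.default_rng(seeds[1])
    causal = list(rng.choice(geno.variants["id"], n_causal, replace=False))
    arch = sc.TrueArchitecture(
        traits={
            trait_name: sc.TraitArchitecture(
                causal,
                rng.normal(0, 1, n_causal),
                h2=h2,
                confounder_effect=confounder_effect,
                log_hr=float(np.log(hr_per_unit)),
                mean=2.25,
            )
        },
        confounder_log_hr=confounder_log_hr,
    )
    kin = sc.make_families(n_samples, block_size=family_block_size, icc=family_icc)
    traits, covars, decomp = sc.simulate_traits(geno, arch, kin, seed=seeds[2])
    outcome = sc.simulate_outcome(
        traits, covars, arch, seed=seeds[3], target_event_fraction=target_event_fraction
    )
    cov = covars[list(adjust_covariates)]
    stats = gwas.association_scan(traits[trait_name], geno, cov, kin=kin, trait_label=trait_name)
    loci = gwas.select_loci(stats, gwas.LociConfig(p_threshold=p_threshold))
    if loci.empty:
        raise RuntimeError("no genome-wide-significant locus: cannot build an instrument")
    ivs = ivbuild.build_instruments(trait_name, loci, geno)
    mr_est = mrcore.two_stage_cox(
        traits[trait_name],
        ivs.score,
        outcome,
        covars[["sex"]],
        allow_weak=allow_weak,
        trait_label=trait_name,
    )
    result = {
        "mr": mr_est,
        "n_loci": len(loci),
        "f_stat": mr_est.f_stat,
        "event_fraction": outcome.attrs["event_fraction"],
        "realized_h2": float(decomp.loc[trait_name, "realized_h2"]),
        "geno": geno,
        "traits": traits,
        "covars": covars,
        "outcome": outcome,
        "stats": stats,
        "loci": loci,
        "instruments": ivs,
        "arch": arch,
    }
    if with_observational:
        result["observational"] = obscox.cox_fit(
            trait_name, traits[trait_name], outcome, covars, mode="univariate"
        )
    return result
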