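"""Synthetic biobank-style cohort generator.

Produces the data structures the analysis pipeline assumes: a biallelic
dosage matrix in Hardy-Weinberg equilibrium with per-variant QC metadata,
quantitative dietary traits with an additive polygenic architecture
(configurable heritability, optional shared causal variants across traits,
family-block relatedness and a latent confounder), categorical FFQ
responses consistent with the conversion table, and a time-to-event
colorectal-cancer outcome drawn from a proportional-hazards model on the
age scale with delayed entry and administrative censoring.

Every generator is a pure function of its inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .ffq import FFQError, category_values

__all__ = [
    "GenotypeMatrix",
    "KinshipStructure",
    "TraitArchitecture",
    "TrueArchitecture",
    "BaselineHazard",
    "CensoringConfig",
    "simulate_genotypes",
    "make_families",
    "simulate_traits",
    "simulate_ffq",
    "simulate_outcome",
    "calibrate_baseline_rate",
]

EVENT_CODES = {0: "censored", 1: "colon", 2: "rectal"}


@dataclass
class GenotypeMatrix:
    """Per-sample effect-allele dosages plus per-variant metadata.

    ``dosages`` is an ``n_samples x n_variants`` array with entries in
    [0, 2]; ``variants`` carries id, chrom, pos (1-based, strictly
    increasing within chromosome), effect/other allele, maf, info and
    missingness used by QC.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self):
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("dosage shape does not match sample/variant tables")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, mask) -> "GenotypeMatrix":
        v = self.variants.loc[mask] if getattr(mask, "dtype", None) == bool else self.variants.iloc[mask]
        idx = self.variants.index.get_indexer(v.index)
        return GenotypeMatrix(self.dosages[:, idx], v.reset_index(drop=True), self.sample_ids)

    def columns_for(self, variant_ids) -> np.ndarray:
        """Dosage columns for the given variant ids (order preserved)."""
        lookup = pd.Index(self.variants["id"])
        idx = lookup.get_indexer(list(variant_ids))
        if (idx < 0).any():
            missing = [v for v, i in zip(variant_ids, idx) if i < 0]
            raise KeyError(f"unknown variant ids: {missing[:5]}")
        return self.dosages[:, idx]


@dataclass
class KinshipStructure:
    """Family-block relatedness: consecutive blocks sharing a random effect.

    ``blocks`` assigns each sample a family id; ``coefficient`` is the
    within-block kinship (0.5 = MZ-like, 0.25 = full sibs); ``icc`` is the
    intraclass correlation of traits attributable to family environment.
    """

    blocks: np.ndarray
    coefficient: float = 0.25
    icc: float = 0.05

    def __post_init__(self):
        if not 0 <= self.coefficient <= 0.5:
            raise ValueError("kinship coefficient must lie in [0, 0.5]")
        if not 0 <= self.icc < 1:
            raise ValueError("icc must lie in [0, 1)")

    def sparse_pairs(self) -> pd.DataFrame:
        """All within-block sample pairs with their kinship coefficient."""
        rows = []
        for b in np.unique(self.blocks):
            members = np.flatnonzero(self.blocks == b)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    rows.append((int(members[i]), int(members[j]), self.coefficient))
        return pd.DataFrame(rows, columns=["i", "j", "kinship"])


@dataclass
class TraitArchitecture:
    """Additive genetic architecture of one dietary trait."""

    causal_ids: list[str]
    effects: np.ndarray
    h2: float
    confounder_effect: float = 0.0
    log_hr: float = 0.0
    mean: float = 2.0

    def __post_init__(self):
        self.effects = np.asarray(self.effects, float)
        if len(self.causal_ids) != len(self.effects):
            raise ValueError("causal_ids and effects length mismatch")
        if not 0 <= self.h2 < 1:
            raise ValueError(f"h2 must lie in [0, 1); got {self.h2}")


@dataclass
class TrueArchitecture:
    """Ground truth for the whole simulated study.

    ``confounder_log_hr`` is the effect of the latent confounder on the
    outcome hazard; together with per-trait ``confounder_effect`` it
    induces classical confounding for the MR-vs-observational contrast.
    """

    traits: dict[str, TraitArchitecture]
    confounder_log_hr: float = 0.0

    def shared_causal_map(self) -> dict[tuple[str, str], list[str]]:
        """Symmetric map of trait pairs to their shared causal variants."""
        out: dict[tuple[str, str], list[str]] = {}
        names = list(self.traits)
        for a in names:
            for b in names:
                if a == b:
                    continue
                shared = sorted(set(self.traits[a].causal_ids) & set(self.traits[b].causal_ids))
                out[(a, b)] = shared
        return out


@dataclass
class BaselineHazard:
    """Exponential baseline hazard on the age scale (events per person-year)."""

    rate: float = 1e-3

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("baseline hazard rate must be positive")


@dataclass
class CensoringConfig:
    """Administrative censoring: end of follow-up and a maximum age."""

    max_follow_up: float = 12.4
    admin_age: float = 85.0


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.01, 0.5),
    hwe: bool = True,
    seed: int = 0,
    n_chromosomes: int = 4,
    spacing_bp: tuple[int, int] = (5_000, 60_000),
    info_beta: tuple[float, float] = (30.0, 2.0),
    missing_beta: tuple[float, float] = (1.0, 60.0),
) -> GenotypeMatrix:
    """Simulate a biallelic dosage panel with QC metadata.

    Genotypes are drawn ``Binomial(2, maf)`` per variant (HWE) with maf
    uniform over ``maf_range``.  With ``hwe=False`` a heterozygote deficit
    (inbreeding coefficient 0.25) is induced so HWE filters have positives.
    INFO scores and missingness fractions are drawn from Beta distributions
    (defaults give mostly clean variants with a tail of QC failures) and
    stored as metadata only; the dosage matrix itself is complete.
    """
    if n_samples < 2 or n_variants < 1:
        raise ValueError("need n_samples >= 2 and n_variants >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, n_variants)
    if hwe:
        dos = rng.binomial(2, maf, size=(n_samples, n_variants)).astype(np.int8)
    else:
        # inbreeding-style het deficit: P(het) = 2pq(1-F)
        F = 0.25
        p = maf
        probs = np.stack(
            [(1 - p) ** 2 + F * p * (1 - p), 2 * p * (1 - p) * (1 - F), p**2 + F * p * (1 - p)]
        ).T  # (M, 3)
        u = rng.random((n_samples, n_variants))
        c = probs.cumsum(axis=1)
        dos = ((u[:, :, None] > c[None, :, :2]).sum(axis=2)).astype(np.int8)
    per_chrom = int(np.ceil(n_variants / n_chromosomes))
    chrom = np.repeat(np.arange(1, n_chromosomes + 1), per_chrom)[:n_variants]
    gaps = rng.integers(spacing_bp[0], spacing_bp[1], n_variants)
    pos = np.empty(n_variants, dtype=np.int64)
    for c_ in np.unique(chrom):
        m = chrom == c_
        pos[m] = 1 + np.cumsum(gaps[m])
    alleles = np.array(["A", "C", "G", "T"])
    ea = alleles[rng.integers(0, 4, n_variants)]
    oa = np.array([alleles[(list(alleles).index(a) + 1 + rng.integers(0, 3)) % 4] for a in ea])
    variants = pd.DataFrame(
        {
            "id": [f"rs{c_}_{p_}" for c_, p_ in zip(chrom, pos)],
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "maf": maf,
            "info": rng.beta(*info_beta, n_variants),
            "missingness": rng.beta(*missing_beta, n_variants),
        }
    )
    sample_ids = [f"S{i:06d}" for i in range(n_samples)]
    return GenotypeMatrix(dos, variants, sample_ids)


def make_families(n_samples: int, block_size: int = 1, coefficient: float = 0.25, icc: float = 0.05) -> KinshipStructure:
    """Partition samples into consecutive family blocks."""
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    blocks = np.arange(n_samples) // block_size
    return KinshipStructure(blocks=blocks, coefficient=coefficient, icc=icc)


def simulate_traits(
    geno: GenotypeMatrix,
    arch: TrueArchitecture,
    kin: KinshipStructure | None = None,
    seed: int = 0,
    missing_rates: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw dietary traits and covariates given a genetic architecture.

    Each trait is built on a unit-variance scale: a standardized genetic
    value contributing variance h2, a family random effect contributing
    ``kin.icc``, a latent confounder U contributing ``confounder_effect**2``
    and Gaussian noise making up the remainder; the trait mean is then
    shifted to ``arch.traits[t].mean``.  Covariates are enrolment age, sex
    (1 = female), the latent confounder ``u`` and a small set of observed
    lifestyle confounders.  Returns (traits, covariates, realized variance
    decomposition).
    """
    rng = np.random.default_rng(seed)
    n = geno.n_samples
    u = rng.standard_normal(n)
    age = np.clip(rng.normal(56.6, 8.0, n), 40.0, 70.0)
    sex = rng.binomial(1, 0.533, n)
    covars = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "u": u,
            "family_history": rng.binomial(1, 0.10, n),
            "income": rng.integers(1, 6, n),
            "smoking": rng.integers(0, 3, n),
            "bmi": rng.normal(27.3, 4.5, n),
            "physical_activity": rng.normal(0.0, 1.0, n),
        },
        index=geno.sample_ids,
    )
    fam_effect = None
    if kin is not None and kin.icc > 0:
        per_block = rng.standard_normal(int(kin.blocks.max()) + 1)
        fam_effect = per_block[kin.blocks]

    traits = {}
    decomp_rows = []
    for name, ta in arch.traits.items():
        icc = kin.icc if (kin is not None and kin.icc > 0) else 0.0
        resid_var = 1.0 - ta.h2 - icc - ta.confounder_effect**2
        if resid_var < 0:
            raise ValueError(
                f"trait {name!r}: h2 + icc + confounder variance exceed 1 "
                f"({ta.h2} + {icc} + {ta.confounder_effect ** 2:.3f})"
            )
        if ta.h2 > 0:
            if len(ta.causal_ids) == 0:
                raise ValueError(f"trait {name!r}: h2 > 0 requires causal variants")
            g = geno.columns_for(ta.causal_ids).astype(float) @ ta.effects
            sd = g.std()
            if sd == 0:
                raise ValueError(f"trait {name!r}: genetic value is constant")
            g = (g - g.mean()) / sd * np.sqrt(ta.h2)
        else:
            g = np.zeros(n)
        y = ta.mean + g + ta.confounder_effect * u + np.sqrt(resid_var) * rng.standard_normal(n)
        if fam_effect is not None:
            y = y + np.sqrt(icc) * fam_effect
        traits[name] = y
        tot = y.var()
        decomp_rows.append(
            {
                "trait": name,
                "target_h2": ta.h2,
                "realized_h2": float(g.var() / tot) if tot > 0 else np.nan,
                "family_var": float(icc * (fam_effect.var() if fam_effect is not None else 0.0)),
                "confounder_var": float(ta.confounder_effect**2),
                "total_var": float(tot),
            }
        )
    traits_df = pd.DataFrame(traits, index=geno.sample_ids)
    if missing_rates:
        for name, rate in missing_rates.items():
            if name in traits_df:
                mask = rng.random(n) < rate
                traits_df.loc[mask, name] = np.nan
    return traits_df, covars, pd.DataFrame(decomp_rows).set_index("trait")


def simulate_ffq(trait_values: pd.Series | pd.DataFrame, item_class: str = "frequency") -> pd.DataFrame:
    """Bin quantitative weekly frequencies back into FFQ categories.

    Each value is assigned the category whose numeric value is nearest
    (ties resolve to the lower category), so converting the result back
    through the conversion table is the identity on category values.
    """
    df = trait_values.to_frame() if isinstance(trait_values, pd.Series) else trait_values
    vals = category_values(item_class)
    from .ffq import load_conversion_table

    table = load_conversion_table()
    by_value = {}
    for label, v in table["classes"][item_class]["responses"].items():
        by_value.setdefault(v, label)
    labels = [by_value[v] for v in vals]
    out = {}
    for col in df.columns:
        x = df[col].to_numpy(float)
        if np.nanmin(x) < 0:
            raise FFQError(f"negative frequency in column {col!r}")
        # nearest category value; ties (exact midpoints) go to the lower one
        d = np.abs(x[:, None] - vals[None, :])
        best = np.where(np.isnan(x), -1, np.argmin(d, axis=1))
        res = np.array([labels[i] if i >= 0 else None for i in best], dtype=object)
        out[col] = res
    return pd.DataFrame(out, index=df.index)


def calibrate_baseline_rate(
    linear_predictor: np.ndarray,
    follow_up: np.ndarray,
    target_event_fraction: float,
) -> float:
    """Solve for the exponential baseline rate giving a target event fraction.

    Uses the closed form P(event_i) = 1 - exp(-rate * exp(lp_i) * f_i) and
    bisection on the mean; deterministic.
    """
    if not 0 < target_event_fraction < 1:
        raise ValueError("target_event_fraction must lie in (0, 1)")
    lp = np.asarray(linear_predictor, float)
    f = np.asarray(follow_up, float)

    def frac(rate):
        return np.mean(1 - np.exp(-rate * np.exp(lp) * f))

    lo, hi = 1e-10, 1.0
    while frac(hi) < target_event_fraction:
        hi *= 10
        if hi > 1e6:
            raise ValueError("cannot reach target event fraction")
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target_event_fraction:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_outcome(
    traits: pd.DataFrame,
    covariates: pd.DataFrame,
    arch: TrueArchitecture,
    baseline: BaselineHazard | None = None,
    censoring: CensoringConfig | None = None,
    seed: int = 0,
    target_event_fraction: float | None = None,
    colon_rectal_split: tuple[float, float] = (2.0, 1.0),
) -> pd.DataFrame:
    """Draw a time-to-colorectal-cancer outcome under proportional hazards.

    The hazard on the age scale is ``rate * exp(sum_t logHR_t * (trait_t -
    mean) + confounder_log_hr * u)`` with exponential baseline; samples
    enter the risk set at enrolment age and are administratively censored
    at end of follow-up or ``admin_age``, whichever comes first.  Events
    are labelled colon or rectal with the configured split (default 2:1).
    When ``target_event_fraction`` is given the baseline rate is calibrated
    to it.  Rows with missing traits contribute a zero trait effect (their
    hazard is the baseline part), keeping the cohort complete.
    """
    censoring = censoring or CensoringConfig()
    rng = np.random.default_rng(seed)
    n = len(traits)
    entry = covariates["age"].to_numpy(float)
    if censoring.admin_age <= entry.min():
        raise ValueError("administrative censoring age precedes all entry ages: empty risk set")
    lp = np.zeros(n)
    any_effect = arch.confounder_log_hr != 0
    for name, ta in arch.traits.items():
        if ta.log_hr != 0:
            any_effect = True
            x = traits[name].to_numpy(float)
            x = np.where(np.isnan(x), ta.mean, x)
            lp += ta.log_hr * (x - ta.mean)
    if arch.confounder_log_hr != 0:
        lp += arch.confounder_log_hr * covariates["u"].to_numpy(float)
    follow = np.minimum(censoring.max_follow_up, censoring.admin_age - entry)
    if baseline is None:
        if target_event_fraction is None:
            raise ValueError("provide either baseline or target_event_fraction")
        rate = calibrate_baseline_rate(lp, follow, target_event_fraction)
    else:
        rate = baseline.rate
        if rate <= 0:
            raise ValueError("all-zero hazard: baseline rate must be positive")
    t_event = rng.exponential(1.0 / (rate * np.exp(lp)))
    event = t_event <= follow
    exit_age = entry + np.where(event, t_event, follow)
    p_colon = colon_rectal_split[0] / sum(colon_rectal_split)
    subsite = np.where(rng.random(n) < p_colon, 1, 2)
    code = np.where(event, subsite, 0)
    out = pd.DataFrame(
        {
            "entry_age": entry,
            "exit_age": exit_age,
            "event": code.astype(int),
            "sex": covariates["sex"].to_numpy(int),
        },
        index=traits.index,
    )
    out.attrs["baseline_rate"] = rate
    out.attrs["event_fraction"] = float(event.mean())
    return out


# ---------------------------------------------------------------------------
# plain-text writers

def write_genotypes(geno: GenotypeMatrix, dosage_path: str, variants_path: str) -> None:
    pd.DataFrame(geno.dosages, index=geno.sample_ids, columns=geno.variants["id"]).to_csv(
        dosage_path, sep="\t"
    )
    geno.variants.to_csv(variants_path, sep="\t", index=False)


def write_cohort(traits: pd.DataFrame, covars: pd.DataFrame, outcome: pd.DataFrame, path: str) -> None:
    pd.concat([traits, covars, outcome], axis=1).to_csv(path, sep="\t")


def write_truth(arch: TrueArchitecture, path: str) -> None:
    record = {
        "confounder_log_hr": float(arch.confounder_log_hr),
        "traits": {
            name: {
                "causal_ids": list(ta.causal_ids),
                "effects": [float(e) for e in ta.effects],
                "h2": float(ta.h2),
                "confounder_effect": float(ta.confounder_effect),
                "log_hr": float(ta.log_hr),
                "mean": float(ta.mean),
            }
            for name, ta in arch.traits.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(record, fh, sort_keys=False)
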