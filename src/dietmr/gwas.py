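"""Variant QC, association scans, locus selection and heritability.

The scan is an ordinary per-variant linear regression of the trait on
dosage plus covariates (computed by Frisch-Waugh residualization so a
whole panel is scanned in one matrix pass).  Familial relatedness is
absorbed by a two-step residual approach: the trait is first adjusted for
covariates and a family-block random effect (empirical BLUP of block
means), and the residuals are then scanned per variant — a GRAMMAR-style
approximation of a per-variant linear mixed model.

Heritability and genetic correlation use Haseman-Elston regression of
phenotypic cross-products on genomic relatedness, evaluated through trace
identities on the standardized dosage matrix so the n x n relatedness
matrix is never materialized; standard errors come from a delete-a-block
jackknife over samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthcohort import GenotypeMatrix, KinshipStructure

__all__ = [
    "QcThresholds",
    "LociConfig",
    "hwe_test",
    "qc_filter",
    "pca_covariates",
    "association_scan",
    "outcome_scan",
    "select_loci",
    "estimate_h2",
    "genetic_correlation",
    "HeritabilityEstimate",
    "GeneticCorrelation",
    "manhattan",
]


@dataclass
class QcThresholds:
    """Per-variant exclusion thresholds, applied in the listed order."""

    min_info: float = 0.3
    max_missingness: float = 0.05
    min_maf: float = 0.0002
    min_hwe_p: float = 1e-6


@dataclass
class LociConfig:
    """Distance-based clumping settings for genomic risk loci."""

    p_threshold: float = 5e-8
    window_kb: float = 250.0

    def __post_init__(self):
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    method: str = "haseman-elston"
    clipped: bool = False


@dataclass
class GeneticCorrelation:
    trait_a: str
    trait_b: str
    rg: float
    se: float
    clipped: bool = False


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Hardy-Weinberg goodness-of-fit p-value (1-df chi-square).

    Expected genotype counts come from the estimated allele frequency;
    monomorphic variants return p = 1 by convention.
    """
    counts = np.array([n_aa, n_ab, n_bb], float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("all-zero genotype counts")
    p = (2 * n_bb + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    q = 1 - p
    expected = n * np.array([q * q, 2 * p * q, p * p])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_p_per_variant(geno: GenotypeMatrix) -> np.ndarray:
    g = np.rint(geno.dosages).astype(int)
    out = np.empty(geno.n_variants)
    for j in range(geno.n_variants):
        c = np.bincount(g[:, j], minlength=3)
        out[j] = hwe_test(c[0], c[1], c[2])
    return out


def qc_filter(geno: GenotypeMatrix, thr: QcThresholds | None = None):
    """Apply the variant QC cascade: INFO, missingness, MAF, then HWE.

    Each variant is counted once, under the first filter it fails, so the
    per-filter removal counts sum to the number removed.  Returns the
    retained panel and a report with counts and per-variant fail reasons.
    """
    thr = thr or QcThresholds()
    v = geno.variants
    reason = np.full(len(v), "", dtype=object)
    fail_info = v["info"].to_numpy() < thr.min_info
    reason[fail_info] = "info"
    fail_miss = (reason == "") & (v["missingness"].to_numpy() > thr.max_missingness)
    reason[fail_miss] = "missingness"
    fail_maf = (reason == "") & (v["maf"].to_numpy() < thr.min_maf)
    reason[fail_maf] = "maf"
    undecided = reason == ""
    if undecided.any():
        hwe_p = _hwe_p_per_variant(geno.subset_variants(np.flatnonzero(undecided)))
        fail_hwe = np.zeros(len(v), bool)
        fail_hwe[np.flatnonzero(undecided)] = hwe_p < thr.min_hwe_p
        reason[fail_hwe] = "hwe"
    keep = reason == ""
    report = {
        "n_input": len(v),
        "n_retained": int(keep.sum()),
        "removed": {
            "info": int((reason == "info").sum()),
            "missingness": int((reason == "missingness").sum()),
            "maf": int((reason == "maf").sum()),
            "hwe": int((reason == "hwe").sum()),
        },
        "fail_reason": pd.Series(reason, index=v["id"].to_numpy()),
    }
    return geno.subset_variants(keep), report


def _standardize_dosages(dosages: np.ndarray) -> np.ndarray:
    X = np.asarray(dosages, float)
    freq = X.mean(axis=0) / 2.0
    sd = np.sqrt(2 * freq * (1 - freq))
    keep = sd > 0
    return (X[:, keep] - 2 * freq[keep]) / sd[keep]


def pca_covariates(geno: GenotypeMatrix, k: int) -> np.ndarray:
    """Top-k principal-component scores of the standardized dosage matrix.

    Signs are fixed by making the largest-magnitude loading of each
    component positive, so results are deterministic.
    """
    if k == 0:
        return np.empty((geno.n_samples, 0))
    if k >= min(geno.n_samples, geno.n_variants):
        raise ValueError("k must be smaller than both sample and variant counts")
    Z = _standardize_dosages(geno.dosages)
    if Z.shape[1] == 0:
        raise ValueError("zero-variance panel: no polymorphic variants")
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            scores[:, j] *= -1
    return scores


def _design(covariates: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    ones = np.ones((n, 1))
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        return ones
    C = np.asarray(covariates, float)
    return np.hstack([ones, C])


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _family_blup_residuals(resid: np.ndarray, kin: KinshipStructure) -> np.ndarray:
    """Subtract shrunken family-block means (empirical BLUP) from residuals."""
    blocks = kin.blocks
    df = pd.DataFrame({"b": blocks, "r": resid})
    grp = df.groupby("b")["r"]
    means, sizes = grp.mean(), grp.size()
    # one-way ANOVA variance components
    grand = resid.mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(((df["r"] - means.loc[df["b"]].to_numpy()) ** 2).sum())
    k = len(sizes)
    n = len(resid)
    if k <= 1 or n - k == 0:
        return resid
    msb, msw = ssb / max(k - 1, 1), ssw / (n - k)
    n0 = (n - (sizes**2).sum() / n) / max(k - 1, 1)
    tau2 = max((msb - msw) / n0, 0.0)
    if tau2 == 0:
        return resid
    shrink = (sizes * tau2) / (sizes * tau2 + msw)
    blup = (shrink * means).loc[blocks].to_numpy()
    return resid - blup


def association_scan(
    trait,
    geno: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    kin: KinshipStructure | None = None,
    trait_label: str = "trait",
) -> pd.DataFrame:
    """Per-variant linear association of a quantitative trait with dosage.

    With ``kin`` supplied, a family-block random effect is removed from the
    covariate-adjusted trait before the scan (two-step approximation of a
    mixed model).  Complete-case over trait and covariates; returns summary
    statistics (beta, se, p, eaf, n) aligned to the variant table.
    """
    y = np.asarray(trait, float)
    n = len(y)
    if n != geno.n_samples:
        raise ValueError("trait length does not match genotype matrix")
    C = _design(covariates, n)
    ok = np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    if ok.sum() < 50:
        raise ValueError("fewer than 50 complete cases")
    y, C = y[ok], C[ok]
    G = geno.dosages[ok].astype(float)
    if np.ptp(y) == 0:
        raise ValueError("constant trait")
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        raise ValueError("singular covariate design")
    y_r = _residualize(y, C)
    if kin is not None:
        y_r = _family_blup_residuals(y_r, KinshipStructure(kin.blocks[ok], kin.coefficient, kin.icc))
    G_r = G - C @ np.linalg.lstsq(C, G, rcond=None)[0]
    gss = (G_r**2).sum(axis=0)
    gss_safe = np.where(gss > 0, gss, np.nan)
    beta = (G_r.T @ y_r) / gss_safe
    dof = len(y) - C.shape[1] - 1
    rss = (y_r**2).sum() - beta**2 * gss_safe
    se = np.sqrt(np.maximum(rss, 0) / dof / gss_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    out = geno.variants[["id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    out["eaf"] = G.mean(axis=0) / 2
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n"] = int(len(y))
    out.attrs["trait"] = trait_label
    return out


def outcome_scan(
    outcome: pd.DataFrame,
    geno: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    trait_label: str = "crc",
) -> pd.DataFrame:
    """Per-variant Cox scan of the time-to-event outcome on dosage.

    Age is the time scale with delayed entry at enrolment; any event code
    > 0 counts as an event.  Non-converging variants are flagged (NaN
    estimates) rather than aborting the scan.
    """
    from .survival import fit_cox

    events = (outcome["event"].to_numpy() > 0).astype(int)
    if events.sum() < 1:
        raise ValueError("no events in outcome table")
    base = pd.DataFrame(
        {
            "entry_age": outcome["entry_age"].to_numpy(float),
            "exit_age": outcome["exit_age"].to_numpy(float),
            "event": events,
        }
    )
    covar_cols = []
    if covariates is not None:
        for c in covariates.columns:
            base[c] = covariates[c].to_numpy(float)
            covar_cols.append(c)
    rows = []
    for j in range(geno.n_variants):
        df = base.copy()
        df["g"] = geno.dosages[:, j].astype(float)
        try:
            fit = fit_cox(df, "g", covar_cols)
            rows.append((fit["log_hr"], fit["se"], fit["p"], True))
        except Exception:
            rows.append((np.nan, np.nan, np.nan, False))
    out = geno.variants[["id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    out["eaf"] = geno.dosages.mean(axis=0) / 2
    out[["beta", "se", "p"]] = pd.DataFrame([r[:3] for r in rows])
    out["converged"] = [r[3] for r in rows]
    out["n"] = len(base)
    out.attrs["trait"] = trait_label
    return out


def select_loci(stats_df: pd.DataFrame, cfg: LociConfig | None = None) -> pd.DataFrame:
    """Greedy distance clumping of significant variants into risk loci.

    The smallest-p significant variant seeds a locus and absorbs all
    significant variants within the window on the same chromosome (ties in
    p break by position); repeat until none remain.  Windows are inclusive
    in base pairs on both ends.
    """
    cfg = cfg or LociConfig()
    sig = stats_df[stats_df["p"] < cfg.p_threshold].copy()
    if sig.empty:
        return pd.DataFrame(columns=["lead_id", "chrom", "pos", "p", "beta", "se", "n_members", "member_ids"])
    sig = sig.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    window = cfg.window_kb * 1000
    taken = np.zeros(len(sig), bool)
    loci = []
    for i in range(len(sig)):
        if taken[i]:
            continue
        lead = sig.iloc[i]
        members = (
            (sig["chrom"] == lead["chrom"])
            & (np.abs(sig["pos"] - lead["pos"]) <= window)
            & ~taken
        )
        taken |= members.to_numpy()
        mem = sig[members]
        loci.append(
            {
                "lead_id": lead["id"],
                "chrom": lead["chrom"],
                "pos": int(lead["pos"]),
                "p": float(lead["p"]),
                "beta": float(lead["beta"]),
                "se": float(lead["se"]),
                "n_members": int(members.sum()),
                "member_ids": list(mem["id"]),
            }
        )
    out = pd.DataFrame(loci).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Haseman-Elston heritability / genetic correlation


def _he_ingredients(Z: np.ndarray):
    """Sufficient statistics for HE regression with K = Z Z' / M."""
    M = Z.shape[1]
    A = Z.T @ Z  # M x M
    u = Z.sum(axis=0)  # Z' 1
    k_diag = (Z**2).sum(axis=1) / M  # K_ii per sample
    return A, u, k_diag, M


def _he_slope(A, u, k_diag, M, x, y, Zx, Zy):
    """HE regression slope of x_i y_j on K_ij over off-diagonal pairs."""
    n = len(x)
    N = n * (n - 1)
    sum_K = (u @ u) / M - k_diag.sum()
    sum_K2 = (A**2).sum() / M**2 - (k_diag**2).sum()
    s_xy = (Zx @ Zy) / M - (k_diag * x * y).sum()  # sum_{i != j} K_ij x_i y_j
    s_prod = x.sum() * y.sum() - (x * y).sum()
    denom = sum_K2 - sum_K**2 / N
    if denom <= 0:
        raise ValueError("degenerate relatedness: no variance in off-diagonal kinship")
    return (s_xy - sum_K * s_prod / N) / denom


def _prep_trait(trait, covariates, n):
    y = np.asarray(trait, float)
    C = _design(covariates, n)
    y = _residualize(y, C)
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValueError("constant trait after covariate adjustment")
    return y / sd


def estimate_h2(
    geno: GenotypeMatrix,
    trait,
    covariates: pd.DataFrame | None = None,
    n_jackknife_blocks: int = 20,
) -> HeritabilityEstimate:
    """SNP heritability by Haseman-Elston regression.

    Regresses products of the covariate-residualized, standardized trait
    over sample pairs on their genomic relatedness; the slope estimates h2.
    SE comes from a delete-a-block jackknife over contiguous sample blocks.
    Estimates outside [0, 1] are clipped and flagged.
    """
    n = geno.n_samples
    if n < 500:
        raise ValueError("need at least 500 samples for HE regression")
    y = _prep_trait(trait, covariates, n)
    Z = _standardize_dosages(geno.dosages)
    A, u, k_diag, M = _he_ingredients(Z)
    Zy = Z.T @ y
    h2 = _he_slope(A, u, k_diag, M, y, y, Zy, Zy)
    # jackknife over contiguous blocks
    bounds = np.linspace(0, n, n_jackknife_blocks + 1).astype(int)
    reps = []
    for b in range(n_jackknife_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        Zb, yb = Z[sl], y[sl]
        Ab = A - Zb.T @ Zb
        ub = u - Zb.sum(axis=0)
        mask = np.ones(n, bool)
        mask[sl] = False
        kd, yd = k_diag[mask], y[mask]
        Zyd = Zy - Zb.T @ yb
        reps.append(_he_slope(Ab, ub, kd, M, yd, yd, Zyd, Zyd))
    reps = np.array(reps)
    B = n_jackknife_blocks
    se = float(np.sqrt((B - 1) / B * ((reps - reps.mean()) ** 2).sum()))
    clipped = not 0 <= h2 <= 1
    return HeritabilityEstimate(h2=float(np.clip(h2, 0, 1)), se=se, clipped=clipped)


def genetic_correlation(
    geno: GenotypeMatrix,
    trait_a,
    trait_b,
    covariates: pd.DataFrame | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> GeneticCorrelation:
    """Genetic correlation between two traits by bivariate Haseman-Elston.

    The cross-trait HE slope estimates the genetic covariance; dividing by
    the geometric mean of the two h2 slopes gives r_g.  Undefined (raises)
    when either heritability estimate is non-positive.
    """
    n = geno.n_samples
    x = _prep_trait(trait_a, covariates, n)
    y = _prep_trait(trait_b, covariates, n)
    Z = _standardize_dosages(geno.dosages)
    A, u, k_diag, M = _he_ingredients(Z)
    Zx, Zy = Z.T @ x, Z.T @ y
    h2x = _he_slope(A, u, k_diag, M, x, x, Zx, Zx)
    h2y = _he_slope(A, u, k_diag, M, y, y, Zy, Zy)
    if h2x <= 0 or h2y <= 0:
        raise ValueError("genetic correlation undefined: non-positive heritability estimate")
    cov_g = _he_slope(A, u, k_diag, M, x, y, Zx, Zy)
    rg = cov_g / np.sqrt(h2x * h2y)
    clipped = not -1 <= rg <= 1
    # rough jackknife on the ratio via 10 contiguous blocks
    bounds = np.linspace(0, n, 11).astype(int)
    reps = []
    for b in range(10):
        sl = slice(bounds[b], bounds[b + 1])
        mask = np.ones(n, bool)
        mask[sl] = False
        Zb = Z[sl]
        Ab = A - Zb.T @ Zb
        ub = u - Zb.sum(axis=0)
        kd = k_diag[mask]
        xd, yd = x[mask], y[mask]
        Zxd, Zyd = Zx - Zb.T @ x[sl], Zy - Zb.T @ y[sl]
        hx = _he_slope(Ab, ub, kd, M, xd, xd, Zxd, Zxd)
        hy = _he_slope(Ab, ub, kd, M, yd, yd, Zyd, Zyd)
        if hx > 0 and hy > 0:
            reps.append(_he_slope(Ab, ub, kd, M, xd, yd, Zxd, Zyd) / np.sqrt(hx * hy))
    reps = np.array(reps) if reps else np.array([rg])
    B = len(reps)
    se = float(np.sqrt((B - 1) / B * ((reps - reps.mean()) ** 2).sum())) if B > 1 else float("nan")
    return GeneticCorrelation(labels[0], labels[1], float(np.clip(rg, -1, 1)), se, clipped)


def manhattan(stats_df: pd.DataFrame, ax=None, threshold: float = 5e-8):
    """Basic Manhattan plot of a summary-statistics table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    offset = 0
    for c in sorted(stats_df["chrom"].unique()):
        sub = stats_df[stats_df["chrom"] == c]
        ax.scatter(sub["pos"] + offset, -np.log10(sub["p"]), s=4)
        offset += sub["pos"].max()
    ax.axhline(-np.log10(threshold), color="red", ls="--", lw=1)
    ax.set_xlabel("position")
    ax.set_ylabel("-log10 p")
    return ax
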