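"""Instrument construction: exclusions, weighted allele scores, F-statistics.

Lead variants of the trait's genomic risk loci become candidate
instruments.  Two exclusion screens guard the MR assumptions: variants
associated with multiple dietary traits (horizontal pleiotropy) and
variants directly associated with the outcome (exclusion restriction).
The remaining variants are combined into an internally weighted allele
score — per-sample sum of effect-allele dosages times the trait-GWAS
beta — whose strength is summarized by the first-stage F-statistic.

Internal weighting (weights estimated in the same sample that is
analyzed) is subject to winner's curse; a warning is logged, matching
standard one-sample practice, and no correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthcohort import GenotypeMatrix

__all__ = [
    "InstrumentSet",
    "InstrumentDiagnostics",
    "WeakInstrumentError",
    "cross_trait_flags",
    "apply_exclusions",
    "allele_score",
    "f_statistic",
    "build_instruments",
]

logger = logging.getLogger(__name__)


class WeakInstrumentError(RuntimeError):
    """Raised when the first-stage F-statistic falls below the gate."""


@dataclass
class InstrumentSet:
    """Selected instrument variants with GWAS weights for one trait."""

    trait: str
    variant_ids: list[str]
    weights: np.ndarray
    flags: pd.DataFrame = None  # per-variant exclusion flags
    score: np.ndarray | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        if len(self.variant_ids) != len(self.weights):
            raise ValueError("variant_ids and weights length mismatch")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.flags is None:
            self.flags = pd.DataFrame(
                {"pleiotropy": False, "outcome_associated": False},
                index=pd.Index(self.variant_ids, name="id"),
            )


@dataclass
class InstrumentDiagnostics:
    """First-stage strength summary for an allele score."""

    f_stat: float
    beta: float
    se: float
    n: int

    def __post_init__(self):
        if self.f_stat < 0:
            raise ValueError("F-statistic must be non-negative")


def cross_trait_flags(loci_by_trait: dict[str, list[str]], min_traits: int = 2) -> pd.DataFrame:
    """Count, per lead variant, the traits it is significant for.

    A variant is flagged when its trait count reaches ``min_traits``
    (default 2: any variant shared by two or more dietary phenotypes, the
    stricter of the two published wordings; set ``min_traits=3`` for the
    "more than two traits" alternative).
    """
    counts: dict[str, int] = {}
    traits: dict[str, list[str]] = {}
    for trait, ids in loci_by_trait.items():
        for vid in set(ids):
            counts[vid] = counts.get(vid, 0) + 1
            traits.setdefault(vid, []).append(trait)
    return pd.DataFrame(
        {
            "n_traits": pd.Series(counts),
            "traits": pd.Series({k: sorted(v) for k, v in traits.items()}),
            "flagged": pd.Series({k: c >= min_traits for k, c in counts.items()}),
        }
    ).rename_axis("id")


def apply_exclusions(
    ivs: InstrumentSet,
    flags: pd.DataFrame | None,
    outcome_stats: pd.DataFrame,
    p_cut: float = 0.05,
) -> tuple[InstrumentSet, pd.DataFrame]:
    """Drop pleiotropy-flagged and outcome-associated instrument variants.

    ``outcome_stats`` must cover every candidate (columns id, p); variants
    with outcome p < ``p_cut`` violate the exclusion-restriction screen.
    Returns the reduced set plus a per-variant exclusion log.
    """
    op = outcome_stats.set_index("id")["p"]
    missing = [v for v in ivs.variant_ids if v not in op.index]
    if missing:
        raise ValueError(f"outcome stats missing for instruments: {missing[:5]}")
    log_rows = []
    keep_ids, keep_w = [], []
    for vid, w in zip(ivs.variant_ids, ivs.weights):
        pleio = bool(flags.loc[vid, "flagged"]) if (flags is not None and vid in flags.index) else False
        out_assoc = bool(op[vid] < p_cut)
        if pleio:
            reason = "pleiotropy"
        elif out_assoc:
            reason = "outcome_associated"
        else:
            reason = ""
            keep_ids.append(vid)
            keep_w.append(w)
        log_rows.append({"id": vid, "excluded": bool(reason), "reason": reason, "outcome_p": float(op[vid])})
    if not keep_ids:
        raise ValueError(
            "all instruments excluded; review the pleiotropy threshold and outcome p cutoff"
        )
    flag_df = pd.DataFrame(
        {
            "pleiotropy": [r["reason"] == "pleiotropy" for r in log_rows],
            "outcome_associated": [r["reason"] == "outcome_associated" for r in log_rows],
        },
        index=pd.Index([r["id"] for r in log_rows], name="id"),
    )
    reduced = InstrumentSet(ivs.trait, keep_ids, np.array(keep_w), flags=flag_df.loc[keep_ids])
    return reduced, pd.DataFrame(log_rows)


def allele_score(geno: GenotypeMatrix, weights: dict[str, float] | pd.Series) -> np.ndarray:
    """Internally weighted allele score: score_i = sum_j w_j * dosage_ij.

    Missing dosages are mean-imputed per variant before scoring so every
    sample receives a score.
    """
    if isinstance(weights, dict):
        weights = pd.Series(weights)
    if len(weights) == 0:
        raise ValueError("empty weight set")
    G = geno.columns_for(list(weights.index)).astype(float)
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G[idx] = col_mean[idx[1]]
    return G @ weights.to_numpy(float)


def f_statistic(beta: float, se: float, n: int | None = None) -> InstrumentDiagnostics:
    """Instrument-strength F: squared first-stage estimate over its variance.

    Equals the squared t-statistic of the score coefficient in the
    first-stage regression.
    """
    if se <= 0:
        raise ValueError("standard error must be positive")
    return InstrumentDiagnostics(f_stat=float((beta / se) ** 2), beta=float(beta), se=float(se), n=int(n or 0))


def check_strength(diag: InstrumentDiagnostics, min_f: float = 10.0, allow_weak: bool = False) -> None:
    """Refuse weak instruments (F below ``min_f``) unless overridden."""
    if diag.f_stat < min_f and not allow_weak:
        raise WeakInstrumentError(
            f"first-stage F = {diag.f_stat:.2f} < {min_f}; pass allow_weak=True to override"
        )


def build_instruments(
    trait: str,
    loci: pd.DataFrame,
    geno: GenotypeMatrix,
    flags: pd.DataFrame | None = None,
    outcome_stats: pd.DataFrame | None = None,
    p_cut: float = 0.05,
) -> InstrumentSet:
    """Assemble an instrument set from a trait's risk loci.

    Lead variants are weighted by their trait-GWAS beta; exclusions are
    applied when flags/outcome stats are supplied, and the allele score is
    attached.  Logs the winner's-curse caveat of internal weighting.
    """
    if loci.empty:
        raise ValueError(f"no risk loci for trait {trait!r}")
    ivs = InstrumentSet(trait, list(loci["lead_id"]), loci["beta"].to_numpy(float))
    if outcome_stats is not None:
        ivs, _ = apply_exclusions(ivs, flags, outcome_stats, p_cut=p_cut)
    elif flags is not None:
        keep = [i for i, v in enumerate(ivs.variant_ids) if not (v in flags.index and flags.loc[v, "flagged"])]
        if not keep:
            raise ValueError("all instruments pleiotropy-flagged")
        ivs = InstrumentSet(trait, [ivs.variant_ids[i] for i in keep], ivs.weights[keep])
    logger.warning(
        "instrument weights for %s estimated in the analysis sample (internal weighting); "
        "estimates are subject to winner's curse",
        trait,
    )
    ivs.score = allele_score(geno, pd.Series(ivs.weights, index=ivs.variant_ids))
    return ivs
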