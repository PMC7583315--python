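"""Allele comparison: delta ln K_D, Z statistic, significance and rank.

The minor allele is compared with the ancestral (wild-type) allele on
the -ln K_D scale. With per-allele uncertainty sigma (the model's
regression residual SD), the Z statistic is

    delta = (-ln K_D)_min - (-ln K_D)_wt
    Z     = delta / sqrt(se_wt^2 + se_min^2)

and alpha is the one-sided standard-normal tail beyond |Z|; the
decision direction comes from the sign of delta. Under the working
premise that expression changes proportionally with TBP-promoter
affinity, the expression change is reported as the ratio exp(delta).

No multiple-testing correction is applied across SNPs; calls are
per-SNP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .affinity import AffinityEstimate

DECISION_DEFICIENCY = "deficiency: significant"
DECISION_EXCESS = "excess: significant"
DECISION_INSIGNIFICANT = "insignificant"

#: Heuristic prioritization bins: alpha upper bound -> rank letter,
#: best (A) to worst (E). The bins are a documented heuristic and can
#: be overridden.
DEFAULT_RANK_BINS: tuple[tuple[float, str], ...] = (
    (1e-6, "A"),
    (1e-4, "B"),
    (1e-3, "C"),
    (1e-2, "D"),
    (0.05, "E"),
)


@dataclass
class MarkerCall:
    rsid: str
    gene_id: str
    neglog_kd_wt: float
    se_wt: float
    neglog_kd_min: float
    se_min: float
    delta_ln_kd: float
    z: float
    alpha: float
    decision: str
    rank_rho: str | None
    expression_ratio: float
    kd_wt_nM: float
    kd_min_nM: float


def assign_rank(alpha: float,
                bins: tuple[tuple[float, str], ...] = DEFAULT_RANK_BINS) -> str:
    """Map a significant call's alpha to a prioritization letter.

    alpha == 0 (a tail underflow for very large |Z|) maps to the best
    rank.
    """
    if not 0 <= alpha < bins[-1][0]:
        raise ValueError(
            f"rank undefined for alpha={alpha}: call is not significant"
        )
    for bound, letter in bins[:-1]:
        if alpha <= bound:
            return letter
    return bins[-1][1]


def compare_alleles(est_wt: AffinityEstimate, est_min: AffinityEstimate,
                    alpha_threshold: float = 0.05, rsid: str = "",
                    gene_id: str = "",
                    rank_bins: tuple[tuple[float, str], ...] = DEFAULT_RANK_BINS,
                    ) -> MarkerCall:
    """Compare minor-allele vs wild-type affinity estimates."""
    if est_wt.se <= 0 or est_min.se <= 0:
        raise ValueError("allele estimates must carry positive uncertainty")
    delta = est_min.neglog_kd - est_wt.neglog_kd
    z = delta / math.sqrt(est_wt.se ** 2 + est_min.se ** 2)
    alpha = float(stats.norm.sf(abs(z)))
    if alpha < alpha_threshold:
        decision = DECISION_DEFICIENCY if delta < 0 else DECISION_EXCESS
        rank = assign_rank(alpha, rank_bins)
    else:
        decision = DECISION_INSIGNIFICANT
        rank = None
    return MarkerCall(
        rsid=rsid,
        gene_id=gene_id,
        neglog_kd_wt=est_wt.neglog_kd,
        se_wt=est_wt.se,
        neglog_kd_min=est_min.neglog_kd,
        se_min=est_min.se,
        delta_ln_kd=delta,
        z=z,
        alpha=alpha,
        decision=decision,
        rank_rho=rank,
        expression_ratio=math.exp(delta),
        kd_wt_nM=est_wt.kd_nM,
        kd_min_nM=est_min.kd_nM,
    )
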