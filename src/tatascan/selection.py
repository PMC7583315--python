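"""Selection-pressure statistics over marker-call counts.

Significant calls are tallied per gene class into rows of counts:
N_RES total markers, of which N_> increase and N_< decrease
TBP-promoter affinity, and (through literature-curated annotations)
N_up increase and N_dn decrease reproductive potential. Two exact
binomial hypotheses are evaluated per row:

* the genome-wide norm, under which SNPs damaging TBP sites are
  fourfold more frequent than improving ones, i.e. affinity-increasing
  markers arise with probability p0 = 0.2; and
* the equal-split null N_up = N_dn (p = 1/2, two-sided), whose
  non-rejection is the operational signature of disruptive selection.

All tail probabilities are exact (no normal approximation); rows can
be as small as a dozen markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from .zscore import (
    DECISION_DEFICIENCY,
    DECISION_EXCESS,
    MarkerCall,
)

GENOME_NORM_P0 = 0.2


@dataclass
class SelectionCounts:
    """One gene-class row of marker counts with binomial tail probabilities."""

    class_label: str
    n_res: int
    n_gt: int          # affinity-increasing markers (N_>)
    n_lt: int          # affinity-decreasing markers (N_<)
    n_up: int = 0      # potential-increasing markers
    n_dn: int = 0      # potential-decreasing markers
    n_gene: int | None = None
    n_snp: int | None = None
    n_unclassified: int = 0
    p_norm_null: float | None = None
    p_norm_null_tail: str = ""
    p_equal_null: float | None = None

    def __post_init__(self) -> None:
        counts = (self.n_res, self.n_gt, self.n_lt, self.n_up, self.n_dn)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_gt + self.n_lt != self.n_res:
            raise ValueError(
                f"{self.class_label}: n_gt + n_lt = {self.n_gt + self.n_lt} "
                f"!= n_res = {self.n_res}"
            )


def binom_tail(n: int, k: int, p0: float, tail: str = "ge") -> float:
    """Exact binomial tail probability.

    tail='ge' gives P(X >= k), 'le' gives P(X <= k), 'two_sided' sums
    both tails by the minimum-likelihood rule. Exact summation of the
    binomial mass function; no normal approximation.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if not 0 < p0 < 1:
        raise ValueError(f"p0={p0} outside (0, 1)")
    if tail == "ge":
        return float(stats.binom.sf(k - 1, n, p0))
    if tail == "le":
        return float(stats.binom.cdf(k, n, p0))
    if tail == "two_sided":
        if n == 0:
            return 1.0
        return float(stats.binomtest(k, n, p0).pvalue)
    raise ValueError(f"unknown tail {tail!r}")


def tally(calls: list[MarkerCall], annotations, class_map: dict[str, str],
          ) -> list[SelectionCounts]:
    """Aggregate significant marker calls into per-class count rows.

    ``annotations`` maps (gene_id, expression_direction) to a potential
    effect; a significant call with no annotation is counted as
    unclassified and excluded from n_up/n_dn.
    """
    ann = {}
    for a in annotations:
        ann[(a.gene_id, a.expression_direction)] = a.potential_effect
    classes: dict[str, dict] = {}
    for call in calls:
        if call.decision not in (DECISION_DEFICIENCY, DECISION_EXCESS):
            continue
        if call.gene_id not in class_map:
            raise KeyError(
                f"gene {call.gene_id!r} of significant call {call.rsid} "
                "missing from the class map"
            )
        row = classes.setdefault(
            class_map[call.gene_id],
            {"n_res": 0, "n_gt": 0, "n_lt": 0, "n_up": 0, "n_dn": 0,
             "unclassified": 0, "genes": set()},
        )
        row["n_res"] += 1
        row["genes"].add(call.gene_id)
        direction = "over" if call.delta_ln_kd > 0 else "under"
        if call.delta_ln_kd > 0:
            row["n_gt"] += 1
        else:
            row["n_lt"] += 1
        effect = ann.get((call.gene_id, direction))
        if effect == "increase":
            row["n_up"] += 1
        elif effect == "decrease":
            row["n_dn"] += 1
        else:
            row["unclassified"] += 1
    return [
        SelectionCounts(
            class_label=label,
            n_res=row["n_res"],
            n_gt=row["n_gt"],
            n_lt=row["n_lt"],
            n_up=row["n_up"],
            n_dn=row["n_dn"],
            n_gene=len(row["genes"]),
            n_unclassified=row["unclassified"],
        )
        for label, row in sorted(classes.items())
    ]


def selection_report(rows: list[SelectionCounts],
                     p0: float = GENOME_NORM_P0) -> list[SelectionCounts]:
    """Attach the two binomial probabilities to each count row.

    Against the genome norm, rows deviating upward (n_gt > p0*n_res)
    report the right tail P(X >= n_gt); rows at or below the norm
    report the cumulative P(X <= n_gt), and the reported tail is
    labelled so the two conventions are never silently mixed. The
    equal-split test is the exact two-sided probability for n_up out of
    n_up + n_dn at p = 1/2.
    """
    for row in rows:
        if row.n_res == 0:
            row.p_norm_null = 1.0
            row.p_norm_null_tail = "ge"
            row.p_equal_null = 1.0
            continue
        if row.n_gt > p0 * row.n_res:
            row.p_norm_null = binom_tail(row.n_res, row.n_gt, p0, "ge")
            row.p_norm_null_tail = "ge"
        else:
            row.p_norm_null = binom_tail(row.n_res, row.n_gt, p0, "le")
            row.p_norm_null_tail = "le"
        n_ann = row.n_up + row.n_dn
        row.p_equal_null = (
            binom_tail(n_ann, row.n_up, 0.5, "two_sided") if n_ann else 1.0
        )
    return rows


def report_frame(rows: list[SelectionCounts]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "class": r.class_label,
                "n_gene": r.n_gene,
                "n_snp": r.n_snp,
                "n_res": r.n_res,
                "n_gt": r.n_gt,
                "n_lt": r.n_lt,
                "p_norm_null": r.p_norm_null,
                "p_norm_null_tail": r.p_norm_null_tail,
                "n_up": r.n_up,
                "n_dn": r.n_dn,
                "p_equal_null": r.p_equal_null,
                "n_unclassified": r.n_unclassified,
            }
            for r in rows
        ]
    )
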