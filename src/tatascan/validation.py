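"""Prediction-vs-experiment comparison and correlation statistics.

Builds the side-by-side table of predicted and EMSA-measured -ln K_D
values for paired WT/minor 26-bp probes, and computes four association
measures between prediction and experiment: Pearson's r (with a
t-transform p-value, n-2 d.f.), Spearman's rho, Kendall's tau-b
(tie-corrected) and the Goodman-Kruskal gamma (ties excluded).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .affinity import kd_nM_to_neglog
from .records import OdnRecord, PairingError


def build_comparison(odns: Sequence[OdnRecord]) -> pd.DataFrame:
    """Pair WT/minor probes per rsid and compute both delta columns.

    measured -ln K_D is recomputed from the nM value; deltas are
    (-ln K_D)_min - (-ln K_D)_wt within each SNP and attached to both
    rows of the pair.
    """
    pairs: dict[tuple[str, str], dict[str, OdnRecord]] = defaultdict(dict)
    order: list[tuple[str, str]] = []
    for odn in odns:
        key = (odn.gene_id, odn.rsid)
        if key not in order:
            order.append(key)
        if odn.allele_class in pairs[key]:
            raise PairingError(f"duplicate {odn.allele_class} allele for {key}")
        pairs[key][odn.allele_class] = odn
    rows = []
    for key in order:
        pair = pairs[key]
        if set(pair) != {"WT", "min"}:
            raise PairingError(
                f"{key}: expected one WT and one min allele, got {sorted(pair)}"
            )
        wt, mn = pair["WT"], pair["min"]
        measured = {a: kd_nM_to_neglog(o.measured_kd_nM)
                    for a, o in pair.items()}
        pred_delta = mn.predicted_neglog_kd - wt.predicted_neglog_kd
        meas_delta = measured["min"] - measured["WT"]
        for allele in ("WT", "min"):
            o = pair[allele]
            rows.append({
                "gene": o.gene_id,
                "rsid": o.rsid,
                "allele": allele,
                "sequence": o.sequence,
                "predicted_neglog_kd": o.predicted_neglog_kd,
                "measured_kd_nM": o.measured_kd_nM,
                "measured_kd_sem_nM": o.measured_kd_sem_nM,
                "measured_neglog_kd": measured[allele],
                "predicted_delta": pred_delta,
                "measured_delta": meas_delta,
            })
    return pd.DataFrame(rows)


def _check_xy(x, y, min_n=3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} points, got {len(x)}")
    return x, y


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation and its two-sided t-transform p-value."""
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def spearman_rho(x, y) -> tuple[float, float]:
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall's tau-b (tie-corrected)."""
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    tau, p = stats.kendalltau(x, y, variant="b")
    return float(tau), float(p)


def gk_gamma(x, y) -> float:
    """Goodman-Kruskal gamma: (C - D) / (C + D) over all point pairs,
    pairs tied on either coordinate excluded."""
    x, y = _check_xy(x, y)
    concordant = discordant = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            s = (x[i] - x[j]) * (y[i] - y[j])
            if s > 0:
                concordant += 1
            elif s < 0:
                discordant += 1
    if concordant + discordant == 0:
        raise ValueError("gamma undefined: all pairs tied")
    return (concordant - discordant) / (concordant + discordant)


def correlation_summary(x, y) -> dict[str, float]:
    """All four association measures between two vectors."""
    r, r_p = pearson_r(x, y)
    rho, rho_p = spearman_rho(x, y)
    tau, tau_p = kendall_tau(x, y)
    return {
        "pearson_r": r,
        "pearson_p": r_p,
        "spearman_rho": rho,
        "spearman_p": rho_p,
        "kendall_tau": tau,
        "kendall_p": tau_p,
        "gk_gamma": gk_gamma(x, y),
        "n": len(np.asarray(x)),
    }


def comparison_correlations(table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Correlation panels for a comparison table: the per-allele
    absolute scale (-ln K_D, all rows) and the per-SNP relative scale
    (delta ln K_D, one point per pair)."""
    absolute = correlation_summary(
        table["predicted_neglog_kd"], table["measured_neglog_kd"]
    )
    pairs = table.drop_duplicates(subset=["gene", "rsid"])
    relative = correlation_summary(
        pairs["predicted_delta"], pairs["measured_delta"]
    )
    return {"absolute": absolute, "relative": relative}


def plot_comparison(table: pd.DataFrame, path) -> None:
    """Two-panel scatter (absolute and relative scales) with the OLS
    line and its 95% confidence band. Figure-only output."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = table.drop_duplicates(subset=["gene", "rsid"])
    panels = [
        (table["predicted_neglog_kd"], table["measured_neglog_kd"],
         "-ln K_D (predicted)", "-ln K_D (measured)"),
        (pairs["predicted_delta"], pairs["measured_delta"],
         "delta ln K_D (predicted)", "delta ln K_D (measured)"),
    ]
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, (x, y, xl, yl) in zip(axes, panels):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        res = stats.linregress(x, y)
        grid = np.linspace(x.min(), x.max(), 100)
        fitted = res.intercept + res.slope * grid
        n = len(x)
        s_err = np.sqrt(np.sum((y - (res.intercept + res.slope * x)) ** 2)
                        / (n - 2))
        t = stats.t.ppf(0.975, n - 2)
        half = t * s_err * np.sqrt(1 / n + (grid - x.mean()) ** 2
                                   / np.sum((x - x.mean()) ** 2))
        ax.scatter(x, y, color="k")
        ax.plot(grid, fitted, "b-")
        ax.plot(grid, fitted - half, "b--", lw=0.8)
        ax.plot(grid, fitted + half, "b--", lw=0.8)
        r, p = pearson_r(x, y)
        ax.set_title(f"r = {r:.2f}, p = {p:.3g}")
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
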