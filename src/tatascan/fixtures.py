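"""Packaged reference fixtures.

Two small tables ship with the package:

* the five-SNP in-vitro verification panel (ten 26-bp ODN probes with
  predicted -ln K_D and EMSA-measured K_D +/- SEM), including the
  rsID-labelling conflicts of the source tables, stored verbatim and
  flagged rather than resolved; and
* the per-gene-class marker-count table (N_RES, N_>, N_<, N_up, N_dn)
  with the printed probability bounds kept as strings.

``panel_promoters`` builds synthetic 70-bp promoters that embed each
verification ODN at its SNP's offset between GC-only flanks. Flanks
are verified against the scorer so that the promoter-level allele
difference keeps the sign of the probe-level difference (for a strong
site such as the SHOX TATA box the best promoter window is exactly the
embedded probe window; for weak sites the best window may be the probe
frame shifted into the flank by a base or two, which max-over-windows
scoring makes explicit). The flanks are synthetic filler, not genomic
sequence.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .affinity import AffinityModelConfig, promoter_affinity, window_affinity
from .records import (
    PROMOTER_LENGTH,
    OdnRecord,
    PromoterRecord,
    SnpRecord,
    apply_allele,
)
from .selection import SelectionCounts

#: 0-based position of the SNP base within each 26-bp ODN.
ODN_SNP_INDEX = 13


def _data_path(name: str):
    return resources.files("tatascan.data") / name


def verification_panel_frame() -> pd.DataFrame:
    with resources.as_file(_data_path("verification_panel.tsv")) as path:
        return pd.read_csv(path, sep="\t", keep_default_na=False)


def load_verification_panel() -> list[OdnRecord]:
    return [
        OdnRecord(
            gene_id=row.gene,
            rsid=row.rsid,
            allele_class=row.allele_class,
            sequence=row.sequence,
            predicted_neglog_kd=float(row.predicted_neglog_kd),
            measured_kd_nM=float(row.measured_kd_nM),
            measured_kd_sem_nM=float(row.measured_kd_sem_nM),
            rsid_conflict=row.rsid_conflict,
        )
        for row in verification_panel_frame().itertuples()
    ]


def marker_counts_frame() -> pd.DataFrame:
    with resources.as_file(_data_path("marker_counts.tsv")) as path:
        return pd.read_csv(path, sep="\t", keep_default_na=False)


def load_marker_counts(include_reference_rows: bool = False,
                       ) -> list[SelectionCounts]:
    rows = []
    for row in marker_counts_frame().itertuples():
        if not include_reference_rows and str(row.class_label).startswith(
                ("whole_genome", "clinical", "female")):
            continue
        rows.append(
            SelectionCounts(
                class_label=row.class_label,
                n_res=int(row.n_res),
                n_gt=int(row.n_gt),
                n_lt=int(row.n_lt),
                n_up=int(row.n_up) if str(row.n_up).strip() else 0,
                n_dn=int(row.n_dn) if str(row.n_dn).strip() else 0,
                n_gene=int(row.n_gene),
                n_snp=int(row.n_snp),
            )
        )
    return rows


def calibrate_model(residual_sd_sigma: float = 0.20):
    """Least-squares calibration of the affinity model on the ten
    verification-panel predictions (the packaged default configuration
    is this fit, frozen)."""
    from .affinity import TbpAffinityModel

    odns = load_verification_panel()
    X = [o.sequence for o in odns]
    y = [o.predicted_neglog_kd for o in odns]
    return TbpAffinityModel(residual_sd_sigma=residual_sd_sigma).fit(X, y)


def panel_snps() -> list[SnpRecord]:
    """The five verification SNPs, ref/alt read off the probe strand."""
    frame = verification_panel_frame()
    snps = []
    for (gene, rsid), grp in frame.groupby(["gene", "rsid"], sort=False):
        wt = grp[grp.allele_class == "WT"].iloc[0]
        mn = grp[grp.allele_class == "min"].iloc[0]
        snps.append(
            SnpRecord(
                rsid=rsid,
                gene_id=gene,
                offset=int(wt.snp_offset),
                ref_allele=wt.sequence[ODN_SNP_INDEX],
                alt_allele=mn.sequence[ODN_SNP_INDEX],
            )
        )
    return snps


def panel_promoters(config: AffinityModelConfig | None = None,
                     seed: int = 2020) -> list[PromoterRecord]:
    """Synthetic 70-bp promoters embedding the WT verification ODNs.

    Flanks are GC-only and verified so that the promoter-level
    delta ln K_D between the two alleles has the probe-level sign and
    that each allele's best window covers the SNP base.
    """
    if config is None:
        config = AffinityModelConfig.default()
    frame = verification_panel_frame()
    snps = {s.gene_id: s for s in panel_snps()}
    rng = np.random.default_rng(seed)
    promoters = []
    for (gene, _rsid), grp in frame.groupby(["gene", "rsid"], sort=False):
        wt = grp[grp.allele_class == "WT"].iloc[0]
        mn = grp[grp.allele_class == "min"].iloc[0]
        snp = snps[gene]
        snp_index = PROMOTER_LENGTH + snp.offset
        start = snp_index - ODN_SNP_INDEX
        if not 0 <= start <= PROMOTER_LENGTH - len(wt.sequence):
            raise ValueError(f"{gene}: ODN does not fit at offset {snp.offset}")
        for _attempt in range(100):
            flank = rng.choice(list("GC"), size=PROMOTER_LENGTH)
            seq = "".join(flank[:start]) + wt.sequence.upper() + "".join(
                flank[start + len(wt.sequence):]
            )
            promoter = PromoterRecord(gene_id=gene, sequence=seq)
            wt_seq, min_seq = apply_allele(promoter, snp)
            est_wt = promoter_affinity(wt_seq, config)
            est_mn = promoter_affinity(min_seq, config)
            delta_prom = est_mn.neglog_kd - est_wt.neglog_kd
            delta_odn = (window_affinity(mn.sequence.upper(), config)
                         - window_affinity(wt.sequence.upper(), config))
            covers_snp = all(
                e.best_window_offset <= snp_index
                < e.best_window_offset + config.window_length
                for e in (est_wt, est_mn)
            )
            if covers_snp and np.sign(delta_prom) == np.sign(delta_odn):
                promoters.append(promoter)
                break
        else:
            raise RuntimeError(f"{gene}: could not build weak flanks")
    return promoters
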