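"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: 70-bp
promoters with a planted TATA-like element over a configurable GC
background, substitution SNPs whose direction of effect on the planted
element is known by construction, marker-count tables drawn under a
chosen improve:damage regime, and saturation-kinetics curves with
Gaussian noise.

The planted element is the consensus of the affinity model's own PWM,
so "improve" and "damage" are well-defined relative to the scorer;
every generated SNP is additionally verified against the scorer
(rejection sampling over fresh backgrounds) before it is returned.
Generators are fully deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .affinity import AffinityModelConfig, promoter_affinity
from .kinetics import KineticsDataset
from .records import PROMOTER_LENGTH, PromoterRecord, SnpRecord, apply_allele
from .selection import SelectionCounts


class GeneratorError(RuntimeError):
    """The requested construction is impossible or verification failed."""


@dataclass
class CountsRegime:
    """Regime for marker-count tables: how many markers, what fraction
    improves affinity, what fraction raises reproductive potential."""

    n_res: int = 261
    improve_fraction: float = 0.2
    up_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.improve_fraction <= 1 and 0 <= self.up_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.n_res < 0:
            raise ValueError("n_res must be >= 0")


@dataclass
class KineticsTruth:
    """Generating parameters for saturation-binding curves."""

    kd_nM: float = 100.0
    vmax: float = 1.0
    noise_sd: float = 0.05
    concentrations_nM: tuple[float, ...] = (25.0, 50.0, 100.0, 400.0)


@dataclass
class SimSpec:
    seed: int = 0
    n_promoters: int = 100
    gc_background: float = 0.5
    tata_core: str = "consensus"      # or "weakened"
    planted_offset: int = 20          # 0-based 5' start of the 15-bp element
    snp_effect: str = "damage"        # improve | damage | neutral
    counts_regime: CountsRegime = field(default_factory=CountsRegime)
    kinetics_truth: KineticsTruth = field(default_factory=KineticsTruth)

    def __post_init__(self) -> None:
        if not 0 < self.gc_background < 1:
            raise ValueError("gc_background must lie in (0, 1)")
        if self.snp_effect not in ("improve", "damage", "neutral"):
            raise ValueError(f"snp_effect {self.snp_effect!r}")
        if self.tata_core not in ("consensus", "weakened"):
            raise ValueError(f"tata_core {self.tata_core!r}")


def _informative_position(config: AffinityModelConfig) -> tuple[int, str, str]:
    """Most informative PWM core position and its best/worst base.

    Restricted to the recognition core (positions 2-8 of the 15-mer)
    where the count contrast is large.
    """
    best_j, best_contrast = 1, -1.0
    for j in range(1, 8):
        col = {b: config.pwm_counts[b][j] for b in "ACGT"}
        contrast = max(col.values()) - min(col.values())
        if contrast > best_contrast:
            best_j, best_contrast = j, contrast
    col = {b: config.pwm_counts[b][best_j] for b in "ACGT"}
    consensus = max(col, key=col.get)
    worst = min(col, key=col.get)
    return best_j, consensus, worst


def _background(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return list(rng.choice(list("ACGT"), size=n, p=p))


def _build_promoter(rng, spec, config, core_seq, gene_id) -> PromoterRecord:
    start = spec.planted_offset
    if not 0 <= start <= PROMOTER_LENGTH - len(core_seq):
        raise GeneratorError(
            f"planted element at {start} does not fit inside the promoter"
        )
    bases = _background(rng, PROMOTER_LENGTH, spec.gc_background)
    bases[start:start + len(core_seq)] = list(core_seq)
    return PromoterRecord(gene_id=gene_id, sequence="".join(bases))


def _one_snp(rng: np.random.Generator, spec: SimSpec,
             config: AffinityModelConfig, gene_id: str,
             ) -> tuple[PromoterRecord, SnpRecord, int]:
    consensus = config.consensus()
    j, best_base, worst_base = _informative_position(config)
    core_index = spec.planted_offset + j
    window = config.window_length
    # promoter positions covered by any 26-bp window containing the core
    lo = max(0, spec.planted_offset - (window - config.pwm_length))
    hi = min(PROMOTER_LENGTH, spec.planted_offset + window)

    if spec.snp_effect == "improve" and spec.tata_core == "consensus":
        raise GeneratorError(
            "cannot improve a perfect-consensus element; use a weakened core"
        )
    core = consensus
    if spec.tata_core == "weakened" or spec.snp_effect == "improve":
        core = consensus[:j] + worst_base + consensus[j + 1:]

    for _attempt in range(200):
        promoter = _build_promoter(rng, spec, config, core, gene_id)
        if spec.snp_effect == "damage":
            offset = core_index - PROMOTER_LENGTH
            ref, alt, truth = best_base, worst_base, -1
        elif spec.snp_effect == "improve":
            offset = core_index - PROMOTER_LENGTH
            ref, alt, truth = worst_base, best_base, +1
        else:
            candidates = [i for i in range(PROMOTER_LENGTH)
                          if i < lo or i >= hi]
            if not candidates:
                raise GeneratorError(
                    "no promoter position lies outside every core window"
                )
            i = int(rng.choice(candidates))
            offset = i - PROMOTER_LENGTH
            ref = promoter.sequence[i]
            alt = {"G": "C", "C": "G", "A": "T", "T": "A"}[ref]
            truth = 0
        snp = SnpRecord(rsid=f"sim{spec.seed}_{gene_id}", gene_id=gene_id,
                        offset=offset, ref_allele=ref, alt_allele=alt)
        wt_seq, min_seq = apply_allele(promoter, snp)
        delta = (promoter_affinity(min_seq, config).neglog_kd
                 - promoter_affinity(wt_seq, config).neglog_kd)
        if (truth < 0 and delta < 0) or (truth > 0 and delta > 0) or \
                (truth == 0 and delta == 0):
            return promoter, snp, truth
    raise GeneratorError(
        f"could not construct a verified {spec.snp_effect} SNP in 200 tries"
    )


def gen_promoter_with_snp(spec: SimSpec,
                          config: AffinityModelConfig | None = None,
                          ) -> tuple[PromoterRecord, SnpRecord, int]:
    """One promoter + SNP with known truth direction (-1, 0 or +1 for
    the intended sign of delta ln K_D)."""
    if config is None:
        config = AffinityModelConfig.default()
    rng = np.random.default_rng(spec.seed)
    return _one_snp(rng, spec, config, gene_id="SIMGENE")


def gen_promoters(spec: SimSpec, config: AffinityModelConfig | None = None,
                  ) -> Iterator[tuple[PromoterRecord, SnpRecord, int]]:
    """``spec.n_promoters`` independent draws from one seeded stream."""
    if config is None:
        config = AffinityModelConfig.default()
    rng = np.random.default_rng(spec.seed)
    for k in range(spec.n_promoters):
        yield _one_snp(rng, spec, config, gene_id=f"SIMGENE{k:04d}")


def gen_counts_table(spec: SimSpec) -> SelectionCounts:
    """Marker-count row drawn under the spec's improve:damage regime."""
    rng = np.random.default_rng(spec.seed)
    reg = spec.counts_regime
    if reg.n_res == 0:
        return SelectionCounts(class_label="simulated", n_res=0, n_gt=0,
                               n_lt=0, n_up=0, n_dn=0)
    n_gt = int(rng.binomial(reg.n_res, reg.improve_fraction))
    n_up = int(rng.binomial(reg.n_res, reg.up_fraction))
    return SelectionCounts(
        class_label="simulated",
        n_res=reg.n_res,
        n_gt=n_gt,
        n_lt=reg.n_res - n_gt,
        n_up=n_up,
        n_dn=reg.n_res - n_up,
    )


def gen_kinetics(spec: SimSpec) -> KineticsDataset:
    """Noisy saturation-binding curve at the spec's concentrations."""
    rng = np.random.default_rng(spec.seed)
    truth = spec.kinetics_truth
    c = np.asarray(truth.concentrations_nM, dtype=float)
    v = truth.vmax * c / (truth.kd_nM + c)
    v = np.clip(v + rng.normal(0.0, truth.noise_sd, size=c.shape), 0.0, None)
    return KineticsDataset(concentrations_nM=c, rates=v)
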