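"""Sequence-based estimate of TBP-promoter binding affinity.

The equilibrium dissociation constant K_D of the TBP-DNA complex is
modelled on the -ln(K_D in molar) scale. A 26-bp window is scored as a
linear combination of three terms mirroring the elementary steps of
TBP-TATA recognition:

* **slide** -- TpA dinucleotide-step density over the window. TBP
  reaches its site by one-dimensional diffusion along the minor groove,
  which is easiest across weakly stacked, deformable TpA steps.
* **stop** -- the best match of any 15-bp sub-window to the canonical
  TATA-box position count matrix (log-odds against a uniform
  background); TBP halts where the recognition element is strongest.
* **bend** -- mean nearest-neighbour stacking free energy (unified
  dimer parameters, kcal/mol at 37C) over that best 15-bp sub-window;
  TBP bends the site by ~80 degrees, so weakly stacked (less negative
  dG) sites pay a smaller deformation penalty.

The three terms are combined linearly,

    -ln K_D = b0 + b_slide * f_TA + b_stop * S_pwm + b_bend * dG_site,

with coefficients calibrated by ordinary least squares against a
reference panel of 26-bp oligonucleotide predictions (see
``TbpAffinityModel.fit`` and the packaged default configuration). A
promoter longer than 26 bp is scored by the single best (minimal-K_D)
26-bp window, so a 26-bp probe reproduces its own window score exactly.

The model's uncertainty is a single regression residual SD (sigma, ln
units) attached to every estimate; it feeds the Z-test that compares
two alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Sequence

import numpy as np
import yaml
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .records import DNA_ALPHABET, SequenceAlphabetError, SequenceLengthError

#: Canonical TATA-box/TBP position count matrix, 15 positions, built from
#: an alignment of 389 eukaryotic TATA-box sites (consensus cTATAWAWR
#: followed by a G-rich downstream stretch).
TBP_PWM_COUNTS: dict[str, tuple[int, ...]] = {
    "A": (61, 16, 352, 3, 354, 268, 360, 222, 155, 56, 83, 82, 82, 68, 77),
    "C": (145, 46, 0, 10, 0, 0, 3, 2, 44, 135, 147, 127, 118, 107, 101),
    "G": (152, 18, 2, 2, 5, 0, 20, 44, 157, 150, 128, 128, 128, 139, 140),
    "T": (31, 309, 35, 374, 30, 121, 6, 121, 33, 48, 31, 52, 61, 75, 71),
}

#: Unified nearest-neighbour stacking free energies dG37 (kcal/mol),
#: 5'->3' top-strand dinucleotide steps of duplex DNA.
NN_STACKING_DG: dict[str, float] = {
    "AA": -1.00, "TT": -1.00, "AT": -0.88, "TA": -0.58,
    "CA": -1.45, "TG": -1.45, "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28, "GA": -1.30, "TC": -1.30,
    "CG": -2.17, "GC": -2.24, "GG": -1.84, "CC": -1.84,
}

WINDOW_LENGTH = 26
PWM_LENGTH = 15
_LN1E9 = math.log(1e9)


class AffinityConfigError(ValueError):
    """The affinity model configuration is incomplete or inconsistent."""


def kd_nM_to_neglog(kd_nM: float) -> float:
    """Convert K_D in nM to -ln(K_D in molar)."""
    if kd_nM <= 0:
        raise ValueError(f"K_D must be positive, got {kd_nM}")
    return -(math.log(kd_nM) - _LN1E9)


def neglog_to_kd_nM(neglog_kd: float) -> float:
    """Convert -ln(K_D in molar) to K_D in nM."""
    return 1e9 * math.exp(-neglog_kd)


@dataclass
class AffinityModelConfig:
    """Fully specified scoring model: tables, coefficients, uncertainty."""

    pwm_counts: dict[str, tuple[int, ...]]
    nn_dg: dict[str, float]
    coef_intercept: float
    coef_slide: float
    coef_stop: float
    coef_bend: float
    residual_sd_sigma: float = 0.20
    pwm_pseudocount: float = 1.0
    window_length: int = WINDOW_LENGTH
    pwm_length: int = PWM_LENGTH

    def __post_init__(self) -> None:
        if self.window_length != WINDOW_LENGTH:
            raise AffinityConfigError("window_length must be 26")
        if self.residual_sd_sigma <= 0:
            raise AffinityConfigError("residual_sd_sigma must be > 0")
        for base in "ACGT":
            if base not in self.pwm_counts:
                raise AffinityConfigError(f"pwm_counts missing base {base}")
            if len(self.pwm_counts[base]) != self.pwm_length:
                raise AffinityConfigError(
                    f"pwm_counts[{base}] must have {self.pwm_length} entries"
                )
        for a in "ACGT":
            for b in "ACGT":
                if a + b not in self.nn_dg:
                    raise AffinityConfigError(f"nn_dg missing step {a + b}")
        self._log_odds = _log_odds_matrix(self.pwm_counts, self.pwm_pseudocount)

    @property
    def log_odds(self) -> dict[str, np.ndarray]:
        return self._log_odds

    def consensus(self) -> str:
        """Highest-count base at each PWM position."""
        cols = []
        for j in range(self.pwm_length):
            cols.append(max("ACGT", key=lambda b: self.pwm_counts[b][j]))
        return "".join(cols)

    def to_yaml(self, path) -> None:
        payload = {
            "pwm_counts": {b: list(v) for b, v in self.pwm_counts.items()},
            "nn_dg": dict(self.nn_dg),
            "coef_intercept": float(self.coef_intercept),
            "coef_slide": float(self.coef_slide),
            "coef_stop": float(self.coef_stop),
            "coef_bend": float(self.coef_bend),
            "residual_sd_sigma": float(self.residual_sd_sigma),
            "pwm_pseudocount": float(self.pwm_pseudocount),
            "window_length": self.window_length,
            "pwm_length": self.pwm_length,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AffinityModelConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["pwm_counts"] = {
            b: tuple(v) for b, v in payload["pwm_counts"].items()
        }
        return cls(**payload)

    @classmethod
    def default(cls) -> "AffinityModelConfig":
        """The packaged calibrated configuration."""
        ref = resources.files("tatascan.data") / "tbp_model.yaml"
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


def _log_odds_matrix(counts, pseudocount) -> dict[str, np.ndarray]:
    total = sum(counts[b][0] for b in "ACGT")
    return {
        b: np.log(
            (np.asarray(counts[b], dtype=float) + pseudocount)
            / (total + 4 * pseudocount)
            / 0.25
        )
        for b in "ACGT"
    }


def _validate_seq(seq: str, min_len: int) -> str:
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise SequenceAlphabetError(f"non-ACGT base(s) {sorted(bad)}")
    if len(seq) < min_len:
        raise SequenceLengthError(
            f"sequence length {len(seq)} < required {min_len}"
        )
    return seq


def pwm_best_subwindow(seq: str, config: AffinityModelConfig) -> tuple[float, int]:
    """Best 15-bp log-odds PWM score within ``seq`` and its start index."""
    lo = config.log_odds
    L = config.pwm_length
    best_score, best_i = -math.inf, 0
    for i in range(len(seq) - L + 1):
        s = sum(lo[seq[i + j]][j] for j in range(L))
        if s > best_score:
            best_score, best_i = s, i
    return best_score, best_i


def window_features(seq26: str, config: AffinityModelConfig) -> tuple[float, float, float]:
    """(slide, stop, bend) features of one 26-bp window."""
    n_steps = len(seq26) - 1
    slide = sum(
        1 for i in range(n_steps) if seq26[i:i + 2] == "TA"
    ) / n_steps
    stop, best_i = pwm_best_subwindow(seq26, config)
    site = seq26[best_i:best_i + config.pwm_length]
    bend = sum(
        config.nn_dg[site[i:i + 2]] for i in range(len(site) - 1)
    ) / (len(site) - 1)
    return slide, stop, bend


def window_affinity(seq26: str, config: AffinityModelConfig | None = None) -> float:
    """-ln K_D (ln-molar) of TBP for one 26-bp window."""
    if config is None:
        config = AffinityModelConfig.default()
    seq26 = _validate_seq(seq26, config.window_length)
    if len(seq26) != config.window_length:
        raise SequenceLengthError(
            f"window_affinity expects exactly {config.window_length} bp, "
            f"got {len(seq26)}"
        )
    slide, stop, bend = window_features(seq26, config)
    return (
        config.coef_intercept
        + config.coef_slide * slide
        + config.coef_stop * stop
        + config.coef_bend * bend
    )


@dataclass
class AffinityEstimate:
    """Promoter-level affinity: -ln K_D, its uncertainty and nM scale."""

    neglog_kd: float
    se: float
    kd_nM: float
    best_window_offset: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be > 0")


def promoter_affinity(seq: str,
                      config: AffinityModelConfig | None = None) -> AffinityEstimate:
    """Score a promoter (>= 26 bp) as the single best 26-bp window.

    The strongest window (largest -ln K_D, i.e. smallest K_D) defines
    the promoter estimate; ``best_window_offset`` is its 0-based start.
    """
    if config is None:
        config = AffinityModelConfig.default()
    seq = _validate_seq(seq, config.window_length)
    W = config.window_length
    best_score, best_off = -math.inf, 0
    for i in range(len(seq) - W + 1):
        s = window_affinity(seq[i:i + W], config)
        if s > best_score:
            best_score, best_off = s, i
    return AffinityEstimate(
        neglog_kd=best_score,
        se=config.residual_sd_sigma,
        kd_nM=neglog_to_kd_nM(best_score),
        best_window_offset=best_off,
    )


class TbpAffinityModel(BaseEstimator, RegressorMixin):
    """Sequence-based TBP affinity estimator (scikit-learn interface).

    ``fit`` calibrates the linear slide/stop/bend combination by
    ordinary least squares against known -ln K_D values of 26-bp
    probes; ``predict`` scores arbitrary sequences (>= 26 bp) by their
    best 26-bp window.

    Parameters
    ----------
    pwm_counts : dict or None
        Position count matrix; None selects the canonical TATA matrix.
    pwm_pseudocount : float
        Laplace pseudocount for the log-odds transform.
    residual_sd_sigma : float
        Model uncertainty (ln units) attached to every estimate.
    """

    def __init__(self, pwm_counts=None, pwm_pseudocount: float = 1.0,
                 residual_sd_sigma: float = 0.20):
        self.pwm_counts = pwm_counts
        self.pwm_pseudocount = pwm_pseudocount
        self.residual_sd_sigma = residual_sd_sigma

    def _base_config(self, coefs=(0.0, 0.0, 0.0, 0.0)) -> AffinityModelConfig:
        counts = self.pwm_counts if self.pwm_counts is not None else TBP_PWM_COUNTS
        return AffinityModelConfig(
            pwm_counts=counts,
            nn_dg=NN_STACKING_DG,
            coef_intercept=coefs[0],
            coef_slide=coefs[1],
            coef_stop=coefs[2],
            coef_bend=coefs[3],
            residual_sd_sigma=self.residual_sd_sigma,
            pwm_pseudocount=self.pwm_pseudocount,
        )

    def _features(self, X: Sequence[str], config) -> np.ndarray:
        rows = []
        for seq in X:
            seq = _validate_seq(seq, config.window_length)
            # feature of the best window so probes and promoters share scale
            W = config.window_length
            best, feats = -math.inf, None
            for i in range(len(seq) - W + 1):
                f = window_features(seq[i:i + W], config)
                s = (config.coef_slide * f[0] + config.coef_stop * f[1]
                     + config.coef_bend * f[2])
                if s > best:
                    best, feats = s, f
            rows.append(feats)
        return np.asarray(rows)

    def fit(self, X: Sequence[str], y) -> "TbpAffinityModel":
        """Least-squares calibration on probe sequences and -ln K_D values."""
        y = np.asarray(y, dtype=float)
        base = self._base_config()
        # calibration probes are scored as single windows; require 26-mers
        for seq in X:
            if len(seq) != base.window_length:
                raise SequenceLengthError(
                    "calibration sequences must be single 26-bp windows"
                )
        F = self._features(X, base)
        design = np.column_stack([np.ones(len(F)), F])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.coef_ = beta[1:]
        self.intercept_ = float(beta[0])
        self.config_ = self._base_config(coefs=(beta[0], *beta[1:]))
        resid = y - design @ beta
        self.residuals_ = resid
        # hat-matrix leave-one-out residuals of the calibration fit
        H = design @ np.linalg.pinv(design.T @ design) @ design.T
        self.loo_residuals_ = resid / (1.0 - np.diag(H))
        self.n_features_in_ = design.shape[1] - 1
        return self

    @classmethod
    def from_config(cls, config: AffinityModelConfig | None = None) -> "TbpAffinityModel":
        """A ready-to-predict model from a (packaged) configuration."""
        if config is None:
            config = AffinityModelConfig.default()
        model = cls(pwm_counts=config.pwm_counts,
                    pwm_pseudocount=config.pwm_pseudocount,
                    residual_sd_sigma=config.residual_sd_sigma)
        model.config_ = config
        model.intercept_ = config.coef_intercept
        model.coef_ = np.array(
            [config.coef_slide, config.coef_stop, config.coef_bend]
        )
        model.n_features_in_ = 3
        return model

    def predict(self, X: Sequence[str]) -> np.ndarray:
        """Best-window -ln K_D for each sequence (>= 26 bp)."""
        check_is_fitted(self, "config_")
        return np.array(
            [promoter_affinity(seq, self.config_).neglog_kd for seq in X]
        )

    def estimate(self, seq: str) -> AffinityEstimate:
        check_is_fitted(self, "config_")
        return promoter_affinity(seq, self.config_)
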