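"""Additive variance decomposition of segregant decision thresholds.

The model is V_P = epsilon^2 + V_GAL3 + V_BG with no dominance, epistasis or
gene-by-environment terms (haploid, isogenic-environment design).  Two bounds
on the focal-allele contribution are reported: an upper bound using the
background variance of the allele-fixed (swap) hybrids and a lower bound
using the segregating wild-type hybrid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "VarianceDecomposition",
    "estimate_measurement_error",
    "filter_segregant_replicates",
    "allele_effect",
    "partition_variance",
]


@dataclass
class VarianceDecomposition:
    epsilon: float
    epsilon_sq: float
    v_p: dict[str, float]
    e_gal3: float
    v_gal3: float
    v_bg_swap: float
    v_bg_wt: float
    contribution_upper: Optional[float]
    contribution_lower: Optional[float]
    # alternate convention: subtract full epsilon^2 instead of epsilon^2/2
    contribution_upper_full_eps: Optional[float] = None
    contribution_lower_full_eps: Optional[float] = None
    # explicit zeros of the model assumptions
    v_d: float = 0.0
    v_i: float = 0.0
    v_eg: float = 0.0
    clamped: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "epsilon_sq": self.epsilon_sq,
            "v_p": self.v_p,
            "e_gal3": self.e_gal3,
            "v_gal3": self.v_gal3,
            "v_bg_swap": self.v_bg_swap,
            "v_bg_wt": self.v_bg_wt,
            "contribution_upper": self.contribution_upper,
            "contribution_lower": self.contribution_lower,
            "contribution_upper_full_eps": self.contribution_upper_full_eps,
            "contribution_lower_full_eps": self.contribution_lower_full_eps,
            "v_d": self.v_d,
            "v_i": self.v_i,
            "v_eg": self.v_eg,
            "clamped": list(self.clamped),
        }


def estimate_measurement_error(rep1: np.ndarray, rep2: np.ndarray) -> float:
    """Per-measurement error from replicate pairs.

    The variance of inter-replicate differences is twice the per-measurement
    variance, so a Normal(mu, sigma) is fit to rep1 - rep2 and
    epsilon = sigma / sqrt(2).
    """
    rep1 = np.asarray(rep1, float)
    rep2 = np.asarray(rep2, float)
    if rep1.size != rep2.size:
        raise ValueError("replicate arrays must have equal length")
    if rep1.size < 10:
        raise ValueError(f"need >= 10 replicate pairs, got {rep1.size}")
    _, sigma = norm.fit(rep1 - rep2)
    return float(sigma / np.sqrt(2.0))


def filter_segregant_replicates(
    table: pd.DataFrame, cutoff: float = 1.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop segregants whose half inter-replicate difference exceeds cutoff.

    A segregant is removed iff |rep1 - rep2| / 2 > cutoff (strict).  Returns
    (kept rows, dropped rows).
    """
    half_diff = (table["rep1"] - table["rep2"]).abs() / 2.0
    keep = ~(half_diff > cutoff)
    return table[keep].reset_index(drop=True), table[~keep].reset_index(drop=True)


def allele_effect(
    pop_a: np.ndarray, pop_neg_a: np.ndarray
) -> tuple[float, float]:
    """Focal-allele effect and variance from the two allele-class means.

    E = (mean_a - mean_(-a)) / 2; V = E^2.
    """
    pop_a = np.asarray(pop_a, float)
    pop_neg_a = np.asarray(pop_neg_a, float)
    if pop_a.size == 0 or pop_neg_a.size == 0:
        raise ValueError("both allele classes must be nonempty")
    e = float((pop_a.mean() - pop_neg_a.mean()) / 2.0)
    return e, e * e


def _rep_means(table: pd.DataFrame) -> np.ndarray:
    rep_cols = [c for c in table.columns if c.startswith("rep")]
    return table[rep_cols].mean(axis=1).to_numpy()


def partition_variance(
    tables: dict[str, pd.DataFrame],
    epsilon: float,
    use_half_epsilon: bool = True,
) -> VarianceDecomposition:
    """Partition V_P into measurement error, focal-allele and background terms.

    ``tables`` maps hybrid ids ('hybrid1' segregating, 'hybrid2'/'hybrid3'
    fixed) to filtered phenotype tables with rep columns and an ``allele``
    column for hybrid1.  The error variance subtracted from the variance of
    replicate means is epsilon^2/2 by default (each phenotype averages two
    replicates); set ``use_half_epsilon=False`` for the raw epsilon^2
    convention.  Both conventions are reported.
    """
    for h in ("hybrid1", "hybrid2", "hybrid3"):
        if h not in tables:
            raise ValueError(f"missing table for {h}")
    eps_sq = epsilon * epsilon
    n_reps = len([c for c in tables["hybrid1"].columns if c.startswith("rep")])
    eps_mean = eps_sq / n_reps if use_half_epsilon else eps_sq
    eps_mean_alt = eps_sq if use_half_epsilon else eps_sq / n_reps

    v_p = {h: float(np.var(_rep_means(t), ddof=1)) for h, t in tables.items()}

    h1 = tables["hybrid1"]
    alleles = set(h1["allele"].unique())
    if alleles >= {"a", "-a"}:
        e_gal3, v_gal3 = allele_effect(
            _rep_means(h1[h1["allele"] == "a"]),
            _rep_means(h1[h1["allele"] == "-a"]),
        )
    else:
        # allele labels unavailable in the segregating hybrid: fall back to
        # the swap-hybrid population means
        e_gal3, v_gal3 = allele_effect(
            _rep_means(tables["hybrid2"]), _rep_means(tables["hybrid3"])
        )

    clamped: list[str] = []

    def _bg(v_raw: float, label: str, eps_term: float) -> float:
        v = v_raw - eps_term
        if v < 0:
            clamped.append(label)
            warnings.warn(
                f"{label}: variance {v_raw:.4g} below error term "
                f"{eps_term:.4g}; clamped to 0",
                stacklevel=2,
            )
            return 0.0
        return v

    v_bg_swap = float(
        np.mean(
            [
                _bg(v_p["hybrid2"], "hybrid2", eps_mean),
                _bg(v_p["hybrid3"], "hybrid3", eps_mean),
            ]
        )
    )
    v_bg_wt = max(0.0, v_p["hybrid1"] - eps_mean - v_gal3)
    if v_p["hybrid1"] - eps_mean - v_gal3 < 0:
        clamped.append("hybrid1")

    def _contrib(v_bg: float) -> Optional[float]:
        denom = v_gal3 + v_bg
        return v_gal3 / denom if denom > 0 else None

    v_bg_swap_alt = float(
        np.mean(
            [
                max(0.0, v_p["hybrid2"] - eps_mean_alt),
                max(0.0, v_p["hybrid3"] - eps_mean_alt),
            ]
        )
    )
    v_bg_wt_alt = max(0.0, v_p["hybrid1"] - eps_mean_alt - v_gal3)

    return VarianceDecomposition(
        epsilon=float(epsilon),
        epsilon_sq=float(eps_sq),
        v_p=v_p,
        e_gal3=float(e_gal3),
        v_gal3=float(v_gal3),
        v_bg_swap=v_bg_swap,
        v_bg_wt=v_bg_wt,
        contribution_upper=_contrib(v_bg_swap),
        contribution_lower=_contrib(v_bg_wt),
        contribution_upper_full_eps=_contrib(v_bg_swap_alt),
        contribution_lower_full_eps=_contrib(v_bg_wt_alt),
        clamped=tuple(clamped),
    )
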