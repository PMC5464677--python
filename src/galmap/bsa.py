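"""Bulk-segregant mapping from ON/OFF pool allele counts.

The statistic is a binned binomial likelihood-ratio contrast: within each bin
the parent-A proportions of the two pools are compared under a shared-vs-free
hypothesis pair, with effective counts n_e = n*N/(n+N) limiting the read
information by the finite pool size N, and the resulting LOD profile smoothed
positionally with a Gaussian kernel on the linkage scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "BsaParameters",
    "LocusCall",
    "LocusCluster",
    "filter_allele_counts",
    "bin_allele_counts",
    "lod_profile",
    "bin_lod",
    "call_loci",
    "cluster_loci",
    "genes_in_interval",
]

COUNT_COLS = ["A_on", "B_on", "A_off", "B_off"]


@dataclass(frozen=True)
class BsaParameters:
    bin_bp: int = 100
    pool_n: int = 1000  # sorted pool size assumed by the statistic
    bp_per_cM: float = 2200.0
    smooth_cM: float = 5.0  # Gaussian kernel sd, in cM
    min_depth: int = 2
    max_depth: int = 1000
    lod_call: float = 10.0
    lod_report: float = 5.0
    support_drop: float = 2.0
    cluster_bp: int = 20_000

    def __post_init__(self) -> None:
        if min(self.bin_bp, self.pool_n, self.cluster_bp) <= 0:
            raise ValueError("bin_bp, pool_n and cluster_bp must be positive")
        if self.bp_per_cM <= 0 or self.smooth_cM < 0:
            raise ValueError("bp_per_cM must be positive, smooth_cM nonnegative")
        if self.lod_report > self.lod_call:
            raise ValueError("lod_report must not exceed lod_call")


@dataclass
class LocusCall:
    cross_id: str
    chrom: str
    peak_pos: int  # bp, bin midpoint
    peak_lod: float
    support_start: int  # 0-based half-open interval
    support_end: int
    allele_freq_difference: float


@dataclass
class LocusCluster:
    chrom: str
    members: list[LocusCall]
    support_start: int  # averaged over member support bounds
    support_end: int

    @property
    def n_crosses(self) -> int:
        return len({m.cross_id for m in self.members})


def filter_allele_counts(
    track: pd.DataFrame, min_depth: int = 2, max_depth: int = 1000
) -> tuple[pd.DataFrame, int]:
    """Keep SNPs where, in each pool, min_depth <= depth <= max_depth.

    Returns (filtered track, number of SNPs removed); raises if nothing
    survives.
    """
    if track.empty:
        raise ValueError("allele-count track is empty")
    d_on = track["A_on"] + track["B_on"]
    d_off = track["A_off"] + track["B_off"]
    keep = (
        (d_on >= min_depth)
        & (d_on <= max_depth)
        & (d_off >= min_depth)
        & (d_off <= max_depth)
    )
    removed = int((~keep).sum())
    out = track[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError(
            f"all {len(track)} SNPs removed by the depth filter "
            f"[{min_depth}, {max_depth}]"
        )
    return out, removed


def bin_allele_counts(track: pd.DataFrame, params: BsaParameters) -> pd.DataFrame:
    """Sum pool counts within bin_bp windows tiling each chromosome.

    Bins are 0-based half-open; SNP positions are 1-based on input.  Bins
    with no SNPs carry zero counts (they are interpolated over in the LOD
    profile).
    """
    frames = []
    for chrom, sub in track.groupby("chrom", sort=False):
        pos0 = sub["pos"].to_numpy() - 1  # to 0-based
        max_pos = int(pos0.max())
        n_bins = max_pos // params.bin_bp + 1
        idx = pos0 // params.bin_bp
        agg = {c: np.bincount(idx, weights=sub[c], minlength=n_bins) for c in COUNT_COLS}
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_start": np.arange(n_bins) * params.bin_bp,
                    "bin_end": (np.arange(n_bins) + 1) * params.bin_bp,
                    **{c: agg[c].astype(np.int64) for c in COUNT_COLS},
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _ll(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood up to the constant binomial coefficient."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(p), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log1p(-p), 0.0)
    return t1 + t2


def bin_lod(
    a_on: np.ndarray,
    b_on: np.ndarray,
    a_off: np.ndarray,
    b_off: np.ndarray,
    pool_n: int,
) -> np.ndarray:
    """Unsmoothed per-bin LOD of the ON/OFF allele-frequency contrast.

    Raw counts are rescaled to effective counts n_e = n*pool_n/(n+pool_n)
    (read noise composed with finite-pool noise), then LOD = log10 of the
    ratio of binomial likelihoods under per-pool MLE proportions versus a
    shared proportion.  Bins with zero depth in either pool give NaN.
    """
    a_on = np.asarray(a_on, float)
    b_on = np.asarray(b_on, float)
    a_off = np.asarray(a_off, float)
    b_off = np.asarray(b_off, float)
    n_on = a_on + b_on
    n_off = a_off + b_off
    with np.errstate(divide="ignore", invalid="ignore"):
        e_on = n_on * pool_n / (n_on + pool_n)
        e_off = n_off * pool_n / (n_off + pool_n)
        k_on = np.where(n_on > 0, a_on * e_on / n_on, 0.0)
        k_off = np.where(n_off > 0, a_off * e_off / n_off, 0.0)
        p_on = np.where(e_on > 0, k_on / e_on, 0.5)
        p_off = np.where(e_off > 0, k_off / e_off, 0.5)
        p0 = np.where(e_on + e_off > 0, (k_on + k_off) / (e_on + e_off), 0.5)
    lod = (
        _ll(k_on, e_on, p_on)
        + _ll(k_off, e_off, p_off)
        - _ll(k_on, e_on, p0)
        - _ll(k_off, e_off, p0)
    ) / np.log(10.0)
    lod = np.maximum(lod, 0.0)  # guard tiny negative rounding
    lod[(n_on == 0) | (n_off == 0)] = np.nan
    return lod


def _interp_nan(x: np.ndarray) -> np.ndarray:
    """Linear interpolation over NaN runs (edges held at nearest value)."""
    out = x.copy()
    bad = ~np.isfinite(out)
    if bad.all():
        return np.zeros_like(out)
    if bad.any():
        idx = np.arange(out.size)
        out[bad] = np.interp(idx[bad], idx[~bad], out[~bad])
    return out


def lod_profile(
    binned: pd.DataFrame, params: BsaParameters, cross_id: str = "cross"
) -> pd.DataFrame:
    """Smoothed LOD profile plus per-bin pool allele frequencies.

    Zero-depth bins are interpolated from neighbors before Gaussian smoothing
    with sd = smooth_cM * bp_per_cM along each chromosome.
    """
    frames = []
    sigma_bp = params.smooth_cM * params.bp_per_cM
    sigma_bins = sigma_bp / params.bin_bp
    for chrom, sub in binned.groupby("chrom", sort=False):
        lod = bin_lod(
            sub["A_on"].to_numpy(),
            sub["B_on"].to_numpy(),
            sub["A_off"].to_numpy(),
            sub["B_off"].to_numpy(),
            params.pool_n,
        )
        lod = _interp_nan(lod)
        if sigma_bins > 0:
            lod = gaussian_filter1d(lod, sigma_bins, mode="nearest")
        with np.errstate(divide="ignore", invalid="ignore"):
            f_on = sub["A_on"] / (sub["A_on"] + sub["B_on"])
            f_off = sub["A_off"] / (sub["A_off"] + sub["B_off"])
        frames.append(
            pd.DataFrame(
                {
                    "cross_id": cross_id,
                    "chrom": chrom,
                    "bin_start": sub["bin_start"].to_numpy(),
                    "bin_end": sub["bin_end"].to_numpy(),
                    "lod": lod,
                    "freqA_on": _interp_nan(f_on.to_numpy(float)),
                    "freqA_off": _interp_nan(f_off.to_numpy(float)),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _support_interval(lod: np.ndarray, peak: int, drop: float) -> tuple[int, int]:
    """Maximal contiguous bin range around the peak with lod >= peak - drop."""
    thr = lod[peak] - drop
    lo = peak
    while lo > 0 and lod[lo - 1] >= thr:
        lo -= 1
    hi = peak
    while hi < lod.size - 1 and lod[hi + 1] >= thr:
        hi += 1
    return lo, hi


def call_loci(
    profile: pd.DataFrame, params: BsaParameters
) -> tuple[list[LocusCall], list[LocusCall]]:
    """Local maxima above the call threshold with 2-LOD support intervals.

    Peaks sharing a support interval merge into the higher peak.  Returns
    (calls at lod > lod_call, secondary report at lod > lod_report).
    """
    calls: list[LocusCall] = []
    report: list[LocusCall] = []
    for chrom, sub in profile.groupby("chrom", sort=False):
        lod = sub["lod"].to_numpy()
        starts = sub["bin_start"].to_numpy()
        ends = sub["bin_end"].to_numpy()
        cross = sub["cross_id"].iloc[0]
        df_freq = (sub["freqA_on"] - sub["freqA_off"]).to_numpy()
        # local maxima (plateaus take the first bin)
        cand = [
            i
            for i in range(lod.size)
            if (i == 0 or lod[i] > lod[i - 1])
            and (i == lod.size - 1 or lod[i] >= lod[i + 1])
            and lod[i] > params.lod_report
        ]
        cand.sort(key=lambda i: -lod[i])
        claimed: list[tuple[int, int]] = []
        for i in cand:
            lo, hi = _support_interval(lod, i, params.support_drop)
            if any(lo <= c_hi and hi >= c_lo for c_lo, c_hi in claimed):
                continue  # merged into a previously accepted higher peak
            claimed.append((lo, hi))
            call = LocusCall(
                cross_id=cross,
                chrom=chrom,
                peak_pos=int((starts[i] + ends[i]) // 2),
                peak_lod=float(lod[i]),
                support_start=int(starts[lo]),
                support_end=int(ends[hi]),
                allele_freq_difference=float(df_freq[i]),
            )
            report.append(call)
            if lod[i] > params.lod_call:
                calls.append(call)
    key = lambda c: (c.chrom, c.peak_pos)
    return sorted(calls, key=key), sorted(report, key=key)


def cluster_loci(
    calls: Sequence[LocusCall], params: BsaParameters
) -> list[LocusCluster]:
    """Single-linkage clustering of peaks within cluster_bp on one chromosome.

    The cluster interval is the mean of member support bounds (averaged
    support interval).
    """
    clusters: list[LocusCluster] = []
    by_chrom: dict[str, list[LocusCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, members in sorted(by_chrom.items()):
        members.sort(key=lambda c: c.peak_pos)
        current = [members[0]]
        for c in members[1:]:
            if c.peak_pos - current[-1].peak_pos <= params.cluster_bp:
                current.append(c)
            else:
                clusters.append(_finish_cluster(chrom, current))
                current = [c]
        clusters.append(_finish_cluster(chrom, current))
    return clusters


def _finish_cluster(chrom: str, members: list[LocusCall]) -> LocusCluster:
    return LocusCluster(
        chrom=chrom,
        members=list(members),
        support_start=int(round(np.mean([m.support_start for m in members]))),
        support_end=int(round(np.mean([m.support_end for m in members]))),
    )


def genes_in_interval(
    chrom: str, start: int, end: int, features: Sequence
) -> list:
    """Gene features overlapping the 0-based half-open interval [start, end).

    Empty annotation gives an empty list; a nonempty annotation with no
    record of the requested chromosome raises, naming the sequence.
    """
    feats = list(features)
    if not feats:
        return []
    seqids = {f.seqid for f in feats}
    if chrom not in seqids:
        raise ValueError(
            f"unknown chromosome {chrom!r}; annotation covers {sorted(seqids)}"
        )
    hits = [f for f in feats if f.seqid == chrom and f.start < end and f.end > start]
    return sorted(hits, key=lambda f: f.start)
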