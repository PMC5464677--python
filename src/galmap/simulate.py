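"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline consumes tables produced here, so the
whole analysis is testable without any external data.  Each generator returns
its output together with a :class:`SimTruth` carrying the planted values; the
truth is echoed, never re-estimated.

All randomness flows from a single seed in :class:`SimConfig`; named
substreams are derived deterministically from it, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "SimConfig",
    "SimTruth",
    "StrainSpec",
    "GrowthParams",
    "VarpartParams",
    "VariantParams",
    "SegregantGenomes",
    "default_glucose_grid",
    "gen_flow_experiment",
    "gen_cross_segregants",
    "gen_pool_counts",
    "gen_varpart_populations",
    "gen_growth_curves",
    "gen_variant_data",
    "mean_block_length",
]

BASES = np.array(["A", "C", "G", "T"])
STOP_CODONS = {"TAA", "TAG", "TGA"}


def default_glucose_grid() -> list[float]:
    """Two-fold dilution series of glucose, 1% down to ~0.004% w/v."""
    return [1.0 / 2**i for i in range(9)]


@dataclass(frozen=True)
class StrainSpec:
    strain_id: str
    true_f50: float  # % w/v glucose
    hill_h: float = 2.0

    def __post_init__(self) -> None:
        if self.true_f50 <= 0:
            raise ValueError(f"true_f50 must be > 0, got {self.true_f50}")
        if self.hill_h <= 0:
            raise ValueError(f"hill_h must be > 0, got {self.hill_h}")


@dataclass(frozen=True)
class GrowthParams:
    rate1: float = 0.5  # doublings / hour, first (glucose) phase
    rate2: float = 0.35  # doublings / hour, second (galactose) phase
    lag_hours: float = 3.0
    od_start: float = 2.0**-8
    od_sat: float = 1.0
    od_noise_sd: float = 0.02  # additive on log2 OD
    sample_interval_h: float = 0.25

    def __post_init__(self) -> None:
        if self.rate1 <= 0 or self.rate2 <= 0:
            raise ValueError("growth rates must be positive")
        if self.lag_hours < 0:
            raise ValueError("lag_hours must be >= 0")
        if self.od_start >= self.od_sat:
            raise ValueError("od_start must be below od_sat")
        if self.od_noise_sd < 0:
            raise ValueError("od_noise_sd must be >= 0")


@dataclass(frozen=True)
class VarpartParams:
    n_segregants: int = 60
    n_reps: int = 2
    v_gal3: float = 0.86
    v_bg: float = 0.14
    epsilon: float = 0.10
    n_outliers: int = 0  # extra-low hybrid-1 segregants
    outlier_shift: float = 0.0  # log2 shift applied to the outliers

    def __post_init__(self) -> None:
        if min(self.v_gal3, self.v_bg, self.epsilon) < 0:
            raise ValueError("variance components must be nonnegative")
        if self.n_segregants < 1:
            raise ValueError("need at least one segregant")


@dataclass(frozen=True)
class VariantParams:
    n_strains: int = 55
    n_promoter_snps: int = 13
    n_coding_snps: int = 27
    n_haplotypes: int = 26
    outgroup_divergence_rate: float = 0.02
    cds_length_bp: int = 1563
    promoter_length_bp: int = 500

    def __post_init__(self) -> None:
        if self.n_haplotypes > self.n_strains:
            raise ValueError("n_haplotypes cannot exceed n_strains")
        if self.cds_length_bp % 3 != 0:
            raise ValueError("cds_length_bp must be divisible by 3")
        if not 0 <= self.outgroup_divergence_rate <= 1:
            raise ValueError("outgroup_divergence_rate must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Parameters for all generators; see module docstring for determinism."""

    seed: int = 0
    strains: tuple[StrainSpec, ...] = (
        StrainSpec("S1", 0.25, 2.0),
        StrainSpec("S2", 0.06, 2.0),
    )
    reference: StrainSpec = StrainSpec("REF", 0.25, 2.0)
    galactose_pct: float = 0.25
    glucose_grid: tuple[float, ...] = tuple(default_glucose_grid())
    control_glucose_pct: float = 2.0
    control_galactose_pct: float = 2.0
    cells_per_well: int = 300
    n_replicates: int = 2
    basal_mean: float = 2.0  # log10 fluorescence units
    induced_mean: float = 3.5
    channel_sd: float = 0.15
    measurement_sd_log2: float = 0.3  # replicate F50 jitter, log2(% glucose)
    outlier_rate: float = 0.0
    outlier_shift: float = 0.0  # log2 units, applied to whole experiments
    # cross / pool parameters
    chrom_lengths_bp: tuple[int, ...] = (3_000_000,) * 4
    snp_spacing_bp: int = 1000
    map_density_bp_per_cM: float = 2200.0
    qtl: Optional[tuple[str, int, float]] = ("chr1", 1_500_000, 1.0)
    background_effects: tuple[int, float] = (0, 0.0)  # (n_loci, per-locus sd)
    n_segregants: int = 1000
    pool_fraction: float = 0.05
    pool_size: int = 30_000
    mean_depth: float = 50.0
    intercross_rounds: int = 4
    segregant_noise_sd: float = 0.3  # phenotype noise at sort time, log2
    growth: GrowthParams = GrowthParams()
    varpart: VarpartParams = VarpartParams()
    variants: VariantParams = VariantParams()

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.glucose_grid):
            raise ValueError(
                f"glucose_grid must be strictly positive, got {self.glucose_grid}"
            )
        if not 0 < self.pool_fraction <= 0.5:
            raise ValueError("pool_fraction must be in (0, 0.5]")
        if self.cells_per_well < 1:
            raise ValueError("cells_per_well must be >= 1")
        if self.measurement_sd_log2 < 0 or self.channel_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must be a probability")
        if self.snp_spacing_bp < 1 or self.map_density_bp_per_cM <= 0:
            raise ValueError("SNP spacing and map density must be positive")
        if self.intercross_rounds < 0:
            raise ValueError("intercross_rounds must be >= 0")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Named deterministic substream of the global seed."""
        key = zlib.crc32(stream.encode())
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        )


@dataclass
class SimTruth:
    """Planted ground truth echoed by the generators."""

    strain_f50: Optional[dict[str, float]] = None
    replicate_log2_f50: Optional[dict[tuple[str, int], float]] = None
    outlier_experiments: Optional[list[tuple[str, int]]] = None
    qtl: Optional[tuple[str, int, float]] = None
    background_loci: Optional[list[tuple[str, int, float]]] = None
    v_gal3: Optional[float] = None
    v_bg: Optional[float] = None
    epsilon: Optional[float] = None
    lag_hours: Optional[dict[str, float]] = None
    n_haplotypes: Optional[int] = None
    n_haplotypes_coding: Optional[int] = None
    n_synonymous: Optional[int] = None
    n_nonsynonymous: Optional[int] = None
    n_promoter_snps: Optional[int] = None
    coding_labels: Optional[list[str]] = None

    def to_json(self) -> str:
        def _convert(obj):
            if isinstance(obj, dict):
                return {str(k): _convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_convert(v) for v in obj]
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj

        return json.dumps(_convert(dataclasses.asdict(self)), indent=1)


# ---------------------------------------------------------------------------
# flow cytometry titrations
# ---------------------------------------------------------------------------


def _mixture_well(
    rng: np.random.Generator,
    n_cells: int,
    induced_weight: float,
    basal_mean: float,
    induced_mean: float,
    channel_sd: float,
) -> np.ndarray:
    """Per-cell reporter values from a two-component log-normal mixture."""
    induced = rng.random(n_cells) < induced_weight
    log10_yfp = np.where(
        induced,
        rng.normal(induced_mean, channel_sd, n_cells),
        rng.normal(basal_mean, channel_sd, n_cells),
    )
    return 10.0**log10_yfp


def _induced_weight(glucose: float, f50: float, hill_h: float) -> float:
    if glucose <= 0:
        return 1.0
    return 1.0 / (1.0 + (glucose / f50) ** hill_h)


def gen_flow_experiment(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate co-culture glucose titrations for every strain/replicate.

    Each experiment (one query strain, one replicate) is a row of wells: the
    titration grid at constant galactose, plus a repressed 2%-glucose control
    and a fully induced 2%-galactose control.  Every well also contains
    reference-strain cells distinguished by a constitutive marker channel.
    Replicate-level F50 jitter is Normal in log2(% glucose); with probability
    ``outlier_rate`` an entire experiment (query and reference together) is
    shifted by ``outlier_shift``, emulating a bad well/plate.
    """
    rng = config.rng("flow")
    rows: list[pd.DataFrame] = []
    rep_truth: dict[tuple[str, int], float] = {}
    outliers: list[tuple[str, int]] = []

    def _emit(well_id, strain_id, role, g, gal, rep, f50, hill, marker_mu):
        weight = _induced_weight(g if gal == config.galactose_pct else -1.0, f50, hill)
        if g == config.control_glucose_pct and gal == 0.0:
            weight = 0.0  # fully repressed control
        yfp = _mixture_well(
            rng,
            config.cells_per_well,
            weight,
            config.basal_mean,
            config.induced_mean,
            config.channel_sd,
        )
        marker = 10.0 ** rng.normal(marker_mu, 0.1, config.cells_per_well)
        return pd.DataFrame(
            {
                "well_id": well_id,
                "strain_id": strain_id,
                "role": role,
                "glucose_pct": g,
                "galactose_pct": gal,
                "replicate": rep,
                "yfp": yfp,
                "marker": marker,
            }
        )

    for spec in config.strains:
        for rep in range(1, config.n_replicates + 1):
            shift = 0.0
            if config.outlier_rate > 0 and rng.random() < config.outlier_rate:
                shift = config.outlier_shift
                outliers.append((spec.strain_id, rep))
            q_f50 = spec.true_f50 * 2.0 ** (
                rng.normal(0.0, config.measurement_sd_log2) + shift
            )
            r_f50 = config.reference.true_f50 * 2.0 ** (
                rng.normal(0.0, config.measurement_sd_log2) + shift
            )
            rep_truth[(spec.strain_id, rep)] = float(np.log2(q_f50))
            wells = [(g, config.galactose_pct) for g in config.glucose_grid]
            wells.append((config.control_glucose_pct, 0.0))
            wells.append((0.0, config.control_galactose_pct))
            for wi, (g, gal) in enumerate(wells):
                well_id = f"{spec.strain_id}:r{rep}:w{wi}"
                rows.append(
                    _emit(well_id, spec.strain_id, "query", g, gal, rep, q_f50, spec.hill_h, 1.0)
                )
                rows.append(
                    _emit(
                        well_id,
                        config.reference.strain_id,
                        "reference",
                        g,
                        gal,
                        rep,
                        r_f50,
                        config.reference.hill_h,
                        3.0,
                    )
                )

    cells = pd.concat(rows, ignore_index=True)
    truth = SimTruth(
        strain_f50={s.strain_id: s.true_f50 for s in config.strains},
        replicate_log2_f50=rep_truth,
        outlier_experiments=outliers,
    )
    return cells, truth


# ---------------------------------------------------------------------------
# meiosis / intercross simulator
# ---------------------------------------------------------------------------


@dataclass
class SegregantGenomes:
    """Haploid segregant genotypes (0 = parent A, 1 = parent B) plus phenotypes."""

    chroms: list[str]
    positions: dict[str, np.ndarray]  # bp, 1-based, strictly increasing
    genotypes: dict[str, np.ndarray]  # (n_segregants, n_snps) int8
    phenotypes: np.ndarray  # log2 units, one sort-time value per segregant

    @property
    def n_segregants(self) -> int:
        return next(iter(self.genotypes.values())).shape[0]


def _meiosis_chrom(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    pos_bp: np.ndarray,
    length_bp: int,
    cm_per_bp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per diploid individual, Haldane crossover process.

    Crossover count per chromosome is Poisson with mean length_cM/100 and
    positions are uniform (no interference).  Vectorized over individuals.
    """
    n, m = hap_a.shape
    lam = length_bp * cm_per_bp / 100.0
    counts = rng.poisson(lam, n)
    total = int(counts.sum())
    ind = np.repeat(np.arange(n), counts)
    xo = rng.uniform(0.0, length_bp, total)
    # crossover at x flips parity for all SNPs with pos > x
    snp_idx = np.searchsorted(pos_bp, xo, side="left")
    hits = np.bincount(ind * (m + 1) + snp_idx, minlength=n * (m + 1))
    # per-individual crossover counts are small, so int8 cumsum is safe
    parity = hits.astype(np.int8).reshape(n, m + 1)[:, :m].cumsum(
        axis=1, dtype=np.int8
    )
    parity += rng.integers(0, 2, n, dtype=np.int8)[:, None]
    parity &= 1
    return np.where(parity == 0, hap_a, hap_b).astype(np.int8)


def gen_cross_segregants(config: SimConfig) -> tuple[SegregantGenomes, SimTruth]:
    """Haploid segregants from a two-parent cross with repeated intercrossing.

    Parent A contributes allele 0 everywhere, parent B allele 1.  The F1
    hybrid is taken through one meiosis, then ``intercross_rounds`` rounds of
    (random pairing -> meiosis), shrinking parental blocks each round.
    Phenotype = qtl_effect x allele + sum(background effects x alleles) +
    Normal(0, segregant_noise_sd).
    """
    if config.n_segregants < 1:
        raise ValueError("at least one segregant must be requested")
    rng = config.rng("cross")
    cm_per_bp = 1.0 / config.map_density_bp_per_cM
    chroms = [f"chr{i + 1}" for i in range(len(config.chrom_lengths_bp))]
    positions = {
        c: np.arange(
            config.snp_spacing_bp, L + 1, config.snp_spacing_bp, dtype=np.int64
        )
        for c, L in zip(chroms, config.chrom_lengths_bp)
    }
    n = config.n_segregants

    genotypes: dict[str, np.ndarray] = {}
    for c, L in zip(chroms, config.chrom_lengths_bp):
        m = positions[c].size
        # F1 meiosis: parental haplotypes are constant 0 / constant 1
        gam = _meiosis_chrom(
            np.zeros((n, m), np.int8),
            np.ones((n, m), np.int8),
            positions[c],
            L,
            cm_per_bp,
            rng,
        )
        genotypes[c] = gam

    for _ in range(config.intercross_rounds):
        i1 = rng.integers(0, n, n)
        i2 = (i1 + rng.integers(1, n, n)) % n if n > 1 else i1
        for c, L in zip(chroms, config.chrom_lengths_bp):
            genotypes[c] = _meiosis_chrom(
                genotypes[c][i1],
                genotypes[c][i2],
                positions[c],
                L,
                cm_per_bp,
                rng,
            )

    pheno = rng.normal(0.0, config.segregant_noise_sd, n)
    truth = SimTruth()
    if config.qtl is not None:
        qc, qpos, qeff = config.qtl
        qi = int(np.argmin(np.abs(positions[qc] - qpos)))
        pheno = pheno + qeff * genotypes[qc][:, qi]
        truth.qtl = (qc, int(positions[qc][qi]), float(qeff))
    n_bg, bg_sd = config.background_effects
    bg_loci: list[tuple[str, int, float]] = []
    for _ in range(int(n_bg)):
        c = chroms[rng.integers(0, len(chroms))]
        bi = int(rng.integers(0, positions[c].size))
        eff = float(rng.normal(0.0, bg_sd))
        pheno = pheno + eff * genotypes[c][:, bi]
        bg_loci.append((c, int(positions[c][bi]), eff))
    truth.background_loci = bg_loci

    return SegregantGenomes(chroms, positions, genotypes, pheno), truth


def mean_block_length(genomes: SegregantGenomes) -> float:
    """Mean parental-block length (bp) over all segregants and chromosomes."""
    lengths: list[float] = []
    for c in genomes.chroms:
        geno = genomes.genotypes[c]
        pos = genomes.positions[c]
        span = float(pos[-1] - pos[0]) if pos.size > 1 else 0.0
        switches = (np.diff(geno, axis=1) != 0).sum(axis=1)
        lengths.extend(span / (switches + 1))
    return float(np.mean(lengths))


def gen_pool_counts(
    genomes: SegregantGenomes, config: SimConfig
) -> pd.DataFrame:
    """ON/OFF tail pools and Poisson-depth binomial read counts per SNP.

    ON pool = top ``pool_fraction`` of segregants by phenotype, OFF = bottom.
    Per SNP: depth ~ Poisson(mean_depth), parent-A read count ~
    Binomial(depth, pool parent-A frequency).
    """
    rng = config.rng("pools")
    n = genomes.n_segregants
    n_pool = int(round(config.pool_fraction * n))
    if n_pool < 2:
        raise ValueError(
            f"pool of {n_pool} segregants is too small (need >= 2); "
            "increase n_segregants or pool_fraction"
        )
    order = np.argsort(genomes.phenotypes, kind="stable")
    off_idx, on_idx = order[:n_pool], order[-n_pool:]

    frames = []
    for c in genomes.chroms:
        geno = genomes.genotypes[c]
        freq_a_on = (geno[on_idx] == 0).mean(axis=0)
        freq_a_off = (geno[off_idx] == 0).mean(axis=0)
        m = geno.shape[1]
        depth_on = rng.poisson(config.mean_depth, m)
        depth_off = rng.poisson(config.mean_depth, m)
        a_on = rng.binomial(depth_on, freq_a_on)
        a_off = rng.binomial(depth_off, freq_a_off)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": c,
                    "pos": genomes.positions[c],
                    "A_on": a_on,
                    "B_on": depth_on - a_on,
                    "A_off": a_off,
                    "B_off": depth_off - a_off,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# variance-partitioning populations
# ---------------------------------------------------------------------------


def gen_varpart_populations(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Three segregant populations emulating the hybrid designs.

    hybrid1 segregates the focal allele (+/- sqrt(v_gal3) genetic effect),
    hybrids 2 and 3 carry it fixed; background values are Normal(0,
    sqrt(v_bg)) in all three; each replicate adds Normal(0, epsilon) noise.
    """
    p = config.varpart
    rng = config.rng("varpart")
    effect = float(np.sqrt(p.v_gal3))
    bg_sd = float(np.sqrt(p.v_bg))
    rows = []
    for hybrid, fixed in (("hybrid1", None), ("hybrid2", "a"), ("hybrid3", "-a")):
        for i in range(p.n_segregants):
            if fixed is None:
                allele = "a" if rng.random() < 0.5 else "-a"
            else:
                allele = fixed
            value = (effect if allele == "a" else -effect) + rng.normal(0.0, bg_sd)
            if hybrid == "hybrid1" and i < p.n_outliers:
                value += p.outlier_shift
            reps = value + rng.normal(0.0, p.epsilon, p.n_reps)
            rows.append(
                {
                    "segregant_id": f"{hybrid}_s{i:03d}",
                    "hybrid_id": hybrid,
                    "allele": allele,
                    **{f"rep{j + 1}": reps[j] for j in range(p.n_reps)},
                }
            )
    table = pd.DataFrame(rows)
    truth = SimTruth(v_gal3=p.v_gal3, v_bg=p.v_bg, epsilon=p.epsilon)
    return table, truth


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------


def gen_growth_curves(
    config: SimConfig,
    lags: Optional[dict[str, float]] = None,
    condition: str = "glucose+galactose",
) -> tuple[pd.DataFrame, SimTruth]:
    """Two-phase growth curves with a diauxic plateau, sampled every 15 min.

    log2 OD rises at ``rate1`` until a quarter of saturation (first-sugar
    exhaustion), stays flat for the planted lag, then rises at ``rate2`` to
    saturation.  Additive Normal(0, od_noise_sd) noise on log2 OD.
    """
    g = config.growth
    rng = config.rng("growth")
    if lags is None:
        lags = {s.strain_id: g.lag_hours for s in config.strains}
    frames = []
    for strain_id, lag in lags.items():
        if lag < 0:
            raise ValueError("lag must be >= 0")
        l0 = np.log2(g.od_start)
        lsat = np.log2(g.od_sat)
        lceil = lsat - 2.0  # first phase ends at quarter saturation
        t1 = (lceil - l0) / g.rate1
        t2 = t1 + lag
        t3 = t2 + (lsat - lceil) / g.rate2
        t = np.arange(0.0, t3 + 2.0, g.sample_interval_h)
        log2od = np.where(
            t <= t1,
            l0 + g.rate1 * t,
            np.where(t <= t2, lceil, np.minimum(lceil + g.rate2 * (t - t2), lsat)),
        )
        if g.od_noise_sd > 0:
            log2od = log2od + rng.normal(0.0, g.od_noise_sd, t.size)
        frames.append(
            pd.DataFrame(
                {
                    "time_h": t,
                    "od600": 2.0**log2od,
                    "strain_id": strain_id,
                    "condition": condition,
                }
            )
        )
    truth = SimTruth(lag_hours={k: float(v) for k, v in lags.items()})
    return pd.concat(frames, ignore_index=True), truth


# ---------------------------------------------------------------------------
# variant matrices
# ---------------------------------------------------------------------------


def _random_cds(rng: np.random.Generator, length_bp: int) -> str:
    """Random CDS: ATG start, no internal stops, TAA stop."""
    n_codons = length_bp // 3
    codons = ["ATG"]
    sense = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in STOP_CODONS
    ]
    picks = rng.integers(0, len(sense), n_codons - 2)
    codons.extend(sense[i] for i in picks)
    codons.append("TAA")
    return "".join(codons)


def _is_synonymous(cds: str, pos1: int, alt: str) -> bool:
    ci = (pos1 - 1) // 3
    within = (pos1 - 1) % 3
    ref_codon = cds[ci * 3 : ci * 3 + 3]
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
    return str(Seq(ref_codon).translate()) == str(Seq(alt_codon).translate())


def gen_variant_data(config: SimConfig):
    """Strain x SNP allele matrix over a random locus, plus an outgroup CDS.

    Returns ``(VariantMatrix, outgroup_cds, SimTruth)``.  SNPs are planted in
    the promoter (positions -promoter_length..-1) and coding region;
    ``n_haplotypes`` distinct allele strings are assigned to strains; the
    outgroup is the reference CDS with independent substitutions at
    ``outgroup_divergence_rate`` per base.
    """
    from .popgen import VariantMatrix  # deferred: popgen imports nothing from here

    p = config.variants
    rng = config.rng("variants")
    cds = _random_cds(rng, p.cds_length_bp)

    # site positions: promoter (negative) and coding (avoid start/stop codons)
    prom_pos = rng.choice(
        np.arange(-p.promoter_length_bp, 0), size=p.n_promoter_snps, replace=False
    )
    cod_pos = rng.choice(
        np.arange(4, p.cds_length_bp - 3 + 1), size=p.n_coding_snps, replace=False
    )
    pos = np.sort(np.concatenate([prom_pos, cod_pos]))
    n_sites = pos.size

    ref = np.empty(n_sites, dtype="<U1")
    alt = np.empty(n_sites, dtype="<U1")
    for i, pp in enumerate(pos):
        if pp >= 1:
            ref[i] = cds[pp - 1]
        else:
            ref[i] = BASES[rng.integers(0, 4)]
        others = [b for b in BASES if b != ref[i]]
        alt[i] = others[rng.integers(0, 3)]

    # distinct haplotype patterns (rows over all sites); hap 0 = reference
    patterns: list[tuple[int, ...]] = [(0,) * n_sites]
    seen = {patterns[0]}
    while len(patterns) < p.n_haplotypes:
        k = int(rng.integers(1, max(2, n_sites // 2)))
        idx = rng.choice(n_sites, size=k, replace=False)
        pat = np.zeros(n_sites, dtype=int)
        pat[idx] = 1
        key = tuple(pat)
        if key not in seen:
            seen.add(key)
            patterns.append(key)

    assignment = np.concatenate(
        [
            np.arange(p.n_haplotypes),
            rng.integers(0, p.n_haplotypes, p.n_strains - p.n_haplotypes),
        ]
    )
    rng.shuffle(assignment)
    pat_arr = np.array(patterns)  # (n_hap, n_sites)
    is_alt = pat_arr[assignment]  # (n_strains, n_sites)
    alleles = np.where(is_alt == 1, alt[None, :], ref[None, :])
    strains = [f"strain{i + 1:02d}" for i in range(p.n_strains)]

    # outgroup: independent substitutions along the CDS
    out = np.array(list(cds))
    hit = rng.random(out.size) < p.outgroup_divergence_rate
    for i in np.flatnonzero(hit):
        others = [b for b in BASES if b != out[i]]
        out[i] = others[rng.integers(0, 3)]
    outgroup = "".join(out)

    coding_mask = pos >= 1
    labels = [
        "synonymous" if _is_synonymous(cds, int(pp), str(a)) else "nonsynonymous"
        for pp, a in zip(pos[coding_mask], alt[coding_mask])
    ]
    matrix = VariantMatrix(
        strains=strains,
        positions=pos,
        ref=ref,
        alt=alt,
        alleles=alleles,
        ref_cds=cds,
        outgroup_cds=outgroup,
    )
    truth = SimTruth(
        n_haplotypes=int(len({tuple(r) for r in is_alt})),
        n_haplotypes_coding=int(len({tuple(r) for r in is_alt[:, coding_mask]})),
        n_synonymous=labels.count("synonymous"),
        n_nonsynonymous=labels.count("nonsynonymous"),
        n_promoter_snps=int((~coding_mask).sum()),
        coding_labels=labels,
    )
    return matrix, outgroup, truth
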