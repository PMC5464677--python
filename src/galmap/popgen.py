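"""Haplotype counting, synonymous/nonsynonymous classification,
McDonald-Kreitman test and the cross-repetition permutation test.

Sites are addressed by ORF-relative position: negative positions are
promoter, positions >= 1 index into the coding sequence (1-based).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.stats import fisher_exact

__all__ = [
    "VariantMatrix",
    "MKCounts",
    "count_haplotypes",
    "classify_coding_snps",
    "divergence_labels",
    "mk_test",
    "mk_from_matrix",
    "gene_repetition_test",
]

MISSING = {"N", "", "-", "."}


@dataclass
class VariantMatrix:
    """Strains x SNP sites over a locus (promoter + coding region)."""

    strains: list[str]
    positions: np.ndarray  # ORF-relative; negative = promoter, >=1 = coding
    ref: np.ndarray  # reference allele per site
    alt: np.ndarray  # alternate allele per site
    alleles: np.ndarray  # (n_strains, n_sites) of single characters
    ref_cds: Optional[str] = None
    outgroup_cds: Optional[str] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.alleles = np.asarray(self.alleles)
        if self.alleles.shape != (len(self.strains), self.positions.size):
            raise ValueError("allele matrix shape does not match strains x sites")
        if self.ref_cds is not None:
            if len(self.ref_cds) % 3 != 0:
                raise ValueError("CDS length must be divisible by 3")
            coding = self.positions[self.positions >= 1]
            if coding.size and coding.max() > len(self.ref_cds):
                raise ValueError("coding position beyond CDS length")

    def region_mask(self, region: str) -> np.ndarray:
        if region == "promoter":
            return self.positions < 0
        if region == "coding":
            return self.positions >= 1
        if region == "all":
            return np.ones(self.positions.size, dtype=bool)
        raise ValueError(f"unknown region {region!r}")


@dataclass
class MKCounts:
    pn: int
    ps: int
    dn: int
    ds: int
    neutrality_index: Optional[float]
    p_value: float

    @property
    def table(self) -> list[list[int]]:
        return [[self.pn, self.ps], [self.dn, self.ds]]


def count_haplotypes(
    matrix: VariantMatrix, region: str = "all"
) -> tuple[int, dict[str, str], list[str]]:
    """Distinct allele strings over the region's sites.

    Strains with any missing in-region call are excluded and listed.
    Returns (count, strain -> haplotype string, excluded strains).
    """
    mask = matrix.region_mask(region)
    if not mask.any():
        raise ValueError(f"no sites in region {region!r}")
    sub = matrix.alleles[:, mask]
    assignment: dict[str, str] = {}
    excluded: list[str] = []
    for strain, row in zip(matrix.strains, sub):
        if any(a in MISSING for a in row):
            excluded.append(strain)
        else:
            assignment[strain] = "".join(row)
    return len(set(assignment.values())), assignment, excluded


def _substituted_codon(cds: str, pos1: int, alt: str) -> tuple[str, str]:
    ci = (pos1 - 1) // 3
    within = (pos1 - 1) % 3
    ref_codon = cds[ci * 3 : ci * 3 + 3]
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
    return ref_codon, alt_codon


def _classify_one(cds: str, pos1: int, ref: str, alt: str) -> str:
    if pos1 < 1 or pos1 > len(cds):
        raise ValueError(f"position {pos1} outside CDS of length {len(cds)}")
    if cds[pos1 - 1] != ref:
        raise ValueError(
            f"reference allele {ref!r} at position {pos1} does not match CDS "
            f"base {cds[pos1 - 1]!r}"
        )
    if alt == ref:
        raise ValueError(f"alternate equals reference ({ref!r}) at position {pos1}")
    ref_codon, alt_codon = _substituted_codon(cds, pos1, alt)
    same = str(Seq(ref_codon).translate()) == str(Seq(alt_codon).translate())
    return "synonymous" if same else "nonsynonymous"


def classify_coding_snps(matrix: VariantMatrix) -> pd.DataFrame:
    """Per-coding-site synonymous/nonsynonymous labels.

    Each SNP's alternate allele is substituted into its codon on the
    reference background independently (multi-SNP codons are not combined)
    and classified by translation under the standard nuclear code.
    """
    if matrix.ref_cds is None:
        raise ValueError("reference CDS required for classification")
    mask = matrix.region_mask("coding")
    rows = [
        {
            "position": int(p),
            "ref": str(r),
            "alt": str(a),
            "label": _classify_one(matrix.ref_cds, int(p), str(r), str(a)),
        }
        for p, r, a in zip(matrix.positions[mask], matrix.ref[mask], matrix.alt[mask])
    ]
    return pd.DataFrame(rows, columns=["position", "ref", "alt", "label"])


def divergence_labels(
    ref_cds: str,
    outgroup_cds: str,
    polymorphic_positions: Sequence[int] = (),
) -> pd.DataFrame:
    """Fixed differences versus the outgroup, classified syn/nonsyn.

    Sites polymorphic within the species are excluded from divergence, per
    the standard MK convention.  Each differing site is classified on the
    reference codon background independently.
    """
    if len(ref_cds) != len(outgroup_cds):
        raise ValueError("reference and outgroup CDS must be aligned (equal length)")
    poly = set(int(p) for p in polymorphic_positions)
    rows = []
    for i, (r, o) in enumerate(zip(ref_cds, outgroup_cds), start=1):
        if r == o or i in poly or o in MISSING:
            continue
        rows.append(
            {
                "position": i,
                "ref": r,
                "alt": o,
                "label": _classify_one(ref_cds, i, r, o),
            }
        )
    return pd.DataFrame(rows, columns=["position", "ref", "alt", "label"])


def mk_test(pn: int, ps: int, dn: int, ds: int) -> MKCounts:
    """McDonald-Kreitman 2x2 contrast with two-sided Fisher exact p.

    NI = (Pn/Ps) / (Dn/Ds); undefined (None) when Ps = 0 or Dn = 0.  No
    continuity correction is applied.
    """
    for name, v in (("pn", pn), ("ps", ps), ("dn", dn), ("ds", ds)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a nonnegative integer, got {v}")
    _, p = fisher_exact([[pn, ps], [dn, ds]], alternative="two-sided")
    ni = (pn / ps) / (dn / ds) if ps > 0 and dn > 0 and ds > 0 else None
    return MKCounts(int(pn), int(ps), int(dn), int(ds), ni, float(p))


def mk_from_matrix(matrix: VariantMatrix) -> MKCounts:
    """MK test from a variant matrix with reference and outgroup CDS."""
    if matrix.outgroup_cds is None:
        raise ValueError("outgroup CDS required for the MK test")
    labels = classify_coding_snps(matrix)
    div = divergence_labels(
        matrix.ref_cds,
        matrix.outgroup_cds,
        polymorphic_positions=labels["position"].tolist(),
    )
    return mk_test(
        pn=int((labels["label"] == "nonsynonymous").sum()),
        ps=int((labels["label"] == "synonymous").sum()),
        dn=int((div["label"] == "nonsynonymous").sum()),
        ds=int((div["label"] == "synonymous").sum()),
    )


def gene_repetition_test(
    k_crosses: int,
    n_genes: int,
    mode: str = "specific",
    n_perm: int = 1_000_000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Chance of one gene recurring as top locus in every cross.

    Each permutation draws one gene uniformly from ``n_genes`` per cross;
    success means (mode="specific") all draws equal a designated gene, or
    (mode="any") all draws are identical.  Returns the Monte-Carlo estimate
    and the closed forms (1/n_genes)^k and n_genes^(1-k).
    """
    if k_crosses < 1 or n_genes < 1:
        raise ValueError("k_crosses and n_genes must be >= 1")
    if mode not in ("specific", "any"):
        raise ValueError(f"mode must be 'specific' or 'any', got {mode!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    analytic = (
        (1.0 / n_genes) ** k_crosses
        if mode == "specific"
        else float(n_genes) ** (1 - k_crosses)
    )
    if analytic > 0 and n_perm < 1.0 / analytic:
        warnings.warn(
            f"n_perm={n_perm} below 1/p={1.0 / analytic:.3g}: Monte-Carlo "
            "estimate will be unstable",
            stacklevel=2,
        )
    hits = 0
    chunk = 1_000_000
    remaining = n_perm
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.integers(0, n_genes, size=(m, k_crosses))
        if mode == "specific":
            hits += int((draws == 0).all(axis=1).sum())
        else:
            hits += int((draws == draws[:, :1]).all(axis=1).sum())
        remaining -= m
    p_mc = hits / n_perm
    return {
        "p_monte_carlo": p_mc,
        "p_analytic": analytic,
        "hits": hits,
        "n_perm": n_perm,
        "mode": mode,
    }
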