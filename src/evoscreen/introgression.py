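"""Archaic-introgression haplotype analysis.

Given a modern-human genotype panel and a small archaic panel over a
genomic region, this module: enumerates *fixed differences* (every
non-missing modern call homozygous for one allele, every archaic call
homozygous for a different one), polarises them against ancestral
alleles, computes pairwise linkage disequilibrium r^2, builds the tag
haplotype block (partners with r^2 above a strict threshold), measures
its genomic span, and evaluates the probability that a haplotype of
that length survived unbroken since the common ancestor — the
incomplete-lineage-sorting null.  A small survival probability supports
gene flow over shared ancestral variation.

Survival model: recombination breakpoints fall as a Poisson process at
rate r per bp per generation for t generations (the combined modern +
archaic branch lengths since divergence), so the shared-haplotype
length around a focal site is Gamma-distributed with shape 2 and mean
L = 1/(r t).  The survival probability of an observed length m is the
upper tail 1 - GammaCDF(m; shape=2, rate=1/L), with closed form
``exp(-m/L) (1 + m/L)``.

Coordinates are 1-based inclusive; the span s..e has length e - s + 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .io import GenotypePanel, MISSING_ALLELE, VariantSite

__all__ = [
    "Polarity",
    "FixedDifferenceSNP",
    "HaplotypeBlock",
    "SurvivalProbabilityResult",
    "LdResult",
    "fixed_difference_scan",
    "polarize_ancestral",
    "ld_r2",
    "tag_haplotype_block",
    "auto_tag",
    "interval_length",
    "haplotype_survival_probability",
    "population_allele_frequency",
]

#: cM/Mb -> crossover probability per bp per generation
CM_PER_MB_TO_PER_BP = 1e-8


class Polarity(Enum):
    DERIVED_ON_MODERN = "derived_on_modern"
    DERIVED_ON_ARCHAIC = "derived_on_archaic"
    UNPOLARIZED = "unpolarized"


@dataclass
class FixedDifferenceSNP:
    """A site fixed for different alleles in the two panels."""

    chrom: str
    pos: int
    id: str
    modern_allele: str
    archaic_allele: str
    ancestral: Optional[str]
    polarity: Polarity = field(init=False)

    def __post_init__(self) -> None:
        if self.modern_allele == self.archaic_allele:
            raise ValueError("modern and archaic alleles must differ")
        if self.ancestral is None:
            self.polarity = Polarity.UNPOLARIZED
        elif self.ancestral == self.modern_allele:
            # the modern lineage retains the ancestral state, so the
            # archaic lineage carries the derived allele
            self.polarity = Polarity.DERIVED_ON_ARCHAIC
        elif self.ancestral == self.archaic_allele:
            self.polarity = Polarity.DERIVED_ON_MODERN
        else:
            self.polarity = Polarity.UNPOLARIZED


def _panel_fixed_allele(
    panel: GenotypePanel, site_i: int, max_missing: float
) -> Optional[str]:
    """The single allele every non-missing call is homozygous for, or
    None if the panel is polymorphic/heterozygous/too-missing here."""
    calls = panel.genotypes[:, site_i, :]
    missing_mask = (calls == MISSING_ALLELE).any(axis=1)
    frac_missing = missing_mask.mean() if len(missing_mask) else 1.0
    if frac_missing > max_missing:
        return None
    called = calls[~missing_mask]
    if called.size == 0:
        return None
    first = called[0, 0]
    if not (called == first).all():
        return None
    return panel.sites[site_i].alleles[first]


def _observed_alleles(panel: GenotypePanel, site_i: int) -> set[str]:
    calls = panel.genotypes[:, site_i, :]
    idx = np.unique(calls[calls != MISSING_ALLELE])
    return {panel.sites[site_i].alleles[int(i)] for i in idx}


def fixed_difference_scan(
    modern: GenotypePanel,
    archaic: GenotypePanel,
    region: tuple[str, int, int],
    max_missing: float = 0.0,
) -> list[FixedDifferenceSNP]:
    """Sites in ``region`` fixed for different alleles in the two panels.

    A site qualifies iff it lies within the region, is biallelic across
    the union of the two panels' called alleles, every non-missing
    modern genotype is homozygous for one allele X, every non-missing
    archaic genotype homozygous for a different allele Y, and the
    missing-genotype fraction is <= ``max_missing`` in each panel
    (default 0: fixity is absolute).  Sites absent from either panel
    cannot be verified and are skipped.  An empty result is not an
    error.
    """
    chrom, start, end = region
    if start > end:
        raise ValueError(f"region start {start} > end {end}")
    out: list[FixedDifferenceSNP] = []
    archaic_index = {(s.chrom, s.pos): i for i, s in enumerate(archaic.sites)}
    for i, site in enumerate(modern.sites):
        if site.chrom != chrom or not (start <= site.pos <= end):
            continue
        j = archaic_index.get((site.chrom, site.pos))
        if j is None:
            continue
        union = _observed_alleles(modern, i) | _observed_alleles(archaic, j)
        if len(union) != 2:
            continue
        allele_m = _panel_fixed_allele(modern, i, max_missing)
        allele_a = _panel_fixed_allele(archaic, j, max_missing)
        if allele_m is None or allele_a is None or allele_m == allele_a:
            continue
        ancestral = site.ancestral or archaic.sites[j].ancestral
        out.append(
            FixedDifferenceSNP(
                chrom=site.chrom,
                pos=site.pos,
                id=site.id,
                modern_allele=allele_m,
                archaic_allele=allele_a,
                ancestral=ancestral,
            )
        )
    return out


def polarize_ancestral(
    snps: Sequence[FixedDifferenceSNP],
) -> tuple[int, int, int]:
    """Counts (derived on archaic, derived on modern, unpolarized).

    "Derived on archaic" means the modern panel carries the ancestral
    allele; the three counts sum to ``len(snps)``.
    """
    n_arc = sum(1 for s in snps if s.polarity is Polarity.DERIVED_ON_ARCHAIC)
    n_mod = sum(1 for s in snps if s.polarity is Polarity.DERIVED_ON_MODERN)
    n_unp = sum(1 for s in snps if s.polarity is Polarity.UNPOLARIZED)
    return n_arc, n_mod, n_unp


# ---------------------------------------------------------------------------
# linkage disequilibrium


@dataclass
class LdResult:
    r2: float
    method: str  # "haplotype" or "composite"
    n: int  # haplotypes (phased) or samples (composite)

    def __float__(self) -> float:
        return self.r2


def _biallelic_presence(panel: GenotypePanel, site_i: int) -> np.ndarray:
    """Per-haplotype 0/1 indicator of the non-reference-most allele,
    NaN where missing; requires the site biallelic among called
    alleles."""
    calls = panel.genotypes[:, site_i, :].astype(float)
    called = calls[calls != MISSING_ALLELE]
    alleles = np.unique(called)
    if len(alleles) > 2:
        raise ValueError(
            f"site {panel.sites[site_i].chrom}:{panel.sites[site_i].pos} "
            "is not biallelic in this panel"
        )
    hi = alleles.max() if len(alleles) else 0
    out = np.where(calls == MISSING_ALLELE, np.nan, (calls == hi).astype(float))
    return out


def ld_r2(
    panel: GenotypePanel,
    site_a: int,
    site_b: int,
    force_composite: bool = False,
) -> Optional[LdResult]:
    """Linkage disequilibrium r^2 between two biallelic sites.

    Fully phased panels use haplotype r^2 = D^2 / (pA qA pB qB) over
    haplotypes with both alleles called.  Panels with any unphased call
    (or ``force_composite``) fall back to composite LD — the squared
    Pearson correlation of genotype dosages — flagged in
    ``LdResult.method``.  A site monomorphic among the usable calls
    returns None (zero variance).
    """
    xa = _biallelic_presence(panel, site_a)
    xb = _biallelic_presence(panel, site_b)
    het_ok = panel.phased[:, site_a].all() and panel.phased[:, site_b].all()
    use_haplotypes = het_ok and not force_composite
    if use_haplotypes:
        ha, hb = xa.ravel(), xb.ravel()
        ok = ~np.isnan(ha) & ~np.isnan(hb)
        ha, hb = ha[ok], hb[ok]
        n = len(ha)
        if n == 0 or ha.std() == 0 or hb.std() == 0:
            return None
        pa, pb = ha.mean(), hb.mean()
        pab = (ha * hb).mean()
        d = pab - pa * pb
        r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
        return LdResult(r2=float(r2), method="haplotype", n=n)
    da, db = np.nansum(xa, axis=1), np.nansum(xb, axis=1)
    ok = ~np.isnan(xa).any(axis=1) & ~np.isnan(xb).any(axis=1)
    da, db = da[ok], db[ok]
    n = len(da)
    if n == 0 or da.std() == 0 or db.std() == 0:
        return None
    r = np.corrcoef(da, db)[0, 1]
    return LdResult(r2=float(r * r), method="composite", n=n)


@dataclass
class HaplotypeBlock:
    """Tag SNP plus its r^2-linked partners and the genomic span."""

    tag: FixedDifferenceSNP
    members: list[FixedDifferenceSNP]
    chrom: str
    start: int
    end: int
    length_bp: int
    r2_threshold: float


def tag_haplotype_block(
    snps: Sequence[FixedDifferenceSNP],
    panel: GenotypePanel,
    tag: FixedDifferenceSNP,
    r2_threshold: float = 0.8,
) -> HaplotypeBlock:
    """Block of SNPs inherited together with the tag (r^2 strictly
    above the threshold) in ``panel``; the interval spans the extreme
    member positions, measured 1-based inclusive."""
    if tag not in snps:
        raise ValueError("tag SNP must be one of the scanned SNPs")
    tag_i = panel.site_index(tag.chrom, tag.pos)
    probe = ld_r2(panel, tag_i, tag_i)
    if probe is None:
        raise ValueError(f"tag SNP {tag.chrom}:{tag.pos} is monomorphic in the panel")
    members = [tag]
    for snp in snps:
        if snp is tag:
            continue
        res = ld_r2(panel, tag_i, panel.site_index(snp.chrom, snp.pos))
        if res is not None and res.r2 > r2_threshold:
            members.append(snp)
    members.sort(key=lambda s: s.pos)
    start, end = members[0].pos, members[-1].pos
    return HaplotypeBlock(
        tag=tag,
        members=members,
        chrom=tag.chrom,
        start=start,
        end=end,
        length_bp=interval_length(tag.chrom, start, end),
        r2_threshold=r2_threshold,
    )


def auto_tag(
    snps: Sequence[FixedDifferenceSNP],
    panel: GenotypePanel,
    r2_threshold: float = 0.8,
) -> FixedDifferenceSNP:
    """The SNP with the most r^2-linked partners, ties broken by lowest
    position — for when no tag SNP is supplied."""
    best: Optional[tuple[int, int, FixedDifferenceSNP]] = None
    for snp in snps:
        i = panel.site_index(snp.chrom, snp.pos)
        if ld_r2(panel, i, i) is None:
            continue
        n_partners = 0
        for other in snps:
            if other is snp:
                continue
            res = ld_r2(panel, i, panel.site_index(other.chrom, other.pos))
            if res is not None and res.r2 > r2_threshold:
                n_partners += 1
        key = (-n_partners, snp.pos)
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], snp)
    if best is None:
        raise ValueError("no polymorphic SNP available as tag")
    return best[2]


def interval_length(chrom: str, start: int, end: int) -> int:
    """Length in bp of a 1-based inclusive interval: end - start + 1."""
    if start > end:
        raise ValueError(f"{chrom}: interval start {start} > end {end}")
    return end - start + 1


# ---------------------------------------------------------------------------
# survival probability


@dataclass
class SurvivalProbabilityResult:
    m_bp: float
    rate_per_bp_per_gen: float
    t_generations: float
    expected_length_bp: float  # L = 1/(r t)
    p: float


def haplotype_survival_probability(
    m_bp: float, rate_cm_per_mb: float, t_generations: float
) -> SurvivalProbabilityResult:
    """Probability that an unbroken shared haplotype of length ``m_bp``
    survives since the common ancestor, under incomplete lineage
    sorting alone.

    ``rate_cm_per_mb`` is the local recombination rate in cM/Mb,
    converted as r = rate x 1e-8 crossovers per bp per generation;
    ``t_generations`` is the combined length of the modern and archaic
    branches since divergence.  p = 1 - GammaCDF(m; shape=2, rate=1/L)
    = exp(-m/L) (1 + m/L) with L = 1/(r t).
    """
    if m_bp < 0:
        raise ValueError("haplotype length must be non-negative")
    if rate_cm_per_mb <= 0 or t_generations <= 0:
        raise ValueError("recombination rate and branch length must be positive")
    r = rate_cm_per_mb * CM_PER_MB_TO_PER_BP
    expected_length = 1.0 / (r * t_generations)
    x = m_bp / expected_length
    p = math.exp(-x) * (1.0 + x)
    return SurvivalProbabilityResult(
        m_bp=m_bp,
        rate_per_bp_per_gen=r,
        t_generations=t_generations,
        expected_length_bp=expected_length,
        p=p,
    )


# ---------------------------------------------------------------------------
# population frequencies


def population_allele_frequency(
    panel: GenotypePanel, chrom: str, pos: int, allele: str, population: str
) -> Optional[float]:
    """Frequency of ``allele`` among the non-missing diploid genotypes
    of one population: allele count / (2 x fully called samples).
    Returns None when no sample of that population is called."""
    site_i = panel.site_index(chrom, pos)
    site = panel.sites[site_i]
    if allele not in site.alleles:
        return 0.0
    allele_idx = site.alleles.index(allele)
    rows = panel.samples_of(population)
    calls = panel.genotypes[rows, site_i, :]
    complete = ~(calls == MISSING_ALLELE).any(axis=1)
    called = calls[complete]
    if called.size == 0:
        return None
    return float((called == allele_idx).sum() / called.size)
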