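"""Pairwise dN/dS screen: orthology, codon alignments, NG86 estimation,
genome-pair filtering, clade contrasts and FDR control.

The estimator is Nei–Gojobori (1986) counting: fractional synonymous and
nonsynonymous *sites* per codon, substitution *differences* averaged
uniformly over all mutational orderings between codons that differ at
more than one position (orderings passing through stop codons excluded),
and a Jukes–Cantor multiple-hit correction
``d = -(3/4) ln(1 - (4/3) p)`` applied to each proportion.

Site convention: at each codon position the synonymous fraction is the
number of the 3 possible single-nucleotide changes that preserve the
amino acid, divided by 3; changes creating a stop codon never count as
synonymous but stay in the denominator of 3.  Hence S + N = 3 per codon
exactly, and S + N = 3 x codons_compared per alignment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SequenceRecord

__all__ = [
    "OrthologPair",
    "CodonAlignment",
    "DnDsEstimate",
    "GenomePairSummary",
    "reciprocal_best_hits",
    "align_proteins",
    "project_codon_alignment",
    "ng86_site_counts",
    "pathway_difference_counts",
    "estimate_dnds",
    "jukes_cantor",
    "summarize_genome_pair",
    "clade_contrast",
    "benjamini_hochberg",
    "mean_identity",
    "SkipColumn",
]

BASES = "ACGT"
GAP_CODON = "---"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: inclusive median-dS acceptance window for a genome pair
DS_WINDOW = (0.27, 0.47)


class SkipColumn(Exception):
    """Signals a codon column the caller must exclude (gap/stop/ambiguity)."""


def _code(code_id: int = 1):
    return unambiguous_dna_by_id[code_id]


@lru_cache(maxsize=None)
def _codon_tables(code_id: int = 1) -> tuple[dict[str, str], frozenset[str]]:
    table = _code(code_id)
    aa = dict(table.forward_table)
    stops = frozenset(table.stop_codons)
    return aa, stops


def translate_codon(codon: str, code_id: int = 1) -> str:
    """Amino acid for a sense codon, '*' for a stop."""
    aa, stops = _codon_tables(code_id)
    if codon in stops:
        return "*"
    return aa[codon]


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str, code_id: int = 1) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) sites of one sense codon.

    Raises :class:`SkipColumn` for gapped, ambiguous or stop codons so
    the caller can exclude the column from both site and difference
    counts.
    """
    aa_map, stops = _codon_tables(code_id)
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise SkipColumn(f"gapped or ambiguous codon {codon!r}")
    if codon in stops:
        raise SkipColumn(f"stop codon {codon!r}")
    aa = aa_map[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in stops and aa_map[mutant] == aa:
                n_syn += 1
        syn += n_syn / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def pathway_difference_counts(
    codon_a: str, codon_b: str, code_id: int = 1
) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences.

    Codon pairs differing at k positions are compared along all k!
    single-step mutational orderings; each step is classified by whether
    it changes the encoded amino acid.  Orderings that pass through a
    stop codon are excluded; if every ordering does, the average falls
    back to all orderings (a step into or out of a stop counts as
    nonsynonymous).
    """
    _, stops = _codon_tables(code_id)
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float, bool]:
        sd = nd = 0.0
        current = codon_a
        stop_free = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in stops and nxt != codon_b:
                stop_free = False
            aa_from = translate_codon(current, code_id)
            aa_to = translate_codon(nxt, code_id)
            if aa_from == aa_to and aa_from != "*":
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return sd, nd, stop_free

    results = [walk(order) for order in permutations(diff_positions)]
    valid = [(s, n) for s, n, ok in results if ok]
    if not valid:
        valid = [(s, n) for s, n, _ in results]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 distance ``-(3/4) ln(1 - (4/3) p)``; None when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# alignment machinery


@dataclass
class OrthologPair:
    """One ortholog: protein + CDS for species A and B.

    A terminal stop codon on either CDS is trimmed at construction; the
    CDS must then be exactly 3x its protein length.
    """

    gene_id: str
    species_a: str
    species_b: str
    protein_a: SequenceRecord
    protein_b: SequenceRecord
    cds_a: SequenceRecord
    cds_b: SequenceRecord

    def __post_init__(self) -> None:
        for prot, cds in ((self.protein_a, self.cds_a), (self.protein_b, self.cds_b)):
            cds.residues = _trim_terminal_stop(prot.residues, cds.residues)
            if len(cds.residues) != 3 * len(prot.residues):
                raise ValueError(
                    f"{self.gene_id}/{cds.id}: CDS length {len(cds.residues)} "
                    f"is not 3x protein length {len(prot.residues)}"
                )


def _trim_terminal_stop(protein: str, cds: str, code_id: int = 1) -> str:
    _, stops = _codon_tables(code_id)
    if len(cds) == 3 * (len(protein) + 1) and cds[-3:] in stops:
        return cds[:-3]
    return cds


@dataclass
class CodonAlignment:
    """Rows of aligned codon columns; gap codon is ``---``."""

    ids: list[str]
    rows: list[list[str]]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("codon alignment rows have unequal column counts")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return "".join(c for c in self.rows[i] if c != GAP_CODON)


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty protein sequence")
    bad = sorted(set(seq) - set(AMINO_ACIDS))
    if bad:
        raise ValueError(f"{name}: non-amino-acid characters {bad}")


def align_proteins(
    prot_a: SequenceRecord, prot_b: SequenceRecord
) -> tuple[str, str]:
    """Global (Needleman–Wunsch, BLOSUM62, affine gaps) protein alignment.

    Returns two gapped rows of equal length whose ungapped forms
    reproduce the inputs.  Ties between co-optimal alignments resolve to
    the aligner's first traceback, which is deterministic.
    """
    _check_protein(prot_a.residues, prot_a.id)
    _check_protein(prot_b.residues, prot_b.id)
    aligner = _protein_aligner()
    alignment = aligner.align(prot_a.residues, prot_b.residues)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    return row_a, row_b


def reciprocal_best_hits(
    proteome_a: Sequence[SequenceRecord],
    proteome_b: Sequence[SequenceRecord],
) -> list[tuple[str, str]]:
    """Reciprocal best hits under local BLOSUM62 alignment score.

    (a, b) is returned iff b is a's best-scoring match in B and a is b's
    best in A; score ties break to the lexicographically smallest id.
    An empty proteome yields an empty list.
    """
    if not proteome_a or not proteome_b:
        return []
    aligner = _protein_aligner()
    aligner.mode = "local"
    ids_a = [r.id for r in proteome_a]
    ids_b = [r.id for r in proteome_b]
    scores = np.empty((len(proteome_a), len(proteome_b)))
    for i, ra in enumerate(proteome_a):
        for j, rb in enumerate(proteome_b):
            scores[i, j] = aligner.score(ra.residues, rb.residues)

    def best(row_scores: np.ndarray, ids: list[str]) -> int:
        top = row_scores.max()
        candidates = [k for k in range(len(ids)) if row_scores[k] == top]
        return min(candidates, key=lambda k: ids[k])

    best_in_b = [best(scores[i, :], ids_b) for i in range(len(proteome_a))]
    best_in_a = [best(scores[:, j], ids_a) for j in range(len(proteome_b))]
    pairs = [
        (ids_a[i], ids_b[j])
        for i, j in enumerate(best_in_b)
        if best_in_a[j] == i
    ]
    return sorted(pairs)


def project_codon_alignment(
    protein_alignment: tuple[str, str],
    cds_a: SequenceRecord,
    cds_b: SequenceRecord,
    code_id: int = 1,
) -> CodonAlignment:
    """Back-translate a protein alignment onto the two CDSs.

    Every protein gap ``-`` becomes the codon gap ``---``; the column
    count equals the protein alignment length.  Each CDS must translate
    (standard code unless overridden) to its ungapped protein row; a
    terminal stop is trimmed.
    """
    rows = []
    ids = [cds_a.id, cds_b.id]
    for prot_row, cds in zip(protein_alignment, (cds_a, cds_b)):
        ungapped = prot_row.replace("-", "")
        cds_seq = _trim_terminal_stop(ungapped, cds.residues, code_id)
        if len(cds_seq) != 3 * len(ungapped):
            raise ValueError(
                f"{cds.id}: CDS length {len(cds_seq)} does not match "
                f"protein length {len(ungapped)} (frameshift?)"
            )
        codons = [cds_seq[i : i + 3] for i in range(0, len(cds_seq), 3)]
        for k, (aa, codon) in enumerate(zip(ungapped, codons)):
            if translate_codon(codon, code_id) != aa:
                raise ValueError(
                    f"{cds.id}: codon {k + 1} ({codon}) translates to "
                    f"{translate_codon(codon, code_id)}, protein has {aa}"
                )
        it = iter(codons)
        rows.append([GAP_CODON if aa == "-" else next(it) for aa in prot_row])
    return CodonAlignment(ids=ids, rows=rows)


# ---------------------------------------------------------------------------
# estimation


@dataclass
class DnDsEstimate:
    """NG86 counting estimate for one codon-aligned ortholog pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: Optional[float]
    pN: Optional[float]
    dS: Optional[float]
    dN: Optional[float]
    omega: Optional[float]
    codons_compared: int
    ds_inestimable: bool = False


def estimate_dnds(alignment: CodonAlignment, code_id: int = 1) -> DnDsEstimate:
    """NG86 pairwise dN/dS with Jukes–Cantor correction.

    Columns with a gap, ambiguity code or stop codon in either row are
    excluded from both site and difference counts.  Site totals are
    averaged over the two sequences.  ``omega`` is None (undefined) when
    dS is zero or inestimable (pS >= 3/4, or no synonymous sites).
    """
    if len(alignment.rows) != 2:
        raise ValueError("estimate_dnds expects a pairwise codon alignment")
    row_a, row_b = alignment.rows
    s_a = s_b = sd = nd = 0.0
    codons = 0
    for ca, cb in zip(row_a, row_b):
        try:
            sa, _ = ng86_site_counts(ca, code_id)
            sb, _ = ng86_site_counts(cb, code_id)
        except SkipColumn:
            continue
        step_sd, step_nd = pathway_difference_counts(ca, cb, code_id)
        s_a += sa
        s_b += sb
        sd += step_sd
        nd += step_nd
        codons += 1
    if codons == 0:
        raise ValueError("no comparable codon columns")
    S = (s_a + s_b) / 2.0
    N = 3.0 * codons - S

    pS = sd / S if S > 0 else None
    pN = nd / N if N > 0 else None
    dS = jukes_cantor(pS) if pS is not None else None
    dN = jukes_cantor(pN) if pN is not None else None
    ds_inestimable = pS is None or dS is None
    omega: Optional[float] = None
    if dS is not None and dS > 0 and dN is not None:
        omega = dN / dS
    return DnDsEstimate(
        S=S,
        N=N,
        Sd=sd,
        Nd=nd,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        omega=omega,
        codons_compared=codons,
        ds_inestimable=ds_inestimable,
    )


def estimate_pair(pair: OrthologPair, code_id: int = 1) -> DnDsEstimate:
    """Align the proteins of an ortholog pair, project to codons, estimate."""
    prot_aln = align_proteins(pair.protein_a, pair.protein_b)
    codon_aln = project_codon_alignment(prot_aln, pair.cds_a, pair.cds_b, code_id)
    return estimate_dnds(codon_aln, code_id)


# ---------------------------------------------------------------------------
# genome-pair filtering and clade contrast


@dataclass
class GenomePairSummary:
    """Per-gene estimates for one genome pair plus the median-dS filter."""

    clade: str
    species_pair: tuple[str, str]
    estimates: dict[str, DnDsEstimate]
    median_ds: float = field(init=False)
    accepted: bool = field(init=False)

    def __post_init__(self) -> None:
        defined = [e.dS for e in self.estimates.values() if e.dS is not None]
        if not defined:
            raise ValueError(
                f"{self.species_pair}: no gene with a defined dS; cannot filter"
            )
        self.median_ds = float(np.median(defined))
        lo, hi = DS_WINDOW
        self.accepted = lo <= self.median_ds <= hi


def summarize_genome_pair(
    estimates: dict[str, DnDsEstimate], clade: str, species_pair: tuple[str, str]
) -> GenomePairSummary:
    """Median dS over genes with a defined dS; accepted iff it falls in
    the inclusive window [0.27, 0.47]."""
    return GenomePairSummary(clade=clade, species_pair=species_pair, estimates=estimates)


def clade_contrast(
    samples_by_clade: dict[str, Sequence[float]],
    contrast: tuple[str, str],
    method: str = "welch",
) -> Optional[float]:
    """Two-clade test on per-pair omega samples.

    ``welch`` (default) is a two-sided Welch t test; ``mannwhitney`` a
    two-sided Mann–Whitney U.  Returns None when a clade has fewer than
    two defined samples.  If both clades are constant the test is
    degenerate: p = 1.0 when the constants agree (no signal), else 0.0.
    """
    x = np.asarray([v for v in samples_by_clade[contrast[0]] if v is not None], float)
    y = np.asarray([v for v in samples_by_clade[contrast[1]] if v is not None], float)
    if len(x) < 2 or len(y) < 2:
        return None
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return 1.0 if x[0] == y[0] else 0.0
    if method == "welch":
        return float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    if method == "mannwhitney":
        return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    raise ValueError(f"unknown contrast method {method!r}")


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, clipped to 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.empty(0)
    return multipletests(p, method="fdr_bh")[1]


def mean_identity(alignments: Sequence[tuple[str, str]]) -> Optional[float]:
    """Mean percent identity over pairwise alignments.

    Identity per alignment = matches / gap-free columns x 100;
    alignments with zero gap-free columns are excluded with a warning.
    Returns None when nothing is left.
    """
    values = []
    for row_a, row_b in alignments:
        pairs = [(a, b) for a, b in zip(row_a, row_b) if a != "-" and b != "-"]
        if not pairs:
            warnings.warn("alignment with zero gap-free columns excluded", stacklevel=2)
            continue
        matches = sum(1 for a, b in pairs if a == b)
        values.append(100.0 * matches / len(pairs))
    if not values:
        return None
    return float(np.mean(values))


#: strict threshold below which a gene is flagged LOW_IDENTITY
LOW_IDENTITY_PERCENT = 60.0


def low_identity_flag(mean_percent: Optional[float]) -> bool:
    return mean_percent is not None and mean_percent < LOW_IDENTITY_PERCENT
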