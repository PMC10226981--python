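"""Readers and writers for the formats the pipeline touches.

Strict dialects, documented here once:

* FASTA — wrapped at 60 columns on write; residues upper-cased on read.
* VCF 4.2 — GT genotypes, optional ``AA`` INFO tag for the ancestral
  allele; ``|`` marks a phased call, ``/`` unphased, ``./.`` missing.
* Trait tables — tab-separated, one species per row, PanTHERIA dialect:
  the sentinel ``-999`` (also ``-999.00``) means *missing* and is mapped
  to NaN on read, never to a magic number downstream.
* Newick — via dendropy; absent branch lengths stay ``None``, never 0.

Genomic coordinates are 1-based inclusive everywhere (the VCF
convention); any half-open arithmetic is internal and never serialized.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

__all__ = [
    "SequenceRecord",
    "TraitTable",
    "VariantSite",
    "GenotypePanel",
    "read_fasta",
    "write_fasta",
    "read_trait_table",
    "read_newick",
    "write_newick",
    "read_vcf_panel",
    "write_vcf_panel",
]

#: missing-genotype allele index
MISSING_ALLELE = -1

#: PanTHERIA missing-data sentinel, honoured on read only.
PANTHERIA_MISSING = -999.0


# ---------------------------------------------------------------------------
# sequences


@dataclass
class SequenceRecord:
    """A named sequence (amino acids or nucleotides, upper-cased)."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved; residues are upper-cased.  An empty file yields
    an empty list with a warning; text before the first header is a
    parse error naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: malformed FASTA header at line {lineno}: "
                    f"expected '>', got {line[:30]!r}"
                )
            break
        else:
            warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
            return []
    records = [
        SequenceRecord(id=rec.id, description=rec.description, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping residues at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# trait tables


@dataclass
class TraitTable:
    """Species x trait grid with explicit missing values (NaN).

    Numeric columns are floats; anything non-numeric is kept as a
    categorical code (string).  Missing is always NaN, never 0.
    """

    data: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species rows: {dupes}")


def read_trait_table(path: str | Path) -> TraitTable:
    """Read a tab-separated species x trait table (PanTHERIA dialect).

    The first column holds species names; the header row holds trait
    names.  Cells equal to the PanTHERIA sentinel ``-999`` (any numeric
    spelling) become NaN.  A row whose length disagrees with the header
    is an error naming the row.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    rows = [r for r in rows if r and any(cell.strip() for cell in r)]
    if not rows:
        raise ValueError(f"{path}: empty trait table")
    header = rows[0]
    n_cols = len(header)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != n_cols:
            raise ValueError(
                f"{path}: row {i} has {len(row)} fields, header has {n_cols}"
            )
    frame = pd.DataFrame(
        [row[1:] for row in rows[1:]],
        index=[row[0] for row in rows[1:]],
        columns=header[1:],
    )
    frame.index.name = header[0]

    def _coerce(col: pd.Series) -> pd.Series:
        numeric = pd.to_numeric(col.replace("", np.nan), errors="coerce")
        if numeric.notna().sum() == col.replace("", np.nan).notna().sum():
            numeric[numeric == PANTHERIA_MISSING] = np.nan
            return numeric
        out = col.replace("", np.nan)
        out[out.isin(["-999", "-999.0", "-999.00"])] = np.nan
        return out

    frame = frame.apply(_coerce)
    return TraitTable(frame)


# ---------------------------------------------------------------------------
# trees


def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a single Newick tree; absent branch lengths stay ``None``."""
    try:
        return dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several tokenizer errors
        raise ValueError(f"{path}: malformed Newick: {exc}") from exc


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


# ---------------------------------------------------------------------------
# genotype panels


@dataclass
class VariantSite:
    """One VCF site.  ``pos`` is 1-based; ``ancestral`` is None if unknown."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    ancestral: Optional[str] = None
    id: str = "."

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts


@dataclass
class GenotypePanel:
    """Samples x sites diploid genotypes with population labels.

    ``genotypes`` is (n_samples, n_sites, 2) of allele indexes into
    ``VariantSite.alleles``; -1 means a missing allele call.  ``phased``
    is (n_samples, n_sites) bool.
    """

    samples: list[str]
    populations: dict[str, str]
    sites: list[VariantSite]
    genotypes: np.ndarray
    phased: np.ndarray
    _site_index: dict[tuple[str, int], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n_samples, n_sites = len(self.samples), len(self.sites)
        if self.genotypes.shape != (n_samples, n_sites, 2):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} != {(n_samples, n_sites, 2)}"
            )
        if self.phased.shape != (n_samples, n_sites):
            raise ValueError("phased flag array has wrong shape")
        last: dict[str, int] = {}
        for site in self.sites:
            if site.chrom in last and site.pos <= last[site.chrom]:
                raise ValueError(
                    f"positions not strictly increasing on {site.chrom} at {site.pos}"
                )
            last[site.chrom] = site.pos
        for site_i, site in enumerate(self.sites):
            called = self.genotypes[:, site_i, :]
            if called.max(initial=-1) >= len(site.alleles):
                raise ValueError(
                    f"genotype at {site.chrom}:{site.pos} indexes an undeclared allele"
                )
        self._site_index = {(s.chrom, s.pos): i for i, s in enumerate(self.sites)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self, chrom: str, pos: int) -> int:
        return self._site_index[(chrom, pos)]

    def samples_of(self, population: str) -> list[int]:
        idx = [
            i for i, s in enumerate(self.samples) if self.populations.get(s) == population
        ]
        if not idx:
            raise ValueError(f"unknown population label: {population!r}")
        return idx

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypePanel":
        idx = [self.samples.index(s) for s in sample_ids]
        return GenotypePanel(
            samples=list(sample_ids),
            populations={s: self.populations[s] for s in sample_ids if s in self.populations},
            sites=self.sites,
            genotypes=self.genotypes[idx, :, :],
            phased=self.phased[idx, :],
        )

    def subset_population(self, population: str) -> "GenotypePanel":
        return self.subset_samples([self.samples[i] for i in self.samples_of(population)])

    def subset_region(self, chrom: str, start: int, end: int) -> "GenotypePanel":
        """Panel restricted to sites in [start, end] (1-based inclusive)."""
        keep = [
            i
            for i, s in enumerate(self.sites)
            if s.chrom == chrom and start <= s.pos <= end
        ]
        return GenotypePanel(
            samples=self.samples,
            populations=self.populations,
            sites=[self.sites[i] for i in keep],
            genotypes=self.genotypes[:, keep, :],
            phased=self.phased[:, keep],
        )


def read_vcf_panel(
    path: str | Path, sample_to_population: Optional[dict[str, str]] = None
) -> GenotypePanel:
    """Read a VCF 4.x file with GT calls into a :class:`GenotypePanel`.

    The ancestral allele is taken from the ``AA`` INFO tag when present.
    Samples named in ``sample_to_population`` but absent from the file
    are an error; file samples absent from the map get no label.
    Multiallelic sites are kept with all their alternate alleles.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sample_to_population = dict(sample_to_population or {})
    absent = sorted(set(sample_to_population) - set(samples))
    if absent:
        raise ValueError(f"samples in population map absent from {path}: {absent}")

    sites: list[VariantSite] = []
    geno_rows: list[np.ndarray] = []
    phase_rows: list[np.ndarray] = []
    for var in vcf:
        aa = var.INFO.get("AA")
        sites.append(
            VariantSite(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alts=tuple(var.ALT),
                ancestral=str(aa).upper() if aa is not None else None,
                id=var.ID or ".",
            )
        )
        calls = np.full((len(samples), 2), MISSING_ALLELE, dtype=np.int16)
        phase = np.zeros(len(samples), dtype=bool)
        for si, gt in enumerate(var.genotypes):
            a, b, is_phased = gt[0], gt[1], bool(gt[2])
            calls[si, 0] = a if a >= 0 else MISSING_ALLELE
            calls[si, 1] = b if b >= 0 else MISSING_ALLELE
            phase[si] = is_phased
        geno_rows.append(calls)
        phase_rows.append(phase)

    n_sites = len(sites)
    genotypes = (
        np.stack(geno_rows, axis=1)
        if n_sites
        else np.empty((len(samples), 0, 2), dtype=np.int16)
    )
    phased = (
        np.stack(phase_rows, axis=1)
        if n_sites
        else np.empty((len(samples), 0), dtype=bool)
    )
    return GenotypePanel(
        samples=samples,
        populations=sample_to_population,
        sites=sites,
        genotypes=genotypes,
        phased=phased,
    )


def write_vcf_panel(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel as uncompressed VCF 4.2 with GT and AA tags."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=evoscreen\n")
        fh.write(
            '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in panel.sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + panel.samples) + "\n")
        for j, site in enumerate(panel.sites):
            info = f"AA={site.ancestral}" if site.ancestral is not None else "."
            fields = [
                site.chrom,
                str(site.pos),
                site.id,
                site.ref,
                ",".join(site.alts) if site.alts else ".",
                ".",
                "PASS",
                info,
                "GT",
            ]
            for i in range(panel.n_samples):
                a, b = panel.genotypes[i, j]
                sep = "|" if panel.phased[i, j] else "/"
                sa = "." if a == MISSING_ALLELE else str(int(a))
                sb = "." if b == MISSING_ALLELE else str(int(b))
                fields.append(f"{sa}{sep}{sb}")
            fh.write("\t".join(fields) + "\n")
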