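"""Shared fixtures: small hand-built panels and sequences."""

from __future__ import annotations

import numpy as np
import pytest

from evoscreen.io import GenotypePanel, SequenceRecord, VariantSite


def build_panel(
    sites: list[tuple[int, str, tuple[str, ...], str | None]],
    genotypes: list[list[tuple[int, int]]],
    chrom: str = "chr1",
    populations: dict[str, str] | None = None,
    phased: bool = True,
) -> GenotypePanel:
    """Panel from a list of (pos, ref, alts, ancestral) and per-sample
    genotype tuples (use -1 for a missing allele)."""
    n_samples = len(genotypes)
    samples = [f"s{i}" for i in range(n_samples)]
    site_objs = [
        VariantSite(chrom=chrom, pos=pos, ref=ref, alts=alts, ancestral=aa, id=f"snp_{pos}")
        for pos, ref, alts, aa in sites
    ]
    geno = np.array(genotypes, dtype=np.int16).reshape(n_samples, len(sites), 2)
    return GenotypePanel(
        samples=samples,
        populations=populations or {s: "pop" for s in samples},
        sites=site_objs,
        genotypes=geno,
        phased=np.full((n_samples, len(sites)), phased, dtype=bool),
    )


@pytest.fixture
def toy_proteins() -> list[SequenceRecord]:
    return [
        SequenceRecord("p1", "p1 kinase", "MKVLHEDAARNDWQ"),
        SequenceRecord("p2", "p2 channel", "MGGYPLLTTRSCE"),
        SequenceRecord("p3", "p3 receptor", "MNNAFEDKYWIHP"),
    ]
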