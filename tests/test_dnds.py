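"""NG86 estimator, orthology, clade contrast and FDR machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evoscreen import dnds
from evoscreen.dnds import (
    CodonAlignment,
    SkipColumn,
    align_proteins,
    benjamini_hochberg,
    clade_contrast,
    estimate_dnds,
    mean_identity,
    ng86_site_counts,
    pathway_difference_counts,
    project_codon_alignment,
    reciprocal_best_hits,
    summarize_genome_pair,
)
from evoscreen.io import SequenceRecord

# ---------------------------------------------------------------------------
# independent oracle: exhaustive 9-neighbour enumeration


STANDARD = {}
_BASES = "ACGT"
_T = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
SENSE_CODONS = sorted(c for c, aa in _T.items() if aa != "*")


def oracle_site_counts(codon):
    """Enumerate all 9 single-nucleotide neighbours; synonymous fraction
    per position = syn / 3 with stop targets counted non-synonymous."""
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _T[mutant] != "*" and _T[mutant] == _T[codon]:
                syn += 1 / 3
    return syn, 3 - syn


class TestSiteCounts:
    @pytest.mark.parametrize("codon", SENSE_CODONS)
    def test_matches_enumeration_oracle_all_sense_codons(self, codon):
        s, n = ng86_site_counts(codon)
        s_ref, n_ref = oracle_site_counts(codon)
        assert s == pytest.approx(s_ref)
        assert n == pytest.approx(n_ref)
        assert s + n == pytest.approx(3.0)

    def test_phe_and_met_examples(self):
        assert ng86_site_counts("TTT")[0] == pytest.approx(1 / 3)
        assert ng86_site_counts("ATG")[0] == 0.0

    @pytest.mark.parametrize("bad", ["TAA", "TGA", "---", "ANT"])
    def test_stop_and_ambiguous_signal_skip(self, bad):
        with pytest.raises(SkipColumn):
            ng86_site_counts(bad)


class TestPathwayCounts:
    def test_single_synonymous_difference(self):
        assert pathway_difference_counts("TTA", "TTG") == (1.0, 0.0)

    def test_single_nonsynonymous_difference(self):
        assert pathway_difference_counts("TTT", "TTA") == (0.0, 1.0)

    def test_two_position_pathway_average(self):
        # TTT (F) <-> GTA (V): paths F->V->V (1 syn) and F->L->V (0 syn)
        sd, nd = pathway_difference_counts("TTT", "GTA")
        assert sd + nd == pytest.approx(2.0)
        assert sd == pytest.approx(0.5)

    def test_symmetric_in_codon_order(self):
        for a, b in [("TTT", "GTA"), ("ATG", "CGC"), ("AAA", "CCC")]:
            assert pathway_difference_counts(a, b) == pytest.approx(
                pathway_difference_counts(b, a)
            )

    def test_stop_passing_orderings_excluded(self):
        # TAT (Y) <-> TGA would involve stops, but both inputs must be
        # sense; check a pair whose direct intermediate is a stop:
        # TAC (Y) <-> TGG (W): via TGC (C) ok, via TAG (stop) excluded
        sd, nd = pathway_difference_counts("TAC", "TGG")
        assert (sd, nd) == (0.0, 2.0)


class TestEstimate:
    def _aln(self, row_a, row_b):
        split = lambda s: [s[i : i + 3] for i in range(0, len(s), 3)]
        return CodonAlignment(ids=["a", "b"], rows=[split(row_a), split(row_b)])

    def test_identical_rows_zero_distances_omega_undefined(self):
        est = estimate_dnds(self._aln("TTTATGGCG", "TTTATGGCG"))
        assert est.Sd == est.Nd == 0
        assert est.dS == est.dN == 0.0
        assert est.omega is None

    def test_single_synonymous_difference_example(self):
        est = estimate_dnds(self._aln("TTTTTA", "TTTTTG"))
        assert est.Sd == pytest.approx(1.0)
        assert est.Nd == pytest.approx(0.0)
        # oracle site counts for the four codons involved
        S_ref = (
            oracle_site_counts("TTT")[0]
            + oracle_site_counts("TTA")[0]
            + oracle_site_counts("TTT")[0]
            + oracle_site_counts("TTG")[0]
        ) / 2
        assert est.S == pytest.approx(S_ref)
        assert est.pS == pytest.approx(1.0 / S_ref)
        # pS = 1.0 here saturates the Jukes-Cantor correction
        assert est.pS >= 0.75
        assert est.dS is None and est.ds_inestimable
        assert est.omega is None

    def test_conservation_and_symmetry(self):
        rng = np.random.default_rng(11)
        codons = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=60)]
        other = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=60)]
        aln = CodonAlignment(ids=["a", "b"], rows=[codons, other])
        flipped = CodonAlignment(ids=["b", "a"], rows=[other, codons])
        est, est_f = estimate_dnds(aln), estimate_dnds(flipped)
        assert est.S + est.N == pytest.approx(3 * est.codons_compared)
        for field in ("S", "N", "Sd", "Nd", "pS", "pN", "dS", "dN", "omega"):
            assert getattr(est, field) == pytest.approx(getattr(est_f, field))

    def test_gap_and_stop_columns_excluded(self):
        aln = CodonAlignment(
            ids=["a", "b"],
            rows=[["TTT", "---", "TAA", "ATG"], ["TTT", "AAA", "TTT", "ATG"]],
        )
        est = estimate_dnds(aln)
        assert est.codons_compared == 2

    def test_no_comparable_columns_is_error(self):
        aln = CodonAlignment(ids=["a", "b"], rows=[["---"], ["TTT"]])
        with pytest.raises(ValueError, match="comparable"):
            estimate_dnds(aln)

    def test_simulation_recovery_single_point(self):
        from evoscreen.simulate import CodonPairSimSpec, simulate_cds_pair

        pair, _ = simulate_cds_pair(
            CodonPairSimSpec(n_codons=10_000, omega=0.3, ds_target=0.3, seed=5)
        )
        aln = project_codon_alignment(
            (pair.protein_a.residues, pair.protein_b.residues), pair.cds_a, pair.cds_b
        )
        est = estimate_dnds(aln)
        assert est.omega == pytest.approx(0.3, abs=0.05)
        assert est.dS == pytest.approx(0.3, abs=0.03)


class TestAlignmentAndProjection:
    def test_identical_sequences_gap_free(self):
        a = SequenceRecord("a", "", "MKVLHE")
        row_a, row_b = align_proteins(a, SequenceRecord("b", "", "MKVLHE"))
        assert row_a == row_b == "MKVLHE"
        assert mean_identity([(row_a, row_b)]) == 100.0

    def test_mkv_vs_mv_single_gap_column(self):
        row_a, row_b = align_proteins(
            SequenceRecord("a", "", "MKV"), SequenceRecord("b", "", "MV")
        )
        assert row_a == "MKV"
        assert row_b.count("-") == 1
        assert row_b.replace("-", "") == "MV"

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            align_proteins(SequenceRecord("a", "", "MKV"), SequenceRecord("b", "", ""))

    def test_gap_free_projection_concatenates_cds(self):
        aln = project_codon_alignment(
            ("MK", "MK"),
            SequenceRecord("a", "", "ATGAAA"),
            SequenceRecord("b", "", "ATGAAG"),
        )
        assert aln.rows[0] == ["ATG", "AAA"]
        assert aln.rows[1] == ["ATG", "AAG"]

    def test_protein_gap_becomes_codon_gap(self):
        aln = project_codon_alignment(
            ("MKK", "M-K"),
            SequenceRecord("a", "", "ATGAAAAAG"),
            SequenceRecord("b", "", "ATGAAG"),
        )
        assert aln.rows[1] == ["ATG", "---", "AAG"]
        assert aln.ungapped(1) == "ATGAAG"

    def test_terminal_stop_trimmed(self):
        aln = project_codon_alignment(
            ("MK", "MK"),
            SequenceRecord("a", "", "ATGAAATAA"),
            SequenceRecord("b", "", "ATGAAG"),
        )
        assert aln.rows[0] == ["ATG", "AAA"]

    def test_translation_mismatch_names_codon(self):
        with pytest.raises(ValueError, match="codon 2"):
            project_codon_alignment(
                ("MK", "MK"),
                SequenceRecord("a", "", "ATGCCC"),  # CCC is Pro, not Lys
                SequenceRecord("b", "", "ATGAAG"),
            )


class TestReciprocalBestHits:
    def test_self_pairing(self, toy_proteins):
        copy = [SequenceRecord(r.id + "_b", r.description, r.residues) for r in toy_proteins]
        pairs = reciprocal_best_hits(toy_proteins, copy)
        assert pairs == [(r.id, r.id + "_b") for r in toy_proteins]

    def test_shuffled_homologs_with_decoy(self, toy_proteins):
        # two recognisable homologs (single substitutions) + one decoy
        homolog_1 = SequenceRecord("h1", "", "MKVLHEDAARNDWE")  # ~p1
        homolog_2 = SequenceRecord("h2", "", "MGGYPLLTTRSCD")  # ~p2
        decoy = SequenceRecord("zz", "", "WWWWWWHHHHCCCC")
        pairs = reciprocal_best_hits(toy_proteins[:2], [decoy, homolog_2, homolog_1])
        assert ("p1", "h1") in pairs
        assert ("p2", "h2") in pairs
        assert all("zz" not in p for p in pairs)

    def test_empty_proteome(self, toy_proteins):
        assert reciprocal_best_hits([], toy_proteins) == []


class TestGenomePairFilter:
    def _summary(self, ds_values):
        ests = {
            f"g{i}": dnds.DnDsEstimate(
                S=10, N=20, Sd=1, Nd=1, pS=0.1, pN=0.05, dS=ds, dN=0.05,
                omega=None if ds in (None, 0) else 0.05 / ds, codons_compared=10,
            )
            for i, ds in enumerate(ds_values)
        }
        return summarize_genome_pair(ests, "mammal", ("sp1", "sp2"))

    @pytest.mark.parametrize(
        "median,accepted", [(0.35, True), (0.27, True), (0.47, True), (0.50, False), (0.20, False)]
    )
    def test_ds_window_inclusive(self, median, accepted):
        s = self._summary([median, median, median])
        assert s.median_ds == pytest.approx(median)
        assert s.accepted is accepted

    def test_undefined_ds_excluded_from_median(self):
        s = self._summary([0.30, None, 0.40])
        assert s.median_ds == pytest.approx(0.35)

    def test_all_undefined_is_error(self):
        with pytest.raises(ValueError, match="defined dS"):
            self._summary([None, None])


class TestCladeContrast:
    def test_separated_clades_significant(self):
        p = clade_contrast(
            {"reptile": [0.1, 0.12, 0.11, 0.09], "bird": [0.5, 0.52, 0.48, 0.51]},
            ("reptile", "bird"),
        )
        # independent reference: Welch t on the same samples
        from scipy import stats as sstats

        ref = sstats.ttest_ind(
            [0.1, 0.12, 0.11, 0.09], [0.5, 0.52, 0.48, 0.51], equal_var=False
        ).pvalue
        assert p == pytest.approx(ref)
        assert p < 0.001

    def test_symmetric_in_clade_order(self):
        samples = {"a": [0.1, 0.3, 0.2], "b": [0.4, 0.2, 0.5]}
        assert clade_contrast(samples, ("a", "b")) == pytest.approx(
            clade_contrast(samples, ("b", "a"))
        )

    def test_degenerate_constant_clades(self):
        assert clade_contrast({"a": [0.2, 0.2], "b": [0.2, 0.2]}, ("a", "b")) == 1.0

    def test_single_sample_clade_missing(self):
        assert clade_contrast({"a": [0.2], "b": [0.3, 0.4]}, ("a", "b")) is None

    def test_mannwhitney_option(self):
        p = clade_contrast(
            {"a": [0.1, 0.2, 0.15, 0.12], "b": [0.5, 0.6, 0.55, 0.52]},
            ("a", "b"),
            method="mannwhitney",
        )
        assert 0 < p < 0.05


def brute_force_bh(pvalues):
    """Literal step-up definition: q_i = min over j with p_(j) >= p_(i)
    of m p_(j) / rank(j), clipped to 1."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    sorted_p = p[order]
    running = np.minimum.accumulate((m * sorted_p / np.arange(1, m + 1))[::-1])[::-1]
    q[order] = np.minimum(running, 1.0)
    return q


class TestBenjaminiHochberg:
    def test_single_p(self):
        assert benjamini_hochberg([0.04])[0] == pytest.approx(0.04)

    def test_hand_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert benjamini_hochberg([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, pvalues):
        assert benjamini_hochberg(pvalues) == pytest.approx(brute_force_bh(pvalues))

    def test_q_at_least_p_and_order_preserving(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=30)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-12).all()
        assert ((q[np.argsort(p)][1:] - q[np.argsort(p)][:-1]) >= -1e-12).all()


class TestMeanIdentity:
    def test_half_mismatched_columns(self):
        row_a = "A" * 100
        row_b = "A" * 50 + "C" * 50
        assert mean_identity([(row_a, row_b)]) == pytest.approx(50.0)
        assert dnds.low_identity_flag(50.0) is True

    def test_exactly_sixty_percent_not_flagged(self):
        assert dnds.low_identity_flag(60.0) is False

    def test_gap_columns_excluded_from_denominator(self):
        assert mean_identity([("AC-G", "AC-T")]) == pytest.approx(2 / 3 * 100)

    def test_all_gap_alignment_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            assert mean_identity([("--", "AA")]) is None
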