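"""Canonical k-mers, presence scanning and the exact Fisher core."""

import math

import numpy as np
import pytest

from coldcre.genes import GeneRecord
from coldcre.kmers import (
    PresenceIndex,
    binned_enrichment,
    build_matrix,
    canonical,
    fisher_enrichment,
    fisher_pvalues,
    gene_kmer_presence,
    odds_ratios,
)

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMP)[::-1]


def hypergeom_tail(a, b, c, d):
    """Independent oracle: exact one-sided tail sum with integer arithmetic."""
    n_row = a + b
    n_col = a + c
    N = a + b + c + d
    den = math.comb(N, n_row)
    num = sum(
        math.comb(n_col, x) * math.comb(N - n_col, n_row - x)
        for x in range(a, min(n_row, n_col) + 1)
    )
    return num / den


class TestCanonical:
    @pytest.mark.parametrize("kmer,expected", [
        ("TTTTT", "AAAAA"),
        ("ACGCGT", "ACGCGT"),  # reverse-complement palindrome
        ("TGCAA", "TGCAA"),    # TGCAA < TTGCA
    ])
    def test_examples(self, kmer, expected):
        assert canonical(kmer) == expected

    def test_idempotent_and_strand_invariant(self, rng):
        for _ in range(200):
            k = int(rng.integers(5, 9))
            s = "".join(rng.choice(list("ACGT"), k))
            c = canonical(s)
            assert canonical(c) == c
            assert canonical(revcomp(s)) == c
            assert c <= revcomp(c)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            canonical("ACGTN")


class TestPresence:
    def test_tiny_gene(self):
        g = GeneRecord("g", upstream_seq="AAAAAA")
        assert gene_kmer_presence(g, k_range=(5,)) == {"AAAAA"}

    def test_short_region_contributes_nothing(self):
        g = GeneRecord("g", upstream_seq="ACGT", body_seq="", downstream_seq="")
        assert gene_kmer_presence(g, k_range=(5,)) == set()

    def test_matches_two_strand_scan_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 1000))
        g = GeneRecord("g", upstream_seq=seq)
        got = gene_kmer_presence(g, k_range=(5,))
        expected = set()
        for strand in (seq, revcomp(seq)):
            for i in range(len(strand) - 4):
                w = strand[i:i + 5]
                expected.add(min(w, revcomp(w)))
        assert got == expected

    def test_feature_matrix_invariant_under_revcomp(self, rng):
        genes = [
            GeneRecord(f"g{i}", upstream_seq="".join(rng.choice(list("ACGT"), 300)))
            for i in range(10)
        ]
        flipped = [
            GeneRecord(g.gene_id, upstream_seq=revcomp(g.upstream_seq))
            for g in genes
        ]
        kmers = ["GATTA", "CCACGT", "ACGCGT", "TTTTTT"]
        ids = [g.gene_id for g in genes]
        X1 = PresenceIndex(genes, (5, 6)).presence_matrix(ids, kmers)
        X2 = PresenceIndex(flipped, (5, 6)).presence_matrix(ids, kmers)
        assert np.array_equal(X1, X2)


class TestFisher:
    @pytest.mark.parametrize("table,expected", [
        ((8, 2, 2, 8), 2126 / 184756),
        ((10, 0, 0, 10), 1 / math.comb(20, 10)),
    ])
    def test_known_tables(self, table, expected):
        res = fisher_enrichment("AAAAA", *table)
        assert res.p == pytest.approx(expected, abs=1e-12)

    def test_balanced_table_not_enriched(self):
        assert fisher_enrichment("AAAAA", 5, 5, 5, 5).p > 0.5

    def test_matches_tail_oracle_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
            if a + b == 0 or c + d == 0:
                continue
            got = float(fisher_pvalues(a, b, c, d))
            assert got == pytest.approx(hypergeom_tail(a, b, c, d), abs=1e-10)

    def test_odds_ratio_and_haldane(self):
        assert float(odds_ratios(8, 2, 2, 8)) == pytest.approx(16.0)
        # zero cell: corrected, finite and positive
        orat = float(odds_ratios(10, 0, 0, 10))
        assert np.isfinite(orat) and orat > 0


class TestBinnedEnrichment:
    def _genes_with_motif(self, rng, n_sig, n_bg, p_sig=0.9, p_bg=0.02,
                          motif="GATTACA"):
        genes, pos, neg = [], [], []
        for i in range(n_sig + n_bg):
            seq = "".join(rng.choice(list("ACGT"), 200))
            signal = i < n_sig
            p = p_sig if signal else p_bg
            if rng.random() < p:
                off = int(rng.integers(0, len(seq) - len(motif)))
                seq = seq[:off] + motif + seq[off + len(motif):]
            g = GeneRecord(f"g{i}", upstream_seq=seq)
            genes.append(g)
            (pos if signal else neg).append(g.gene_id)
        return genes, pos, neg

    def test_planted_kmer_recovered(self, rng):
        genes, pos, neg = self._genes_with_motif(rng, 250, 250)
        index = PresenceIndex(genes, (7,))
        selected = binned_enrichment(index, pos, neg, seed=0)
        assert canonical("GATTACA") in selected

    def test_null_returns_nothing(self, rng):
        genes, pos, neg = self._genes_with_motif(rng, 100, 100, p_sig=0.0,
                                                 p_bg=0.0)
        index = PresenceIndex(genes, (5, 6))
        assert binned_enrichment(index, pos, neg, seed=0) == []

    def test_single_bin_reduces_to_plain_screen(self, rng):
        genes, pos, neg = self._genes_with_motif(rng, 60, 60)
        index = PresenceIndex(genes, (7,))
        selected, tables = binned_enrichment(index, pos, neg, n_bins=1,
                                             seed=0, return_tables=True)
        sig = set(tables.loc[tables["q"] < 0.05, "kmer"])
        assert set(selected) == sig

    def test_selected_kmers_significant_in_every_bin(self, rng):
        genes, pos, neg = self._genes_with_motif(rng, 250, 250)
        index = PresenceIndex(genes, (7,))
        selected, tables = binned_enrichment(index, pos, neg, seed=0,
                                             return_tables=True)
        for km in selected:
            qs = tables.loc[tables["kmer"] == km, "q"]
            assert len(qs) == 5 and (qs < 0.05).all()

    def test_too_few_genes_raises(self, rng):
        genes, pos, neg = self._genes_with_motif(rng, 3, 10)
        index = PresenceIndex(genes, (5,))
        from coldcre.simulate import InsufficientExamplesError
        with pytest.raises(InsufficientExamplesError):
            binned_enrichment(index, pos, neg, n_bins=5)


class TestMatrix:
    def test_cells_match_presence_and_zero_columns_kept(self, rng):
        genes = [
            GeneRecord(f"g{i}", upstream_seq="".join(rng.choice(list("ACGT"), 150)))
            for i in range(8)
        ]
        index = PresenceIndex(genes, (5, 6, 7, 8))
        kmers = ["GATTA", "AACCGGTT"]  # the 8-mer is unlikely to occur
        mat = build_matrix(index, kmers, [g.gene_id for g in genes[:4]],
                           [g.gene_id for g in genes[4:]])
        for i, gid in enumerate(mat.genes):
            present = gene_kmer_presence(genes[i], (5, 8))
            for j, km in enumerate(kmers):
                assert mat.values[i, j] == (1 if canonical(km) in present else 0)
        assert mat.values.shape == (8, 2)
        assert list(mat.class_labels) == [1] * 4 + [0] * 4

    def test_empty_kmer_list_rejected(self, rng):
        genes = [GeneRecord("g", upstream_seq="ACGTACGT")]
        index = PresenceIndex(genes, (5,))
        with pytest.raises(ValueError, match="no-features"):
            build_matrix(index, [], ["g"], [])
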