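"""Synthetic dataset generator: planting, labels, reproducibility."""

import numpy as np
import pytest
from scipy.stats import binom

from coldcre.genes import write_region_fasta
from coldcre.kmers import canonical
from coldcre.labeling import label_genes
from coldcre.pwm import kmer_to_pwm
from coldcre.simulate import (
    MotifTooLongError,
    PlantedMotif,
    SimulationConfig,
    generate_dataset,
    plant_instance,
    write_de_table,
)

from conftest import TIME_POINTS

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMP)[::-1]


def small_config(**kw):
    defaults = dict(
        n_genes=150, upstream_len=200, body_len_range=(100, 200),
        downstream_len=100, seed=7,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestPlantInstance:
    def test_single_column_overwrite(self, rng):
        seq = "CCCCCCCCCC"
        out, off, orient, site = plant_instance(seq, kmer_to_pwm("A"), rng)
        assert len(out) == 10
        assert sum(a != b for a, b in zip(seq, out)) <= 1
        assert out[off] in "AT"  # A forward or its complement on revcomp

    def test_deterministic_given_rng_state(self):
        pwm = kmer_to_pwm("GATTACA")
        out1 = plant_instance("C" * 50, pwm, np.random.default_rng(5))
        out2 = plant_instance("C" * 50, pwm, np.random.default_rng(5))
        assert out1 == out2

    def test_forced_forward_orientation_writes_consensus(self, rng):
        seq = "C" * 30
        out, off, orient, site = plant_instance(seq, kmer_to_pwm("GATTACA"),
                                                rng, orientation="forward")
        assert out[off:off + 7] == "GATTACA"
        assert out.count("GATTACA") == 1  # absent from the C-run baseline

    def test_motif_longer_than_sequence_rejected(self, rng):
        with pytest.raises(MotifTooLongError):
            plant_instance("ACG", kmer_to_pwm("GATTACA"), rng)


class TestGenerateDataset:
    def test_empty_config(self):
        genes, de, lib, truth = generate_dataset(small_config(n_genes=0))
        assert genes == [] and de.empty and truth == []

    def test_every_gene_has_three_regions_and_full_de_coverage(self):
        cfg = small_config()
        genes, de, lib, truth = generate_dataset(cfg)
        for g in genes:
            assert len(g.upstream_seq) == cfg.upstream_len
            assert cfg.body_len_range[0] <= len(g.body_seq) <= cfg.body_len_range[1]
            assert len(g.downstream_seq) == cfg.downstream_len
            assert set(g.upstream_seq) <= set("ACGT")
        per_gene = de.groupby("gene_id").size()
        n_conditions = len(cfg.time_points) + len(cfg.other_conditions)
        assert (per_gene == n_conditions).all()

    def test_certain_planting_scan_oracle(self):
        """p_signal=1, p_background=0: every 0.5 hr up gene carries the
        consensus in its upstream (either strand); no negative does."""
        cfg = small_config(
            n_genes=200,
            planted_motifs=[PlantedMotif("GATTACA", ("0.5",), 1.0, 0.0)],
        )
        genes, de, lib, truth = generate_dataset(cfg)
        labels = label_genes(de)
        by_id = {g.gene_id: g for g in genes}

        def carries(g):
            s = g.upstream_seq
            return "GATTACA" in s or "GATTACA" in revcomp(s)

        for gid in labels["0.5"].up_genes:
            assert carries(by_id[gid])
        # with p_background=0 nothing is planted outside the target genes
        planted_ids = {t.gene_id for t in truth}
        assert not planted_ids & labels["0.5"].negatives
        assert planted_ids >= labels["0.5"].up_genes

    def test_up_counts_within_binomial_bounds(self):
        fracs = (0.05, 0.07, 0.10, 0.15, 0.20, 0.25)
        cfg = SimulationConfig(
            n_genes=2000, upstream_len=50, body_len_range=(50, 60),
            downstream_len=50, responsive_fraction_per_timepoint=fracs, seed=1,
        )
        genes, de, lib, truth = generate_dataset(cfg)
        labels = label_genes(de)
        for tp, f in zip(TIME_POINTS, fracs):
            n_up = len(labels[tp].up_genes)
            lo = binom.ppf(0.005, 2000, f)
            hi = binom.ppf(0.995, 2000, f)
            assert lo <= n_up <= hi, (tp, n_up, lo, hi)

    def test_cascading_counts_non_decreasing_in_expectation(self):
        cfg = SimulationConfig(
            n_genes=3000, upstream_len=50, body_len_range=(50, 60),
            downstream_len=50,
            responsive_fraction_per_timepoint=(0.05, 0.10, 0.15, 0.20, 0.25, 0.30),
            seed=2,
        )
        _, de, _, _ = generate_dataset(cfg)
        labels = label_genes(de)
        counts = [len(labels[tp].up_genes) for tp in TIME_POINTS]
        # allow small sampling noise around the strictly increasing means
        assert all(b >= a - 25 for a, b in zip(counts, counts[1:]))
        assert counts[-1] > counts[0]

    def test_truth_ledger_consistent_with_sequences(self):
        cfg = small_config(
            planted_motifs=[PlantedMotif("CCACGTG", ("1", "3"), 0.9, 0.1)],
        )
        genes, de, lib, truth = generate_dataset(cfg)
        by_id = {g.gene_id: g for g in genes}
        assert truth, "expected planted instances"
        for t in truth:
            seq = by_id[t.gene_id].region(t.region)
            written = seq[t.offset: t.offset + 7]
            assert written == t.instance
            expected = "CCACGTG" if t.orientation == "forward" else revcomp("CCACGTG")
            assert written == expected

    def test_byte_identical_reproducibility(self, tmp_path):
        for sub in ("a", "b"):
            cfg = small_config(planted_motifs=[
                PlantedMotif("GATTACA", ("0.5",), 0.5, 0.05)])
            genes, de, _, _ = generate_dataset(cfg)
            d = tmp_path / sub
            d.mkdir()
            write_region_fasta(genes, d / "genes.fasta")
            write_de_table(de, d / "de.tsv")
        assert (tmp_path / "a/genes.fasta").read_bytes() == \
               (tmp_path / "b/genes.fasta").read_bytes()
        assert (tmp_path / "a/de.tsv").read_bytes() == \
               (tmp_path / "b/de.tsv").read_bytes()

    def test_tfbm_library_contains_planted_and_decoys(self):
        cfg = small_config(
            planted_motifs=[PlantedMotif("GATTACA", ("0.5",), 0.8, 0.05)],
            n_decoy_tfbms=4,
        )
        _, _, lib, _ = generate_dataset(cfg)
        planted = [r for r in lib if r.family == "FAM_GATTACA"]
        assert planted and planted[0].pwm.consensus() == "GATTACA"
        assert sum(r.family.startswith("DECOYFAM") for r in lib) == 4

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(responsive_fraction_per_timepoint=(0.3, 0.2, 0.2, 0.2, 0.2, 0.2))
        with pytest.raises(MotifTooLongError):
            small_config(upstream_len=5,
                         planted_motifs=[PlantedMotif("GATTACA", ("0.5",))])
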