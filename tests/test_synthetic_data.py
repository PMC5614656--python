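"""Synthetic transcriptomes, expression assignment and read simulation."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import gamma

from splicestat import synthetic_data as synth
from splicestat.synthetic_data import ReadSimConfig


class TestSyntheticTranscriptome:
    def test_counts_conserved(self):
        tx = synth.synthetic_transcriptome(5, M_distribution=2, seed=1)
        assert len(tx.genes) == 5
        assert len(tx.transcripts) == 10
        assert len(set(tx.t2g.values())) == 5

    def test_deterministic_fasta_bytes(self, tmp_path):
        paths = []
        for i in (1, 2):
            tx = synth.synthetic_transcriptome(3, M_distribution=3, seed=42)
            p = tmp_path / f"tx{i}.fasta"
            tx.write_fasta(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_gc_content_near_half(self):
        tx = synth.synthetic_transcriptome(
            400, M_distribution=1, length_range=(2500, 2500), seed=2
        )
        pooled = "".join(tx.transcripts.values())
        gc = (pooled.count("G") + pooled.count("C")) / len(pooled)
        assert gc == pytest.approx(0.5, abs=0.02)

    def test_short_lengths_need_explicit_opt_in(self):
        with pytest.raises(ValueError):
            synth.synthetic_transcriptome(2, length_range=(100, 200), seed=3)
        tx = synth.synthetic_transcriptome(
            2, length_range=(100, 200), seed=3, allow_short=True
        )
        assert all(len(s) < 300 for s in tx.transcripts.values())


class TestExtractTranscriptSequences:
    def write_genome(self, tmp_path, contigs):
        path = tmp_path / "genome.fasta"
        with open(path, "w") as fh:
            for name, seq in contigs.items():
                fh.write(f">{name}\n{seq}\n")
        return path

    def test_two_exon_plus_strand_concatenation(self, tmp_path):
        contig = "ACGTACGTGGATCCAAGGTTCCGGAATTACGTACGTAAGGCCTTGGAACCTTAAGGCCAA"
        genome = self.write_genome(tmp_path, {"chr1": contig})
        gtf = tmp_path / "ann.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t3\t8\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tsrc\texon\t21\t28\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        seqs = synth.extract_transcript_sequences(genome, gtf)
        # 1-based inclusive: bases 3-8 then 21-28
        assert seqs["t1"] == contig[2:8] + contig[20:28]

    def test_minus_strand_reverse_complemented(self, tmp_path):
        contig = "AACCGGTTACGT"
        genome = self.write_genome(tmp_path, {"chr1": contig})
        gtf = tmp_path / "ann.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t1\t6\t.\t-\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        seqs = synth.extract_transcript_sequences(genome, gtf)
        assert seqs["t1"] == "CCGGTT"  # revcomp of AACCGG

    def test_out_of_bounds_exon_names_transcript(self, tmp_path):
        genome = self.write_genome(tmp_path, {"chr1": "ACGTACGT"})
        gtf = tmp_path / "ann.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t5\t50\t.\t+\t.\tgene_id "g1"; transcript_id "tbad";\n'
        )
        with pytest.raises(ValueError, match="tbad"):
            synth.extract_transcript_sequences(genome, gtf)

    def test_no_exons_rejected(self, tmp_path):
        genome = self.write_genome(tmp_path, {"chr1": "ACGTACGT"})
        gtf = tmp_path / "ann.gtf"
        gtf.write_text(
            'chr1\tsrc\tgene\t1\t8\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        with pytest.raises(ValueError):
            synth.extract_transcript_sequences(genome, gtf)


class TestAssignExpression:
    def test_normal_law_moments(self):
        tx = synth.synthetic_transcriptome(
            1000, M_distribution=100, length_range=(300, 301), seed=4
        )
        vals = np.array(list(synth.assign_expression(tx, "normal:20,2", seed=5).values()))
        assert vals.size == 10**5
        assert vals.mean() == pytest.approx(20.0, abs=0.05)
        assert vals.std() == pytest.approx(2.0, abs=0.05)
        assert vals.min() >= 0

    def test_weibull_law_mean_identity(self):
        tx = synth.synthetic_transcriptome(
            1000, M_distribution=100, length_range=(300, 301), seed=6
        )
        vals = np.array(
            list(synth.assign_expression(tx, "weibull:0.39,10", seed=7).values())
        )
        assert vals.mean() == pytest.approx(10 * gamma(1 + 1 / 0.39), abs=0.6)

    def test_deterministic_mapping(self):
        tx = synth.synthetic_transcriptome(10, M_distribution=2, seed=8)
        assert synth.assign_expression(tx, "normal:20,2", seed=9) == (
            synth.assign_expression(tx, "normal:20,2", seed=9)
        )

    def test_unknown_law_rejected(self):
        tx = synth.synthetic_transcriptome(2, M_distribution=1, seed=10)
        with pytest.raises(ValueError):
            synth.assign_expression(tx, "poisson:5,0", seed=0)


class TestReadPairCount:
    @pytest.mark.parametrize(
        "E,L,expected",
        [
            (20.0, 1000, 100),  # int(100.5) = 100
            (0.0, 500, 0),
            (1.0, 100, 1),  # int(1.0) = 1
            (0.99, 100, 0),  # int(0.995) = 0
        ],
    )
    def test_round_half_up_formula(self, E, L, expected):
        assert synth.read_pair_count(E, L) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            synth.read_pair_count(-1.0, 100)
        with pytest.raises(ValueError):
            synth.read_pair_count(1.0, 0)


class TestGenerateReadPairs:
    def test_pair_count_and_geometry(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), 600))
        pairs = synth.generate_read_pairs("t1", seq, 3, ReadSimConfig(seed=0), rng)
        assert len(pairs) == 3
        for name, r1, r2 in pairs:
            assert len(r1) == len(r2) == 100
            assert name.startswith("t1:pair")

    def test_reads_are_substrings_or_revcomp(self):
        from Bio.Seq import Seq

        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), 800))
        for _, r1, r2 in synth.generate_read_pairs(
            "t1", seq, 20, ReadSimConfig(seed=0), rng
        ):
            assert r1 in seq
            assert str(Seq(r2).reverse_complement()) in seq

    def test_fragment_starts_uniform(self):
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list("ACGT"), 1300))
        pairs = synth.generate_read_pairs("t1", seq, 10_000, ReadSimConfig(seed=0), rng)
        starts = [seq.index(r1) for _, r1, _ in pairs]
        # 1300 - 300 + 1 = 1001 valid starts; bin into 10 and chi-square
        counts, _ = np.histogram(starts, bins=10, range=(0, 1001))
        assert stats.chisquare(counts).pvalue > 1e-3

    def test_too_short_transcript_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            synth.generate_read_pairs(
                "t1", "ACGT" * 50, 1, ReadSimConfig(seed=0), np.random.default_rng(0)
            )


class TestFastqSimulation:
    def test_record_counts_match_formula(self, tmp_path):
        tx = synth.synthetic_transcriptome(
            5, M_distribution=2, length_range=(400, 900), seed=14
        )
        expr = synth.assign_expression(tx, "weibull:0.39,10", seed=15)
        cfg = ReadSimConfig(replicates=1, seed=16)
        truth = synth.simulate_fastq(tx, expr, cfg, tmp_path, prefix="x")
        expected = sum(
            synth.read_pair_count(expr[t], len(s)) for t, s in tx.transcripts.items()
        )
        assert truth["pairs"].sum() == expected
        n_records = (tmp_path / "x_rep1_R1.fastq").read_text().count("@")
        assert n_records == expected

    def test_requantification_recovers_expression(self, tmp_path):
        tx = synth.synthetic_transcriptome(
            20, M_distribution=2, length_range=(400, 1200), seed=17
        )
        expr = synth.assign_expression(tx, "weibull:0.39,10", seed=18)
        cfg = ReadSimConfig(replicates=1, seed=19)
        synth.simulate_fastq(tx, expr, cfg, tmp_path, prefix="x")
        quant = synth.requantify_exact(
            tmp_path / "x_rep1_R1.fastq", tmp_path / "x_rep1_R2.fastq", tx
        )
        assert quant.attrs["unassigned_pairs"] == 0
        for _, row in quant.iterrows():
            E = expr[row["transcript_id"]]
            assert abs(row["E_hat"] - E) <= 200.0 / row["length"]


class TestExpressionTable:
    def test_round_trips_through_reader(self, tmp_path):
        from splicestat import expression_io as eio

        table, t2g, truth = synth.expression_table(
            50, M_distribution={1: 1, 2: 1, 3: 1}, law="weibull:0.39,10", seed=20
        )
        path = tmp_path / "quant.sf"
        table.to_csv(path, sep="\t", index=False)
        back = eio.read_expression_table(path, "salmon", t2g=t2g)
        np.testing.assert_allclose(back["expression"], table["TPM"])
        assert len(back) == len(truth)

    def test_deterministic(self):
        t1, _, _ = synth.expression_table(20, seed=21)
        t2, _, _ = synth.expression_table(20, seed=21)
        assert t1.equals(t2)
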