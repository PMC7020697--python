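"""Round-trips, coordinate conventions and validation of the I/O layer."""

import numpy as np
import pandas as pd
import pytest

from medipdiff import Peak, ProbeTable, read_bed, read_probe_table, write_bed
from medipdiff.datamodel import (
    GroupDesign,
    PhenotypeTable,
    read_clone_tsv,
    read_fasta_promoters,
    read_gmt,
    read_phenotypes,
    write_clone_tsv,
    write_gmt,
    write_probe_table,
)
from medipdiff.bsp import methylation_ratio
from medipdiff.simulate import simulate_clone_matrices


def _write(path, text):
    path.write_text(text)
    return path


class TestProbeTable:
    def test_two_channel_conversion(self, tmp_path):
        path = _write(tmp_path / "probes.tsv", "\n".join([
            "probe_id\tchrom\tstart\tend\ts1_MeDIP\ts1_Input",
            "p1\tchr1\t0\t60\t4\t2",
            "p2\tchr1\t100\t160\t2\t2",
        ]) + "\n")
        table = read_probe_table(path, format="two_channel")
        assert table.sample_ids == ["s1"]
        assert table.frame["s1"].tolist() == [1.0, 0.0]

    def test_nonpositive_intensity_names_probe(self, tmp_path):
        path = _write(tmp_path / "probes.tsv", "\n".join([
            "probe_id\tchrom\tstart\tend\ts1_MeDIP\ts1_Input",
            "p1\tchr1\t0\t60\t4\t2",
            "bad_probe\tchr1\t100\t160\t0\t2",
        ]) + "\n")
        with pytest.raises(ValueError, match="bad_probe"):
            read_probe_table(path, format="two_channel")

    def test_unsorted_input_sorted_with_values_aligned(self, tmp_path):
        rows = [("p3", "chr2", 50, 110, 0.3), ("p1", "chr1", 500, 560, 0.1),
                ("p2", "chr1", 100, 160, 0.2)]
        text = "probe_id\tchrom\tstart\tend\ts1\n" + "".join(
            f"{p}\t{c}\t{s}\t{e}\t{v}\n" for p, c, s, e, v in rows)
        table = read_probe_table(_write(tmp_path / "probes.tsv", text))
        # oracle: independently sorted copy of the input rows
        expected = sorted(rows, key=lambda r: (r[1], r[2]))
        assert table.frame["probe_id"].tolist() == [r[0] for r in expected]
        assert table.frame["s1"].tolist() == [r[4] for r in expected]

    def test_duplicate_probe_id_rejected(self):
        frame = pd.DataFrame({"probe_id": ["p1", "p1"], "chrom": ["chr1"] * 2,
                              "start": [0, 100], "end": [60, 160],
                              "s1": [0.0, 1.0]})
        with pytest.raises(ValueError, match="duplicate"):
            ProbeTable(frame, ["s1"])

    def test_probe_table_roundtrip(self, tmp_path, sim_bundle):
        _, table, _, _ = sim_bundle
        write_probe_table(table, tmp_path / "probes.tsv")
        back = read_probe_table(tmp_path / "probes.tsv")
        pd.testing.assert_frame_equal(back.frame, table.frame)


class TestGroupDesign:
    def test_requires_two_groups(self):
        with pytest.raises(ValueError, match="two"):
            GroupDesign({"a": "G1", "b": "G1"})

    def test_validates_coverage(self, sim_bundle):
        _, table, design, _ = sim_bundle
        design.validate_against(table)
        with pytest.raises(ValueError, match="not assigned"):
            GroupDesign({"x": "A", "y": "B"}).validate_against(table)


class TestBed:
    def test_line_format(self, tmp_path):
        peak = Peak("chr1", 100, 500, ["a", "b"], 3.2, name="peak_1")
        write_bed([peak], tmp_path / "out.bed")
        assert (tmp_path / "out.bed").read_text() == "chr1\t100\t500\tpeak_1\t3.2\t.\n"

    def test_empty_records_empty_file(self, tmp_path):
        write_bed([], tmp_path / "out.bed")
        assert (tmp_path / "out.bed").read_text() == ""
        assert len(read_bed(tmp_path / "out.bed")) == 0

    def test_roundtrip_random_peaks(self, tmp_path):
        rng = np.random.default_rng(0)
        peaks = []
        for i in range(10):
            start = int(rng.integers(0, 10_000))
            peaks.append(Peak(f"chr{rng.integers(1, 4)}", start,
                              start + int(rng.integers(60, 900)), ["p"],
                              float(np.round(rng.uniform(0, 10), 4)),
                              name=f"peak_{i + 1}"))
        write_bed(peaks, tmp_path / "peaks.bed")
        back = read_bed(tmp_path / "peaks.bed")
        for peak, row in zip(peaks, back.itertuples(index=False)):
            assert (peak.chrom, peak.start, peak.end, peak.name, peak.score) \
                == (row.chrom, row.start, row.end, row.name, row.score)

    def test_score_clamped(self, tmp_path):
        write_bed([Peak("chr1", 0, 10, ["a"], 1e6)], tmp_path / "o.bed")
        assert read_bed(tmp_path / "o.bed")["score"].iloc[0] == 1000


class TestFastaPromoters:
    def _annot(self, tmp_path, genes):
        lines = ["gene_id\tchrom\ttss\tstrand\tstart\tend"]
        for g in genes:
            lines.append(f"{g}\tchr1\t1500\t+\t200\t1700")
        return _write(tmp_path / "annot.tsv", "\n".join(lines) + "\n")

    def test_join_and_uppercase(self, tmp_path):
        fasta = _write(tmp_path / "p.fa", ">geneA\n" + "acgt" * 375 + "\n")
        recs = read_fasta_promoters(fasta, self._annot(tmp_path, ["geneA"]))
        assert len(recs) == 1
        assert recs[0].end - recs[0].start == 1500
        assert recs[0].sequence == "ACGT" * 375

    def test_missing_entry_names_gene(self, tmp_path):
        fasta = _write(tmp_path / "p.fa", ">geneA\n" + "A" * 1500 + "\n")
        with pytest.raises(ValueError, match="geneB"):
            read_fasta_promoters(fasta, self._annot(tmp_path, ["geneA", "geneB"]))

    def test_non_acgtn_rejected(self, tmp_path):
        fasta = _write(tmp_path / "p.fa", ">geneA\n" + "AXGT" * 375 + "\n")
        with pytest.raises(ValueError, match="geneA"):
            read_fasta_promoters(fasta, self._annot(tmp_path, ["geneA"]))


class TestGmtClonesPhenotypes:
    def test_gmt_parse_and_roundtrip(self, tmp_path):
        path = _write(tmp_path / "s.gmt", "S1\tdesc\tg1\tg2\n")
        coll = read_gmt(path)
        assert coll.sets["S1"][1] == frozenset({"g1", "g2"})
        write_gmt(coll, tmp_path / "back.gmt")
        assert read_gmt(tmp_path / "back.gmt").sets == coll.sets

    def test_clone_matrix_all_ones_ratio(self, tmp_path):
        header = "animal_id\tgroup\tamplicon_id\tclone_id\t" + "\t".join(
            f"cpg_{k + 1}" for k in range(6))
        rows = [f"m1\tCON\tWnt5a\tclone_{c + 1}\t" + "\t".join("1" * 1 for _ in range(6))
                for c in range(10)]
        path = _write(tmp_path / "c.tsv", header + "\n" + "\n".join(rows) + "\n")
        (matrix,) = read_clone_tsv(path)
        assert matrix.calls.shape == (10, 6)
        assert methylation_ratio(matrix).overall == 1.0

    def test_clone_matrix_invalid_entry_rejected(self, tmp_path):
        path = _write(tmp_path / "c.tsv",
                      "animal_id\tgroup\tamplicon_id\tclone_id\tcpg_1\n"
                      "m1\tCON\tWnt5a\tclone_1\t2\n")
        with pytest.raises(ValueError, match="0, 1 or NA"):
            read_clone_tsv(path)

    def test_clone_roundtrip_with_missing(self, tmp_path):
        matrices, _ = simulate_clone_matrices(n_animals=2, n_clones=3, seed=4)
        write_clone_tsv(matrices, tmp_path / "c.tsv")
        back = read_clone_tsv(tmp_path / "c.tsv")
        assert len(back) == len(matrices)
        key = lambda m: (m.amplicon_id, m.group, m.animal_id)
        for a, b in zip(sorted(matrices, key=key), sorted(back, key=key)):
            np.testing.assert_array_equal(a.calls, b.calls)

    def test_phenotype_times_and_groups(self, tmp_path):
        header = ("animal_id\tgroup\tbody_weight\tglucose_0\tglucose_15"
                  "\tglucose_30\tglucose_60\tglucose_120\tfasting_insulin")
        good = header + "\nm1\tCON\t8.0\t5\t10\t8\t7\t6\t9.0\n"
        table = read_phenotypes(_write(tmp_path / "p.tsv", good))
        assert table.glucose_times == [0, 15, 30, 60, 120]
        bad = header + "\nm1\tKETO\t8.0\t5\t10\t8\t7\t6\t9.0\n"
        with pytest.raises(ValueError, match="KETO"):
            read_phenotypes(_write(tmp_path / "bad.tsv", bad))

    def test_phenotype_negative_measurement_rejected(self):
        frame = pd.DataFrame({"animal_id": ["m1"], "group": ["CON"],
                              "body_weight": [-1.0], "glucose_0": [5.0]})
        with pytest.raises(ValueError, match="body_weight"):
            PhenotypeTable(frame)
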