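"""Barcode demultiplexing, UMI deduplication and the FASTQ round trip."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macscreen import macseq_counts as mc
from macscreen.synthetic_data import make_layout, make_reference, write_macseq_fastq

BC = "ACGTACGTAC"
TABLE = {BC: "A01", "TTTTGGGGCC": "B02"}
Q_OK = "I" * 20  # Phred 40
READ = BC + "GATCGATCGA"


class TestDemultiplex:
    def test_exact_match_assigned(self):
        well, umi = mc.demultiplex(READ, Q_OK, TABLE)
        assert well == "A01"
        assert umi == "GATCGATCGA"

    def test_one_mismatch_rejected(self):
        mutated = "T" + READ[1:]
        assert mc.demultiplex(mutated, Q_OK, TABLE) == "barcode_mismatch"

    def test_low_quality_in_barcode_rejected(self):
        # quality 19 ('4') at position 5 of the barcode span
        qual = "IIII4" + "I" * 15
        assert mc.demultiplex(READ, qual, TABLE) == "low_quality"

    def test_low_quality_in_umi_rejected(self):
        qual = "I" * 15 + "4" + "I" * 4
        assert mc.demultiplex(READ, qual, TABLE) == "low_quality"

    def test_quality_exactly_at_threshold_passes(self):
        q20 = "5" * 20  # Phred 20
        assert mc.demultiplex(READ, q20, TABLE) == ("A01", "GATCGATCGA")

    def test_short_read_rejected(self):
        assert mc.demultiplex(BC[:8], "I" * 8, TABLE) == "too_short"


class TestTrimRead2:
    def test_trim_then_keep(self):
        r2 = "".join("ACGT"[i % 4] for i in range(75))
        out = mc.trim_read2(r2)
        assert out == r2[15:50]
        assert len(out) == 35

    def test_exactly_50nt(self):
        r2 = "A" * 15 + "C" * 35
        assert mc.trim_read2(r2) == "C" * 35

    def test_too_short_rejected(self):
        assert mc.trim_read2("A" * 20) is None


class TestAssignGene:
    REF = {"gA": "A" * 30 + "CCGGTT" + "A" * 30, "gB": "G" * 60}

    def test_unique_match(self):
        assert mc.assign_gene("CCGGTT", self.REF) == "gA"

    def test_ambiguous_is_none(self):
        ref = {"gA": "ACGT" * 20, "gB": "ACGT" * 15}
        assert mc.assign_gene("ACGTACGT", ref) is None

    def test_unmapped_is_none(self):
        assert mc.assign_gene("TTTTTTTT", self.REF) is None

    def test_empty_reference_is_error(self):
        with pytest.raises(ValueError):
            mc.assign_gene("ACGT", {})


class TestCountUmis:
    def test_pcr_duplicates_collapse(self):
        triples = pd.DataFrame(
            [("w", "g", "AAAA")] * 5, columns=["well", "gene", "umi"]
        )
        assert mc.count_umis(triples).loc["g", "w"] == 1

    def test_distinct_umis_counted(self):
        triples = pd.DataFrame(
            [("w", "g", "AAAA"), ("w", "g", "CCCC")], columns=["well", "gene", "umi"]
        )
        assert mc.count_umis(triples).loc["g", "w"] == 2

    def test_order_invariance(self, rng):
        triples = pd.DataFrame(
            {
                "well": rng.choice(["w1", "w2"], 200),
                "gene": rng.choice(["g1", "g2", "g3"], 200),
                "umi": rng.choice(["A", "C", "G", "T"], 200),
            }
        )
        shuffled = triples.sample(frac=1, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(mc.count_umis(triples), mc.count_umis(shuffled))


class TestNormalization:
    def test_single_gene_well(self):
        m = pd.DataFrame({"w": [7]}, index=["g"])
        cpm = mc.normalize_library_size(m, log=False)
        assert cpm.loc["g", "w"] == pytest.approx(1e6)

    def test_depth_invariance(self):
        m = pd.DataFrame({"w": [3, 7]}, index=["g1", "g2"])
        a = mc.normalize_library_size(m, log=False)
        b = mc.normalize_library_size(2 * m, log=False)
        pd.testing.assert_frame_equal(a, b)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_column_sums_are_scale(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.integers(0, 50, size=(20, 5)))
        m.iloc[:, 0] += 1  # avoid an all-zero well
        cpm = mc.normalize_library_size(m, log=False)
        assert np.allclose(cpm.sum(axis=0), 1e6, atol=1e-6)

    def test_zero_library_well_dropped(self):
        m = pd.DataFrame({"good": [1, 2], "empty": [0, 0]}, index=["g1", "g2"])
        out = mc.normalize_library_size(m)
        assert out.attrs["dropped_wells"] == ["empty"]
        assert list(out.columns) == ["good"]


class TestRoundTrip:
    @pytest.fixture
    def plate(self, rng):
        layout = make_layout(["drugA", "drugB"], replicates=2, seed=11)
        reference = make_reference(n_genes=8, seed=12)
        molecules = pd.DataFrame(
            [
                (w, g, int(rng.integers(1, 25)))
                for w in layout.wells["well"]
                for g in list(reference)[:5]
            ],
            columns=["well", "gene", "count"],
        )
        return layout, reference, molecules

    @pytest.mark.parametrize("dup_factor", [1, 3, 10])
    def test_exact_recovery(self, plate, tmp_path, dup_factor):
        """Error-free FASTQ reproduces the molecule table for any dup factor."""
        layout, reference, molecules = plate
        r1, r2 = tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz"
        n = write_macseq_fastq(
            molecules, layout, reference, r1, r2, dup_factor=dup_factor, seed=13
        )
        assert n == molecules["count"].sum() * dup_factor
        matrix, stats = mc.process_fastq_pair(r1, r2, layout.barcode_table, reference)
        truth = (
            molecules.pivot(index="gene", columns="well", values="count")
            .fillna(0)
            .astype(int)
            .rename_axis(None)
        )
        assert matrix.sort_index().equals(truth.sort_index())
        assert stats.assigned == n
        assert stats.total == n

    def test_rejection_accounting(self, plate, tmp_path):
        """Corrupted barcodes are rejected and the accounting still sums."""
        layout, reference, molecules = plate
        r1, r2 = tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz"
        n = write_macseq_fastq(molecules, layout, reference, r1, r2, seed=14)
        table = dict(list(layout.barcode_table.items())[:2])  # drop two wells
        _, stats = mc.process_fastq_pair(r1, r2, table, reference)
        assert stats.rejected_barcode > 0
        assert stats.total == n

    def test_duplicate_barcode_refused(self, plate, tmp_path):
        layout, reference, molecules = plate
        wells = layout.wells.copy()
        wells.loc[:, "barcode"] = wells["barcode"].iloc[0]
        with pytest.raises(ValueError):
            type(layout)(wells)

    def test_r1_layout(self, plate, tmp_path):
        """R1 carries the well barcode at 1-10 and a distinct UMI at 11-20."""
        import gzip

        layout, reference, molecules = plate
        r1, r2 = tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz"
        write_macseq_fastq(molecules, layout, reference, r1, r2, seed=15)
        bc_of = {w: b for b, w in layout.barcode_table.items()}
        with gzip.open(r1, "rt") as fh:
            lines = fh.read().splitlines()
        for header, seq in zip(lines[0::4], lines[1::4]):
            well = header.split(":")[1]
            assert seq[:10] == bc_of[well]
            assert len(seq) == 20
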