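"""Data model and I/O: genome TSV, genotype TSV, phased VCF, event BED."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meioscan.genotypes import (
    MISSING,
    P1,
    P2,
    ChromosomeDef,
    CrossoverEvent,
    GenotypeError,
    GenotypeMatrix,
    Marker,
    read_events_bed,
    read_genome,
    read_genotype_table,
    read_vcf_phased,
    write_events_bed,
    write_genotype_table,
)


class TestGenomeTSV:
    def test_single_chromosome(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("chr1\t5200000\n")
        g = read_genome(p)
        assert g == [ChromosomeDef("chr1", 5_200_000)]

    def test_nine_chromosome_genome_total(self, tmp_path):
        mb = [6.00, 5.40, 5.00, 4.60, 4.20, 3.80, 3.30, 2.70, 2.23]
        p = tmp_path / "g.tsv"
        p.write_text("".join(f"chr{i + 1}\t{int(m * 1e6)}\n" for i, m in enumerate(mb)))
        g = read_genome(p)
        assert len(g) == 9
        assert sum(c.length for c in g) == 37_230_000

    def test_zero_length_rejected_with_row(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("chr1\t1000\nchr2\t0\n")
        with pytest.raises(GenotypeError, match=":2"):
            read_genome(p)

    def test_duplicate_name_rejected(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("chr1\t1000\nchr1\t2000\n")
        with pytest.raises(GenotypeError, match="duplicate"):
            read_genome(p)


class TestGenotypeTable:
    GENOME = [ChromosomeDef("chr1", 50_000), ChromosomeDef("chr2", 30_000)]

    def _write(self, tmp_path, body, header="marker\tchrom\tpos_bp\tiso1\tiso2"):
        p = tmp_path / "gt.tsv"
        p.write_text(header + "\n" + body)
        return p

    def test_all_parent1_calls(self, tmp_path):
        p = self._write(tmp_path, "m1\tchr1\t100\ta\ta\nm2\tchr1\t200\ta\ta\nm3\tchr1\t300\ta\ta\n")
        m = read_genotype_table(p, self.GENOME)
        assert m.n_markers == 3 and m.n_isolates == 2
        assert (m.calls == P1).all()

    def test_illegal_symbol_reports_line(self, tmp_path):
        p = self._write(tmp_path, "m1\tchr1\t100\ta\ta\nm2\tchr1\t200\tx\ta\n")
        with pytest.raises(GenotypeError, match=":3"):
            read_genotype_table(p, self.GENOME)

    def test_unknown_chromosome_reports_line(self, tmp_path):
        p = self._write(tmp_path, "m1\tchrX\t100\ta\ta\n")
        with pytest.raises(GenotypeError, match=":2"):
            read_genotype_table(p, self.GENOME)

    def test_duplicate_position_rejected(self, tmp_path):
        p = self._write(tmp_path, "m1\tchr1\t100\ta\ta\nm2\tchr1\t100\tb\tb\n")
        with pytest.raises(GenotypeError, match="duplicate"):
            read_genotype_table(p, self.GENOME)

    def test_unsorted_rows_sorted_content_preserved(self, tmp_path):
        # oracle: parse the same rows pre-sorted by hand; outputs must agree
        rows = [
            ("m3", "chr2", 10, "b", "a"),
            ("m1", "chr1", 300, "a", "b"),
            ("m2", "chr1", 100, "b", "-"),
        ]
        body = "".join(f"{r[0]}\t{r[1]}\t{r[2]}\t{r[3]}\t{r[4]}\n" for r in rows)
        shuffled = read_genotype_table(self._write(tmp_path, body), self.GENOME)
        rows_sorted = sorted(rows, key=lambda r: (("chr1", "chr2").index(r[1]), r[2]))
        body2 = "".join(f"{r[0]}\t{r[1]}\t{r[2]}\t{r[3]}\t{r[4]}\n" for r in rows_sorted)
        presorted = read_genotype_table(self._write(tmp_path, body2), self.GENOME)
        assert [m.id for m in shuffled.markers] == [m.id for m in presorted.markers]
        assert (shuffled.calls == presorted.calls).all()

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        n_markers=st.integers(1, 12),
        n_iso=st.integers(1, 4),
        seed=st.integers(0, 10_000),
        with_cm=st.booleans(),
    )
    def test_write_read_round_trip(self, tmp_path_factory, n_markers, n_iso, seed, with_cm):
        """Round-trip preserves calls, marker order and isolate order."""
        tmp_path = tmp_path_factory.mktemp("rt")
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(np.arange(1, 40_000), size=n_markers, replace=False))
        cm = np.sort(rng.random(n_markers) * 50) if with_cm else [None] * n_markers
        markers = [
            Marker(f"m{i}", "chr1", int(pos[i]), float(cm[i]) if with_cm else None)
            for i in range(n_markers)
        ]
        calls = rng.choice([P1, P2, MISSING], size=(n_markers, n_iso)).astype(np.int8)
        isolates = [f"s{i}" for i in range(n_iso)]
        m = GenotypeMatrix(markers, isolates, calls, genome=[ChromosomeDef("chr1", 50_000)])
        p = tmp_path / "rt.tsv"
        write_genotype_table(m, p)
        back = read_genotype_table(p, m.genome)
        assert back.isolates == m.isolates
        assert [x.id for x in back.markers] == [x.id for x in m.markers]
        assert (back.calls == m.calls).all()
        if with_cm:
            np.testing.assert_allclose(
                [x.pos_cM for x in back.markers], [x.pos_cM for x in m.markers]
            )


class TestMatrixInvariants:
    def test_interleaved_chromosomes_rejected(self):
        markers = [
            Marker("a", "chr1", 10),
            Marker("b", "chr2", 10),
            Marker("c", "chr1", 20),
        ]
        with pytest.raises(GenotypeError, match="interleaved"):
            GenotypeMatrix(markers, ["i"], np.zeros((3, 1), dtype=np.int8))

    def test_position_beyond_chromosome_rejected(self):
        with pytest.raises(GenotypeError, match="outside"):
            GenotypeMatrix(
                [Marker("a", "chr1", 200)],
                ["i"],
                np.zeros((1, 1), dtype=np.int8),
                genome=[ChromosomeDef("chr1", 100)],
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(GenotypeError, match="shape"):
            GenotypeMatrix([Marker("a", "chr1", 10)], ["i", "j"], np.zeros((1, 1), dtype=np.int8))


class TestEventsBed:
    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "e.bed"
        write_events_bed([CrossoverEvent("iso1", "chr1", 100, 200)], p)
        lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert lines == ["chr1\t99\t200\tiso1"]

    def test_empty_event_list_header_only(self, tmp_path):
        p = tmp_path / "e.bed"
        write_events_bed([], p)
        text = p.read_text()
        assert text.startswith("#")
        assert len(text.splitlines()) == 1

    def test_sorted_output_and_round_trip(self, tmp_path):
        events = [
            CrossoverEvent("i2", "chr2", 500, 600),
            CrossoverEvent("i1", "chr1", 900, 950),
            CrossoverEvent("i3", "chr1", 100, 300),
        ]
        p = tmp_path / "e.bed"
        write_events_bed(events, p)
        back = read_events_bed(p)
        assert [(e.chromosome, e.left_bp) for e in back] == [
            ("chr1", 100),
            ("chr1", 900),
            ("chr2", 500),
        ]
        assert {(e.isolate, e.left_bp, e.right_bp) for e in back} == {
            (e.isolate, e.left_bp, e.right_bp) for e in events
        }

    def test_mid_bp_floor(self):
        assert CrossoverEvent("i", "chr1", 100, 201).mid_bp == 150


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=50000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tp1\tp2\ts1\ts2\ts3
"""


def _vcf_line(pos, gts, ref="A", alt="T", chrom="chr1"):
    return f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"


class TestVcfImport:
    def test_progeny_calls_phased_by_parentage(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            VCF_HEADER
            + _vcf_line(100, ["0/0", "1/1", "1/1", "0/0", "./."])
            + _vcf_line(200, ["0/0", "0/0", "0/0", "0/0", "0/0"])  # parents equal: dropped
            + _vcf_line(300, ["1/1", "0/0", "0/0", "1/1", "0/1"])  # P1 allele is 1 here
        )
        m = read_vcf_phased(p, "p1", "p2")
        assert m.isolates == ["s1", "s2", "s3"]
        assert m.n_markers == 2
        # site 100: s1 matches parent2, s2 matches parent1, s3 missing
        assert list(m.calls[0]) == [P2, P1, MISSING]
        # site 300: s1 carries 0 (= parent2 allele), s2 carries 1 (= parent1), s3 het
        assert list(m.calls[1]) == [P2, P1, MISSING]

    def test_uninformative_sites_filtered(self, tmp_path):
        # 10 sites, 4 informative (parents fixed for different alleles)
        lines = []
        for i in range(10):
            pos = 100 * (i + 1)
            if i % 3 == 0 and i < 10:  # i = 0,3,6,9 -> 4 informative sites
                lines.append(_vcf_line(pos, ["0/0", "1/1", "0/0", "1/1", "0/0"]))
            else:
                lines.append(_vcf_line(pos, ["0/0", "0/0", "0/0", "0/0", "0/0"]))
        p = tmp_path / "v.vcf"
        p.write_text(VCF_HEADER + "".join(lines))
        m = read_vcf_phased(p, "p1", "p2")
        assert m.n_markers == 4

    def test_all_progeny_matching_parent1_gives_all_p1_column(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(VCF_HEADER + _vcf_line(100, ["0/0", "1/1", "0/0", "0/0", "0/0"]))
        m = read_vcf_phased(p, "p1", "p2")
        assert (m.calls[0] == P1).all()

    def test_missing_parent_sample_errors(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(VCF_HEADER + _vcf_line(100, ["0/0", "1/1", "0/0", "0/0", "0/0"]))
        with pytest.raises(GenotypeError, match="nope"):
            read_vcf_phased(p, "nope", "p2")
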