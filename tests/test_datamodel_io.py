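import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleogen.datamodel_io import (
    MISSING,
    FrequencyPanel,
    GenotypePanel,
    Individual,
    SNPRecord,
    apply_region_mask,
    assign_blocks,
    read_bed,
    read_eigenstrat,
    read_frequency_table,
    read_genotypes,
    read_pileup,
    read_vcf,
    write_eigenstrat,
    write_frequency_table,
    write_genotypes,
    write_pileup,
    write_vcf,
)
from paleogen.datamodel_io.types import PileupSite
from paleogen.errors import (
    DimensionMismatchError,
    DuplicateSNPError,
    FormatError,
    ValidationError,
)

from conftest import make_snp, random_panel


class TestSNPRecord:
    def test_transition_definition(self):
        assert make_snp(ref="C", alt="T").is_transition
        assert make_snp(ref="T", alt="C").is_transition
        assert make_snp(ref="G", alt="A").is_transition
        assert not make_snp(ref="A", alt="C").is_transition
        assert not make_snp(ref="A", alt="T").is_transition

    def test_invariants(self):
        with pytest.raises(ValidationError):
            make_snp(ref="C", alt="C")
        with pytest.raises(ValidationError):
            make_snp(pos=0)
        with pytest.raises(ValidationError):
            make_snp(ref="X")


class TestGenotypePanel:
    def test_shape_mismatch(self, small_panel):
        with pytest.raises(ValidationError):
            GenotypePanel(small_panel.snps, small_panel.individuals,
                          np.zeros((2, 4), dtype=np.int8))

    def test_haploid_cannot_carry_two(self, small_panel):
        g = small_panel.genotypes.copy()
        g[2, 0] = 2  # anc1 is haploid
        with pytest.raises(ValidationError):
            GenotypePanel(small_panel.snps, small_panel.individuals, g)

    def test_duplicate_snp_ids(self, small_panel):
        snps = [small_panel.snps[0]] * 4
        with pytest.raises(DuplicateSNPError):
            GenotypePanel(snps, small_panel.individuals, small_panel.genotypes)


class TestEigenstrat:
    def test_roundtrip_identity(self, small_panel, tmp_path):
        write_eigenstrat(small_panel, tmp_path / "p")
        assert read_eigenstrat(tmp_path / "p") == small_panel

    def test_roundtrip_random_100_snps(self, tmp_path):
        panel = random_panel(np.random.default_rng(42), n_ind=5, n_snp=100,
                             haploid_rows={1})
        write_eigenstrat(panel, tmp_path / "r")
        back = read_eigenstrat(tmp_path / "r")
        assert back == panel
        np.testing.assert_array_equal(back.genotypes, panel.genotypes)

    def test_dimension_mismatch(self, small_panel, tmp_path):
        write_eigenstrat(small_panel, tmp_path / "p")
        # truncate .ind to 2 rows while .geno has 3 columns
        lines = (tmp_path / "p.ind").read_text().splitlines()[:2]
        (tmp_path / "p.ind").write_text("\n".join(lines) + "\n")
        (tmp_path / "p.meta.tsv").unlink()
        with pytest.raises(DimensionMismatchError):
            read_eigenstrat(tmp_path / "p")

    def test_haploid_encoding(self, small_panel, tmp_path):
        write_eigenstrat(small_panel, tmp_path / "p")
        rows = (tmp_path / "p.geno").read_text().splitlines()
        haploid_chars = {row[2] for row in rows}  # anc1 is the third column
        assert haploid_chars <= {"0", "1", "9"}

    def test_empty_panel(self, tmp_path):
        panel = GenotypePanel([], [Individual("a", "P")],
                              np.empty((1, 0), dtype=np.int8))
        write_eigenstrat(panel, tmp_path / "e")
        back = read_eigenstrat(tmp_path / "e")
        assert back.n_snps == 0 and back.n_individuals == 1

    def test_byte_stable(self, small_panel, tmp_path):
        write_eigenstrat(small_panel, tmp_path / "a")
        write_eigenstrat(read_eigenstrat(tmp_path / "a"), tmp_path / "b")
        for ext in (".geno", ".snp", ".ind", ".meta.tsv"):
            assert (tmp_path / f"a{ext}").read_bytes() == \
                   (tmp_path / f"b{ext}").read_bytes()

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), n_ind=st.integers(1, 6),
           n_snp=st.integers(0, 30))
    def test_roundtrip_property(self, seed, n_ind, n_snp, tmp_path_factory):
        panel = random_panel(np.random.default_rng(seed), n_ind, n_snp,
                             haploid_rows={0})
        d = tmp_path_factory.mktemp("es")
        write_eigenstrat(panel, d / "x")
        assert read_eigenstrat(d / "x") == panel


class TestVCF:
    def test_roundtrip_identity(self, small_panel, tmp_path):
        write_vcf(small_panel, tmp_path / "p.vcf")
        assert read_vcf(tmp_path / "p.vcf") == small_panel

    def test_missing_gt_convention(self, small_panel, tmp_path):
        write_vcf(small_panel, tmp_path / "p.vcf")
        text = (tmp_path / "p.vcf").read_text()
        assert "./." in text  # mod1 at snp3
        back = read_vcf(tmp_path / "p.vcf")
        assert back.genotypes[0, 3] == MISSING

    def test_multiallelic_skipped(self, small_panel, tmp_path):
        write_vcf(small_panel, tmp_path / "p.vcf")
        lines = (tmp_path / "p.vcf").read_text().splitlines()
        extra = lines[-1].split("\t")
        extra[1], extra[2], extra[4] = "999", "multi", "A,G"
        lines.append("\t".join(extra))
        (tmp_path / "m.vcf").write_text("\n".join(lines) + "\n")
        back = read_vcf(tmp_path / "m.vcf")
        assert back.n_snps == small_panel.n_snps

    def test_dispatch(self, small_panel, tmp_path):
        write_genotypes(small_panel, tmp_path / "x.vcf", format="vcf")
        assert read_genotypes(tmp_path / "x.vcf", format="vcf") == small_panel
        write_genotypes(small_panel, tmp_path / "es", format="eigenstrat")
        assert read_genotypes(tmp_path / "es", format="eigenstrat") == small_panel


class TestFrequencyTable:
    def _panel(self):
        snps = [make_snp(0, anc="C"), make_snp(1, ref="G", alt="A", anc="A")]
        return FrequencyPanel(snps, ["POP1", "POP2"],
                              np.array([[5, 3], [0, 10]]),
                              np.array([[10, 6], [4, 10]]))

    def test_simple_frequency(self, tmp_path):
        panel = self._panel()
        write_frequency_table(panel, tmp_path / "f.tsv")
        back = read_frequency_table(tmp_path / "f.tsv")
        assert back == panel
        assert back.freq("POP1")[0] == pytest.approx(0.5)

    def test_derived_exceeds_total(self):
        snps = [make_snp(0)]
        with pytest.raises(ValidationError, match="snp0"):
            FrequencyPanel(snps, ["P"], np.array([[11]]), np.array([[10]]))

    def test_roundtrip_byte_stable(self, tmp_path):
        panel = self._panel()
        write_frequency_table(panel, tmp_path / "a.tsv")
        write_frequency_table(read_frequency_table(tmp_path / "a.tsv"),
                              tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_missing_columns(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("snp\tchrom\n1\t2\n")
        with pytest.raises(FormatError):
            read_frequency_table(tmp_path / "bad.tsv")


class TestBlocks:
    def test_same_window_same_block(self):
        snps = [make_snp(0, pos=1), make_snp(1, pos=4_999_999)]
        bp = assign_blocks(snps, window=5_000_000)
        assert bp.block_of[0] == bp.block_of[1]

    def test_next_window_next_block(self):
        snps = [make_snp(0, pos=1), make_snp(1, pos=5_000_001)]
        bp = assign_blocks(snps, window=5_000_000)
        assert bp.block_of[1] == bp.block_of[0] + 1

    def test_chromosomes_never_share(self):
        snps = [make_snp(0, chrom="1", pos=100), make_snp(1, chrom="2", pos=100)]
        bp = assign_blocks(snps)
        assert bp.block_of[0] != bp.block_of[1]

    def test_unsorted_raises(self):
        snps = [make_snp(0, pos=200), make_snp(1, pos=100)]
        with pytest.raises(ValidationError):
            assign_blocks(snps)
        snps = [make_snp(0, chrom="1"), make_snp(1, chrom="2"),
                make_snp(2, chrom="1", pos=999)]
        with pytest.raises(ValidationError):
            assign_blocks(snps)

    def test_block_count_occupied_windows(self):
        # density inside a window is irrelevant; count = occupied windows
        snps = ([make_snp(i, pos=10 + i) for i in range(50)]
                + [make_snp(99, pos=12_000_000)])
        bp = assign_blocks(snps, window=5_000_000)
        assert bp.n_blocks == 2


class TestRegionMask:
    def test_keep_all_is_identity(self, small_panel):
        ivs = {"1": [(0, 10**9)], "2": [(0, 10**9)]}
        assert apply_region_mask(small_panel, ivs, "keep") == small_panel

    def test_drop_all_gives_empty(self, small_panel):
        ivs = {"1": [(0, 10**9)], "2": [(0, 10**9)]}
        assert apply_region_mask(small_panel, ivs, "drop").n_snps == 0

    def test_bed_off_by_one(self, small_panel):
        # SNP at 1-based position 100 <-> BED interval (99, 100)
        assert apply_region_mask(small_panel, {"1": [(99, 100)]}, "keep").n_snps == 1
        assert apply_region_mask(small_panel, {"1": [(100, 101)]}, "keep").n_snps == 0

    def test_keep_drop_partition(self, small_panel):
        ivs = {"1": [(0, 250)]}
        kept = apply_region_mask(small_panel, ivs, "keep")
        dropped = apply_region_mask(small_panel, ivs, "drop")
        assert kept.n_snps + dropped.n_snps == small_panel.n_snps
        ids = {s.id for s in kept.snps} | {s.id for s in dropped.snps}
        assert ids == {s.id for s in small_panel.snps}

    def test_malformed_interval(self, small_panel):
        with pytest.raises(ValidationError):
            apply_region_mask(small_panel, {"1": [(100, 100)]}, "keep")

    def test_read_bed(self, tmp_path):
        (tmp_path / "m.bed").write_text("1\t0\t100\n1\t200\t300\nX\t5\t6\n")
        ivs = read_bed(tmp_path / "m.bed")
        assert ivs == {"1": [(0, 100), (200, 300)], "X": [(5, 6)]}
        (tmp_path / "bad.bed").write_text("1\t300\t200\n")
        with pytest.raises(ValidationError):
            read_bed(tmp_path / "bad.bed")


class TestPileupIO:
    def test_roundtrip(self, tmp_path):
        sites = [
            PileupSite("1", 10, "C", [("C", 37, 60), ("T", 20, 60)]),
            PileupSite("1", 20, "G", [], gap_distance=3, in_repeat=True),
        ]
        write_pileup(sites, tmp_path / "p.txt")
        back = list(read_pileup(tmp_path / "p.txt"))
        assert back == sites

    def test_samtools_markers(self, tmp_path):
        (tmp_path / "s.txt").write_text("1\t5\tC\t3\t^I.,T\tIII\tIII\n")
        [site] = read_pileup(tmp_path / "s.txt")
        assert [b for b, _, _ in site.reads] == ["C", "C", "T"]
        assert site.reads[0][1] == ord("I") - 33

    def test_depth_mismatch(self, tmp_path):
        (tmp_path / "bad.txt").write_text("1\t5\tC\t2\t.\tI\tI\n")
        with pytest.raises(FormatError):
            list(read_pileup(tmp_path / "bad.txt"))
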