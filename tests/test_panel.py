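"""Panel/genotype I/O and marker harmonization."""

import numpy as np
import pytest

from paleoproj.panel import (
    DIPLOID,
    PSEUDO_HAPLOID,
    AlignmentError,
    FrequencyPanel,
    GenotypeMatrix,
    Marker,
    PanelParseError,
    align_genotypes_to_panel,
    complement_dosage,
    read_frequency_panel,
    read_genotypes_vcf,
    write_vcf,
)
from paleoproj.projection import ProjectionOptions, project_individual
from paleoproj.simulate import SimulationConfig, simulate_individuals, simulate_panel


def _write_panel_tsv(path, rows, ancestries=("a1", "a2")):
    header = "id\tchrom\tpos\tcounted_allele\tother_allele\t" + "\t".join(ancestries)
    path.write_text("\n".join([header] + rows) + "\n")


class TestMarker:
    def test_valid_marker(self):
        m = Marker("rs1", "1", 100, "A", "G")
        assert not m.is_strand_ambiguous

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(pos=0),
            dict(counted_allele="A", other_allele="A"),
            dict(counted_allele="N"),
            dict(other_allele="AT"),
        ],
    )
    def test_invalid_markers_rejected(self, kwargs):
        base = dict(id="rs1", chrom="1", pos=100, counted_allele="A", other_allele="G")
        base.update(kwargs)
        with pytest.raises(ValueError):
            Marker(**base)

    @pytest.mark.parametrize("pair,expected", [
        (("A", "T"), True), (("C", "G"), True), (("A", "G"), False), (("C", "T"), False),
    ])
    def test_strand_ambiguity(self, pair, expected):
        assert Marker("m", "1", 1, *pair).is_strand_ambiguous is expected


class TestReadFrequencyPanel:
    def test_two_marker_two_ancestry_file(self, tmp_path):
        path = tmp_path / "panel.tsv"
        _write_panel_tsv(path, [
            "m1\t1\t100\tA\tG\t0.25\t0.75",
            "m2\t1\t200\tC\tT\t0.10\t0.90",
        ])
        panel = read_frequency_panel(path)
        assert panel.n_ancestries == 2 and panel.n_markers == 2
        assert panel.ancestries == ["a1", "a2"]
        np.testing.assert_allclose(panel.freqs, [[0.25, 0.10], [0.75, 0.90]])

    def test_out_of_range_frequency_names_line(self, tmp_path):
        path = tmp_path / "panel.tsv"
        _write_panel_tsv(path, [
            "m1\t1\t100\tA\tG\t0.25\t0.75",
            "m2\t1\t200\tC\tT\t1.30\t0.90",
        ])
        with pytest.raises(PanelParseError, match="line 3"):
            read_frequency_panel(path)

    def test_duplicate_marker_id_rejected(self, tmp_path):
        path = tmp_path / "panel.tsv"
        _write_panel_tsv(path, [
            "m1\t1\t100\tA\tG\t0.2\t0.7",
            "m1\t1\t200\tC\tT\t0.1\t0.9",
        ])
        with pytest.raises(PanelParseError, match="duplicate"):
            read_frequency_panel(path)

    def test_round_trip_simulated_panel(self, tmp_path):
        panel = simulate_panel(K=21, M=1000, fst=0.1, seed=7)
        path = tmp_path / "panel.tsv"
        panel.to_tsv(path)
        back = read_frequency_panel(path)
        assert back.ancestries == panel.ancestries
        assert [m.id for m in back.markers] == [m.id for m in panel.markers]
        np.testing.assert_allclose(back.freqs, panel.freqs, atol=5e-7)


class TestReadGenotypesVcf:
    def _vcf(self, tmp_path, body, samples=("S1",)):
        path = tmp_path / "g.vcf"
        header = (
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        path.write_text(header + body)
        return path

    def test_het_call_gives_dosage_one(self, tmp_path):
        gm = read_genotypes_vcf(self._vcf(tmp_path, "1\t100\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\n"))
        assert gm.dosages[0, 0] == 1.0
        assert gm.ploidy == [DIPLOID]

    def test_missing_call_gives_nan(self, tmp_path):
        gm = read_genotypes_vcf(self._vcf(tmp_path, "1\t100\t.\tG\tA\t.\tPASS\t.\tGT\t./.\n"))
        assert np.isnan(gm.dosages[0, 0])

    def test_haploid_calls_flag_pseudo_haploid(self, tmp_path):
        body = "1\t100\t.\tG\tA\t.\tPASS\t.\tGT\t1\t0/1\n1\t200\t.\tT\tC\t.\tPASS\t.\tGT\t0\t1/1\n"
        gm = read_genotypes_vcf(self._vcf(tmp_path, body, samples=("PH", "DP")))
        assert gm.ploidy == [PSEUDO_HAPLOID, DIPLOID]
        np.testing.assert_array_equal(gm.dosages[0], [2.0, 0.0])

    def test_multiallelic_skipped_with_warning(self, tmp_path):
        body = ("1\t100\t.\tG\tA,T\t.\tPASS\t.\tGT\t1/2\n"
                "1\t200\t.\tT\tC\t.\tPASS\t.\tGT\t1/1\n")
        with pytest.warns(UserWarning, match="multi-allelic"):
            gm = read_genotypes_vcf(self._vcf(tmp_path, body))
        assert gm.n_markers == 1

    def test_round_trip_against_simulator_truth(self, tmp_path):
        panel = simulate_panel(K=2, M=5, fst=0.2, seed=3)
        cfg = SimulationConfig(K=2, M=5, fst=0.2, n_individuals=3,
                               dirichlet_alpha=1.0, missing_rate=0.2, seed=4)
        truth = simulate_individuals(panel, cfg)
        path = tmp_path / "sim.vcf"
        write_vcf(truth.genotypes, path)
        back = read_genotypes_vcf(path)
        assert back.individuals == truth.genotypes.individuals
        np.testing.assert_array_equal(back.dosages, truth.genotypes.dosages)


class TestAlignment:
    def test_matching_alleles_keep_dosage(self, tiny_panel, tiny_genotypes):
        aligned = align_genotypes_to_panel(tiny_genotypes, tiny_panel)
        assert aligned.alignment_report["kept"] == 4
        np.testing.assert_array_equal(
            aligned.genotypes.dosages, tiny_genotypes.dosages
        )

    def test_swapped_alleles_complement_dosage(self, tiny_panel):
        swapped = [
            Marker("m1", "1", 100, "G", "A"),  # REF=counted, ALT=other
            Marker("m2", "1", 200, "C", "T"),
        ]
        gm = GenotypeMatrix(["i"], swapped, np.array([[2.0, 1.0]]))
        aligned = align_genotypes_to_panel(gm, tiny_panel)
        assert aligned.alignment_report == {
            "kept": 1, "swapped": 1, "ambiguous_dropped": 0, "mismatch_dropped": 0,
        }
        # swapped marker m1: dosage 2 -> 0; m2 untouched
        np.testing.assert_array_equal(aligned.genotypes.dosages, [[0.0, 1.0]])

    def test_ambiguous_and_mismatch_dropped(self, tiny_panel):
        markers = [
            Marker("m1", "1", 100, "A", "T"),  # strand-ambiguous pair
            Marker("m2", "1", 200, "C", "A"),  # allele-set mismatch
            Marker("m3", "2", 50, "G", "A"),   # clean
        ]
        gm = GenotypeMatrix(["i"], markers, np.array([[2.0, 2.0, 1.0]]))
        aligned = align_genotypes_to_panel(gm, tiny_panel)
        assert aligned.alignment_report == {
            "kept": 1, "swapped": 0, "ambiguous_dropped": 1, "mismatch_dropped": 1,
        }
        assert aligned.panel.markers[0].id == "m3"

    def test_report_sums_to_intersection(self, tiny_panel, tiny_genotypes):
        aligned = align_genotypes_to_panel(tiny_genotypes, tiny_panel)
        assert sum(aligned.alignment_report.values()) == 4

    def test_empty_intersection_errors(self, tiny_panel):
        gm = GenotypeMatrix(["i"], [Marker("x", "9", 999, "A", "G")], np.array([[1.0]]))
        with pytest.raises(AlignmentError, match="marker set"):
            align_genotypes_to_panel(gm, tiny_panel)

    def test_alignment_idempotent(self, tiny_panel, tiny_genotypes):
        once = align_genotypes_to_panel(tiny_genotypes, tiny_panel)
        twice = align_genotypes_to_panel(once.genotypes, once.panel)
        np.testing.assert_array_equal(once.genotypes.dosages, twice.genotypes.dosages)
        assert twice.alignment_report["swapped"] == 0
        assert twice.alignment_report["kept"] == once.panel.n_markers

    def test_complement_twice_is_identity(self):
        d = np.array([0.0, 1.0, 2.0, np.nan])
        np.testing.assert_array_equal(complement_dosage(complement_dosage(d)), d)

    def test_allele_swapped_vcf_gives_identical_estimates(self, tmp_path):
        """Writing 10% of markers with swapped REF/ALT must not change q."""
        panel = simulate_panel(K=3, M=2000, fst=0.15, seed=11)
        cfg = SimulationConfig(K=3, M=2000, fst=0.15, n_individuals=2,
                               dirichlet_alpha=5.0, seed=12)
        truth = simulate_individuals(panel, cfg)
        swap = {m.id for j, m in enumerate(panel.markers) if j % 10 == 0}
        plain, flipped = tmp_path / "plain.vcf", tmp_path / "flipped.vcf"
        write_vcf(truth.genotypes, plain)
        write_vcf(truth.genotypes, flipped, swap_markers=swap)
        qs = []
        for path in (plain, flipped):
            aligned = align_genotypes_to_panel(read_genotypes_vcf(path), panel)
            est = project_individual(
                aligned.genotypes.dosages[0], aligned.panel.freqs,
                aligned.genotypes.ploidy[0], ProjectionOptions(),
            )
            qs.append(est.q)
        np.testing.assert_allclose(qs[0], qs[1], atol=1e-12)


class TestGenotypeMatrixInvariants:
    def test_pseudo_haploid_heterozygote_rejected(self, tiny_panel):
        with pytest.raises(ValueError, match="heterozygous"):
            GenotypeMatrix(
                ["i"], list(tiny_panel.markers),
                np.array([[1.0, 0.0, 2.0, 2.0]]), ploidy=[PSEUDO_HAPLOID],
            )

    def test_dosage_range_enforced(self, tiny_panel):
        with pytest.raises(ValueError, match="dosages"):
            GenotypeMatrix(["i"], list(tiny_panel.markers), np.array([[3.0, 0, 0, 0]]))
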