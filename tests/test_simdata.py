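"""Generator determinism, planted-variant truth and mask geometry."""

import numpy as np
import pytest
from scipy import stats

from peff import kmers, simdata


class TestReference:
    def test_fixed_seed_is_byte_identical(self, tmp_path):
        for sub in ("a", "b"):
            ref = simdata.generate_reference(1, 5_000, 3, 400, seed=1)
            (tmp_path / sub).mkdir()
            ref.write_fasta(tmp_path / sub / "ref.fa")
            ref.write_gff3(tmp_path / sub / "ref.gff3")
        assert (tmp_path / "a/ref.fa").read_bytes() == (tmp_path / "b/ref.fa").read_bytes()
        assert (tmp_path / "a/ref.gff3").read_bytes() == (tmp_path / "b/ref.gff3").read_bytes()

    def test_construction_guarantees(self):
        ref = simdata.generate_reference(1, 100_000, 10, 2_000, seed=1)
        assert len(ref.contigs) == 1 and len(ref.contigs[0][1]) == 100_000
        genes = ref.genes.sort_values("start")
        assert len(genes) == 10
        assert (genes["end"] - genes["start"] + 1 == 2_000).all()
        starts = genes["start"].to_numpy()
        ends = genes["end"].to_numpy()
        assert (starts[1:] > ends[:-1]).all()  # non-overlapping

    def test_infeasible_gene_packing_errors(self):
        with pytest.raises(ValueError, match="pack"):
            simdata.generate_reference(1, 1_000, 2, 600, seed=0)


class TestPopulation:
    def test_frequency_one_means_every_accession_carries(self, tiny_reference):
        locus = simdata.CausalLocus("contig1", 5_000, 40, 1.0, 0.0)
        spec = simdata.PopulationSpec(15, [locus], seed=3)
        pop = simdata.simulate_population(tiny_reference, spec)
        assert pop.truth.iloc[:, 0].sum() == 15

    def test_carriage_count_within_binomial_interval(self, tiny_reference):
        locus = simdata.CausalLocus("contig1", 5_000, 40, 0.5, 0.0)
        spec = simdata.PopulationSpec(200, [locus], seed=5)
        pop = simdata.simulate_population(tiny_reference, spec)
        lo = stats.binom.ppf(0.0005, 200, 0.5)
        hi = stats.binom.ppf(0.9995, 200, 0.5)
        assert lo <= pop.truth.iloc[:, 0].sum() <= hi

    def test_no_variation_reproduces_reference(self, tiny_reference):
        spec = simdata.PopulationSpec(3, [], snp_rate=0.0, seed=1)
        pop = simdata.simulate_population(tiny_reference, spec)
        for acc in pop.accessions:
            assert pop.sequences(acc)["contig1"] == tiny_reference.sequence("contig1")

    def test_overlapping_loci_error(self, tiny_reference):
        loci = [
            simdata.CausalLocus("contig1", 5_000, 60, 0.5, 0.0),
            simdata.CausalLocus("contig1", 5_030, 60, 0.5, 0.0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            simdata.simulate_population(
                tiny_reference, simdata.PopulationSpec(5, loci, seed=1)
            )

    def test_noncarriers_lack_the_segment(self, tiny_reference, tiny_population):
        locus = tiny_population.spec.causal_loci[0]
        ref_len = len(tiny_reference.sequence("contig1"))
        for acc in tiny_population.accessions:
            carried = bool(tiny_population.truth.loc[acc, "causal"])
            length = tiny_population.haplotype_length(acc)
            assert length == (ref_len if carried else ref_len - locus.length)


class TestReads:
    def test_zero_error_reads_are_haplotype_substrings(self, tiny_population):
        params = simdata.ReadSimParams(read_length=80, coverage=1.0,
                                       error_rate=0.0, seed=9)
        acc = tiny_population.accessions[0]
        rs = simdata.simulate_reads_for_accession(
            tiny_population, acc, params, np.random.default_rng(1)
        )
        hap = tiny_population.sequences(acc)["contig1"]
        for seq in rs.sequences()[:50]:
            assert seq in hap or kmers.reverse_complement(seq) in hap

    def test_read_count_matches_coverage_formula(self, tiny_population):
        params = simdata.ReadSimParams(read_length=100, coverage=30.0,
                                       error_rate=0.0, seed=2)
        acc = tiny_population.accessions[0]
        rs = simdata.simulate_reads_for_accession(
            tiny_population, acc, params, np.random.default_rng(0)
        )
        expected = 30.0 * tiny_population.haplotype_length(acc) / 100
        assert len(rs) == round(expected)

    def test_error_rate_recovers_within_binomial_tolerance(self, tiny_population):
        err = 0.01
        params = simdata.ReadSimParams(read_length=100, coverage=2.0,
                                       error_rate=err, seed=3)
        acc = tiny_population.accessions[0]
        rng = np.random.default_rng(12)
        clean = simdata.simulate_reads_for_accession(
            tiny_population, acc,
            simdata.ReadSimParams(read_length=100, coverage=2.0,
                                  error_rate=0.0, seed=3),
            np.random.default_rng(12),
        )
        noisy = simdata.simulate_reads_for_accession(
            tiny_population, acc, params, np.random.default_rng(12)
        )
        frac = np.mean(clean.codes != noisy.codes)
        n = clean.codes.size
        # substitutions re-draw to a different base always
        assert abs(frac - err) < 4 * np.sqrt(err * (1 - err) / n)

    def test_mean_kmer_depth_tracks_requested_coverage(self, tiny_population):
        cov = 20.0
        k, L = 31, 100
        params = simdata.ReadSimParams(read_length=L, coverage=cov,
                                       error_rate=0.0, seed=4)
        acc = tiny_population.accessions[0]
        rs = simdata.simulate_reads_for_accession(
            tiny_population, acc, params, np.random.default_rng(7)
        )
        counts = kmers.count_sample_kmers(rs, k=k, min_count=1)
        lam = cov * (L - k + 1) / L  # expected per-k-mer depth
        assert abs(np.mean(counts.total) - lam) / lam < 0.05

    def test_fixed_seed_reads_are_identical(self, tiny_population):
        params = simdata.ReadSimParams(read_length=60, coverage=2.0,
                                       error_rate=0.01, seed=5)
        a = dict(simdata.iter_gbs_reads(tiny_population, params))
        b = dict(simdata.iter_gbs_reads(tiny_population, params))
        for acc in a:
            np.testing.assert_array_equal(a[acc].codes, b[acc].codes)


class TestPhenotypes:
    def test_noise_free_effect_is_exact_group_difference(self, tiny_population):
        params = simdata.PhenoSimParams(
            mu=10.0, betas=(2.0,), sigma_g2=0.0, sigma_e2=0.0,
            treatment_effect=0.0, n_replicates=1, seed=0,
        )
        table = simdata.simulate_phenotypes(
            tiny_population.truth, np.eye(10), params
        )
        merged = table.merge(
            tiny_population.truth.reset_index(), on="accession"
        )
        carriers = merged.loc[merged["causal"] == 1, "value"]
        others = merged.loc[merged["causal"] == 0, "value"]
        assert carriers.nunique() == 1 and others.nunique() == 1
        assert carriers.iloc[0] - others.iloc[0] == pytest.approx(2.0)

    def test_variance_decomposition_at_large_n(self):
        n, reps = 2_000, 3
        truth = __import__("pandas").DataFrame(index=[f"a{i}" for i in range(n)])
        params = simdata.PhenoSimParams(
            mu=0.0, betas=(), sigma_g2=1.0, sigma_e2=1.0,
            treatment_effect=0.0, n_replicates=reps, seed=21,
            treatments=("HP",),
        )
        table = simdata.simulate_phenotypes(truth, np.eye(n), params)
        means = table.groupby("accession")["value"].mean()
        expected = 1.0 + 1.0 / reps
        assert abs(means.var() - expected) / expected < 0.1

    def test_treatment_effect_shifts_lp_mean(self, tiny_population):
        params = simdata.PhenoSimParams(
            mu=5.0, betas=(0.0,), sigma_g2=0.0, sigma_e2=0.05,
            treatment_effect=-1.0, n_replicates=200, seed=2,
        )
        table = simdata.simulate_phenotypes(
            tiny_population.truth, np.eye(10), params
        )
        by_t = table.groupby("treatment")["value"].mean()
        assert by_t["LP"] - by_t["HP"] == pytest.approx(-1.0, abs=0.05)

    def test_non_psd_kinship_rejected(self, tiny_population):
        K = np.eye(10)
        K[0, 1] = K[1, 0] = 2.0  # indefinite
        with pytest.raises(ValueError, match="semi-definite"):
            simdata.simulate_phenotypes(
                tiny_population.truth, K,
                simdata.PhenoSimParams(betas=(0.0,), seed=0),
            )


class TestRootMasks:
    def test_vertical_600px_segment_is_one_inch(self):
        mask, truth = simdata.render_root_mask(
            [(50.0, 20.0, 50.0, 620.0, 5.0)], shape=(700, 100), dpi=600
        )
        assert truth.length_mm == pytest.approx(25.4)
        assert mask.any()

    def test_collinear_touching_segments_add_lengths(self):
        _, one = simdata.render_root_mask(
            [(10.0, 50.0, 610.0, 50.0, 5.0)], shape=(100, 700), dpi=600
        )
        _, two = simdata.render_root_mask(
            [(10.0, 50.0, 310.0, 50.0, 5.0), (310.0, 50.0, 610.0, 50.0, 5.0)],
            shape=(100, 700), dpi=600,
        )
        assert two.length_mm == pytest.approx(one.length_mm)

    def test_l_shape_hull_matches_triangle_closed_form(self):
        w = 5.0
        _, truth = simdata.render_root_mask(
            [(20.0, 20.0, 20.0, 320.0, w), (20.0, 320.0, 320.0, 320.0, w)],
            shape=(400, 400), dpi=600,
        )
        s = 25.4 / 600
        triangle_px = 0.5 * 300 * 300
        r = w / 2
        # Minkowski expansion of the endpoint triangle by the stroke radius
        perimeter_px = 300 + 300 + 300 * np.sqrt(2)
        expected_px = triangle_px + perimeter_px * r + np.pi * r * r
        assert truth.hull_area_mm2 == pytest.approx(expected_px * s * s, rel=0.01)

    def test_foreground_count_within_2pct_of_analytic_area(self):
        for segs, shape in [
            ([(30.0, 30.0, 30.0, 530.0, 7.0)], (600, 100)),
            ([(30.0, 40.0, 430.0, 440.0, 5.0)], (500, 500)),
        ]:
            mask, truth = simdata.render_root_mask(segs, shape, dpi=600)
            s = 25.4 / 600
            assert mask.sum() * s * s == pytest.approx(truth.area_mm2, rel=0.02)

    def test_zero_width_segment_rejected(self):
        with pytest.raises(ValueError, match="width"):
            simdata.render_root_mask([(5, 5, 50, 50, 0.0)], (100, 100), dpi=600)

    def test_out_of_canvas_segment_rejected(self):
        with pytest.raises(ValueError, match="canvas"):
            simdata.render_root_mask([(5, 5, 200, 5, 4.0)], (100, 100), dpi=600)
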