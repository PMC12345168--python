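"""Generator-level tests: determinism, noise-free identities, ground truth,
and the statistical shape the downstream analyses rely on."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import skew

from ptrkit.errors import ConfigError, UnknownConditionError
from ptrkit.preprocess import aggregate_and_filter
from ptrkit.stats import rank_sum_test
from ptrkit.synthetic import (
    SyntheticConfig,
    SyntheticTruth,
    default_config,
    generate_study,
    truth_rtp,
    write_study,
)

from conftest import build_pairs, noise_free_config


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("n_conditions", 0),
        ("n_conditions", 2.5),
        ("genes_per_condition", -1),
        ("n_replicates", 1),
        ("mrna_sd", -0.1),
        ("ortholog_coverage", 1.5),
        ("essential_sd_scale", 0.0),
        ("essential_noise_scale", 1.2),
        ("outlier_fraction", -0.01),
        ("library_depth", 0),
    ])
    def test_invalid_field_rejected(self, field, value):
        with pytest.raises(ConfigError):
            default_config(**{field: value})

    def test_core_counts_consistency(self):
        with pytest.raises(ConfigError):
            default_config(n_core_all=200, n_core_bacterial=100)

    def test_too_many_essentials_for_private_pool(self):
        with pytest.raises(ConfigError):
            generate_study(default_config(
                genes_per_condition=650, n_orthogroups=600,
                ortholog_coverage=1.0, essential_fraction=0.5))


class TestDeterminism:
    def test_same_seed_identical(self):
        cfg = default_config(seed=99, genes_per_condition=400, n_orthogroups=120,
                             n_core_bacterial=40, n_core_all=20)
        a = generate_study(cfg)
        b = generate_study(cfg)
        for cond in a.condition_ids:
            assert np.array_equal(a.mrna[cond].values, b.mrna[cond].values)
            assert np.array_equal(a.protein[cond].values, b.protein[cond].values)
        assert a.orthomap.groups == b.orthomap.groups
        assert a.essential == b.essential
        assert a.truth.conserved_offset == b.truth.conserved_offset

    def test_different_seed_differs(self):
        cfg = default_config(seed=1, genes_per_condition=400, n_orthogroups=120,
                             n_core_bacterial=40, n_core_all=20)
        cfg2 = dataclasses.replace(cfg, seed=2)
        a, b = generate_study(cfg), generate_study(cfg2)
        assert not np.array_equal(a.mrna["c1"].values, b.mrna["c1"].values)


class TestNoiseFreeLimit:
    def test_ptr_equals_conserved_offset_exactly(self):
        cfg = noise_free_config(5, outlier_fraction=0.0, n_conditions=3,
                                genes_per_condition=600, n_orthogroups=150,
                                n_core_bacterial=50, n_core_all=20)
        study = generate_study(cfg)
        for cond in study.condition_ids:
            mrna, prot = study.mrna[cond], study.protein[cond]
            for g, r_row, p_row in zip(mrna.gene_ids, mrna.values, prot.values):
                og = study.orthomap.group_of(g, cond)
                if og is None:
                    continue
                ptr = np.log2(p_row) - np.log2(r_row)
                c_j = study.truth.conserved_offset[og]
                assert np.allclose(ptr, c_j, atol=1e-9)


class TestDropoutMonotonicity:
    def test_raising_midpoint_reduces_detection(self):
        # oracle: count detections over 20 seed replicates; monotone by construction
        small = dict(n_conditions=2, genes_per_condition=500, n_orthogroups=100,
                     n_core_bacterial=30, n_core_all=10)
        detected_lo, detected_hi = 0, 0
        for seed in range(20):
            lo = generate_study(default_config(seed=seed, **small))
            hi = generate_study(default_config(
                seed=seed, protein_dropout_midpoint=4.5 + 2.0, **small))
            detected_lo += sum((t.values > 0).sum() for t in lo.protein.values())
            detected_hi += sum((t.values > 0).sum() for t in hi.protein.values())
        assert detected_hi < detected_lo


class TestTruthRtp:
    def _truth(self):
        return SyntheticTruth(
            conserved_offset={"OG1": 2.0, "OG2": -1.0},
            condition_deviation={
                "c1": {"OG1": 1.0, "OG2": 0.0},
                "c2": {"OG1": -1.0},
            },
            essential={}, outlier_orthogroups={}, outlier_private={},
            latent_mrna_mean={},
        )

    def test_zero_deviation(self):
        truth = self._truth()
        truth.condition_deviation["c1"]["OG1"] = 0.0
        assert truth_rtp(truth, ["c1"])["OG2"] == pytest.approx(-1.0)

    def test_single_condition(self):
        assert truth_rtp(self._truth(), ["c1"])["OG1"] == pytest.approx(3.0)

    def test_symmetric_deviations_cancel(self):
        assert truth_rtp(self._truth(), ["c1", "c2"])["OG1"] == pytest.approx(2.0)

    def test_partial_coverage_excluded(self):
        # OG2 lacks a deviation in c2 -> not covered by the subset
        assert "OG2" not in truth_rtp(self._truth(), ["c1", "c2"])

    def test_unknown_condition(self):
        with pytest.raises(UnknownConditionError):
            truth_rtp(self._truth(), ["c9"])

    def test_empty_subset(self):
        with pytest.raises(ValueError):
            truth_rtp(self._truth(), [])


class TestStatisticalShape:
    def test_rho_decreases_with_conserved_ptr_sd(self):
        # expectation over seeds: larger conserved offsets decorrelate mRNA/protein
        small = dict(n_conditions=2, genes_per_condition=800, n_orthogroups=100,
                     n_core_bacterial=30, n_core_all=10)
        from ptrkit.correlation import spearman

        def mean_rho(conserved):
            vals = []
            for seed in range(8):
                study = generate_study(default_config(
                    seed=seed, conserved_ptr_sd=conserved,
                    private_ptr_sd=np.hypot(conserved, 0.5), **small))
                for pair in build_pairs(study).values():
                    vals.append(spearman(pair.mrna, pair.protein).rho)
            return np.mean(vals)

        assert mean_rho(2.5) < mean_rho(1.0)

    def test_default_preset_rho_in_band(self, study_default, pairs_default):
        from ptrkit.correlation import spearman
        rhos = [spearman(p.mrna, p.protein).rho for p in pairs_default.values()]
        assert all(0.40 <= r <= 0.65 for r in rhos)

    def test_left_skew_with_sign_bias(self, study_default, pairs_default):
        from ptrkit.outliers import fit_ptr_regression, standardized_residuals
        sks = []
        for pair in pairs_default.values():
            model = fit_ptr_regression(pair)
            recs = standardized_residuals(model, pair)
            sks.append(skew([r.z for r in recs]))
        assert np.median(sks) < 0

    def test_essential_abundance_and_variance(self, study_default, pairs_default):
        pair = pairs_default["c1"]
        ess = study_default.essential["c1"]
        mask = np.array([g in ess for g in pair.gene_ids])
        assert mask.sum() > 100
        p_ab = rank_sum_test(pair.mrna[mask], pair.mrna[~mask], "greater").p_value
        p_sd = rank_sum_test(pair.mrna_sd[mask], pair.mrna_sd[~mask], "less").p_value
        assert p_ab < 0.01 and p_sd < 0.01

    def test_core_coverage_structure(self, study_default):
        omap = study_default.orthomap
        n_all = sum(1 for og in omap.groups if len(omap.coverage(og)) == 9)
        n_bact = sum(1 for og in omap.groups
                     if omap.coverage(og) >= set(f"c{i}" for i in range(1, 9)))
        assert n_all >= 58
        assert n_bact >= 140


class TestWriteStudy:
    def test_files_written_and_readable(self, tmp_path):
        from ptrkit.io_tables import read_abundance_table, read_gene_list, read_orthogroups

        cfg = default_config(seed=3, n_conditions=2, genes_per_condition=300,
                             n_orthogroups=80, n_core_bacterial=30, n_core_all=10)
        study = generate_study(cfg)
        written = write_study(study, tmp_path)
        assert len(written["mrna"]) == 2 and len(written["protein"]) == 2
        t = read_abundance_table(written["mrna"][0], "c1", "mrna")
        assert t.n_genes == 300
        omap = read_orthogroups(written["orthogroups"][0], ["c1", "c2"])
        assert omap.groups == study.orthomap.groups
        ess = read_gene_list(written["essential"][0])
        assert ess == study.essential["c1"]
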