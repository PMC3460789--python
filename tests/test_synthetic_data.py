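"""Tests for the ground-truth generators and fixture writers."""

import numpy as np
import pandas as pd
import pytest

from e3miner.domain_mining import classify_families, filter_hits, parse_domtblout
from e3miner.homology import map_homologs, parse_homologene
from e3miner.synthetic_data import (
    CourseConfig,
    PanelConfig,
    apportion,
    attainable_classes,
    generate_est_voter,
    generate_full_panel,
    generate_stage_course,
    generate_tissue_panel,
    make_e3_homology_example,
    write_domain_fixture,
    write_domtblout,
    write_homology_fixture,
)
from e3miner.tissue_rating import rate_all, rate_one_dataset, zscores


class TestApportionment:
    def test_exact_proportions(self):
        assert apportion(10, {"A": 0.5, "B": 0.3, "C": 0.2}) == {"A": 5, "B": 3, "C": 2}

    def test_largest_remainder_gets_the_leftover(self):
        # quotas 3.34 / 3.33 / 3.33: A's remainder is largest
        assert apportion(10, {"A": 0.334, "B": 0.333, "C": 0.333}) == {
            "A": 4,
            "B": 3,
            "C": 3,
        }

    @pytest.mark.parametrize("n", [0, 1, 7, 100, 2003])
    def test_counts_always_sum_to_n(self, n):
        counts = apportion(n, {"A": 0.15, "P": 0.67, "HP": 0.10, "MS": 0.005, "SP": 0.075})
        assert sum(counts.values()) == n


class TestPanelConfigValidation:
    def test_rejects_fewer_than_two_tissues(self):
        with pytest.raises(ValueError):
            PanelConfig(tissues=("testis",))

    def test_rejects_bad_proportions(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PanelConfig(class_proportions={"A": 0.5, "P": 0.4})

    def test_rejects_duplicate_tissues(self):
        with pytest.raises(ValueError):
            PanelConfig(tissues=("testis", "testis", "brain"))

    def test_rejects_missing_target(self):
        with pytest.raises(ValueError):
            PanelConfig(tissues=("brain", "liver"), target_tissue="testis")


class TestTissuePanel:
    def test_planted_sp_gene_is_one_hot_high_and_classified_sp(self):
        config = PanelConfig(
            n_genes=1,
            class_proportions={"SP": 1.0},
            noise_log_sd=0.0,
            call_flip_rate=0.0,
            sp_fold=99.0,
            baseline_log_sd=1e-9,
            seed=0,
        )
        datasets, _ = generate_tissue_panel(config)
        row = datasets[0].values.iloc[0]
        z = zscores(row.to_numpy())
        t = list(config.tissues).index("testis")
        assert z[t] == pytest.approx(2.846, abs=5e-4)
        assert rate_one_dataset(datasets[0]).iloc[0, t] == "SP"

    def test_all_absent_proportions_yield_all_a_calls(self):
        config = PanelConfig(
            n_genes=20, class_proportions={"A": 1.0}, call_flip_rate=0.0, seed=0
        )
        datasets, _ = generate_tissue_panel(config)
        for ds in datasets:
            assert (ds.calls.to_numpy() == "A").all()

    def test_same_seed_reproduces_identical_datasets(self):
        config = PanelConfig(n_genes=50, seed=42)
        a, _ = generate_tissue_panel(config)
        b, _ = generate_tissue_panel(config)
        for da, db in zip(a, b):
            pd.testing.assert_frame_equal(da.values, db.values)
            pd.testing.assert_frame_equal(da.calls, db.calls)

    def test_gene_count_conserved_in_every_dataset(self):
        config = PanelConfig(n_genes=137, seed=1)
        datasets, truth = generate_full_panel(config)
        assert len(truth.specificity) == 137
        for ds in datasets:
            assert ds.values.shape[0] == 137

    def test_noiseless_panel_recovers_every_attainable_label(self, noiseless_panel):
        config, datasets, truth = noiseless_panel
        ratings = rate_all(datasets)
        attainable = attainable_classes(len(config.tissues))
        final = ratings.final["testis"]
        for gene, label in truth.specificity.items():
            if label in attainable:
                assert final[gene] == label, (gene, label, final[gene])


class TestEstVoter:
    def test_absent_genes_have_zero_counts(self):
        config = PanelConfig(n_genes=10, class_proportions={"A": 1.0}, seed=0)
        est = generate_est_voter(config)
        assert (est.values.to_numpy() == 0).all()

    def test_reproducible_under_seed(self):
        config = PanelConfig(n_genes=30, seed=9)
        pd.testing.assert_frame_equal(
            generate_est_voter(config).values, generate_est_voter(config).values
        )

    def test_empty_config_gives_header_only_dataset(self):
        est = generate_est_voter(PanelConfig(n_genes=0))
        assert est.values.shape == (0, 10)
        assert est.calls is None

    def test_counts_are_integers_without_calls(self):
        est = generate_est_voter(PanelConfig(n_genes=25, seed=3))
        assert est.kind == "est_counts"
        assert np.issubdtype(est.values.to_numpy().dtype, np.integer)


class TestStageCourse:
    def test_me_gene_crosses_half_max_at_the_meiotic_stage(self):
        config = CourseConfig(
            n_genes=1, group_proportions={"ME": 1.0}, noise_log_sd=0.0, seed=0
        )
        datasets, _ = generate_stage_course(config)
        profile = datasets[0].values.iloc[0].to_numpy()
        half = profile.min() + 0.5 * (profile.max() - profile.min())
        assert (profile >= half).argmax() == 1  # pacSC
        assert profile[0] < profile[1] == profile[2] == profile[3]

    def test_none_genes_stay_below_threefold(self):
        config = CourseConfig(
            n_genes=50, group_proportions={"NONE": 1.0}, noise_log_sd=0.0, seed=0
        )
        datasets, _ = generate_stage_course(config)
        vals = datasets[0].values.to_numpy()
        assert ((vals.max(axis=1) + 1) / (vals.min(axis=1) + 1) < 3).all()

    def test_rejects_onset_fold_below_three(self):
        with pytest.raises(ValueError, match="onset_fold"):
            CourseConfig(onset_fold=2.0)

    def test_same_seed_reproduces_courses(self):
        config = CourseConfig(n_genes=40, seed=5)
        a, _ = generate_stage_course(config)
        b, _ = generate_stage_course(config)
        for da, db in zip(a, b):
            pd.testing.assert_frame_equal(da.values, db.values)


class TestDomainFixture:
    def test_round_trip_classification(self, tmp_path):
        path = write_domain_fixture({"g1": "zf-C3HC4"}, tmp_path / "d.tsv")
        hits = parse_domtblout(path)
        assert len(hits) == 1
        catalog = classify_families(filter_hits(hits), {"g1": "g1"})
        assert catalog.entries == {"g1": "RING"}

    def test_empty_map_round_trips_to_empty(self, tmp_path):
        path = write_domain_fixture({}, tmp_path / "d.tsv")
        assert parse_domtblout(path) == []

    def test_unknown_family_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown family"):
            write_domain_fixture({"g1": "F-box"}, tmp_path / "d.tsv")

    def test_mixed_domain_protein_resolved_by_best_evalue(self, tmp_path):
        path = write_domtblout(
            [("g1", "zf-C3HC4", 1e-8), ("g1", "U-box", 1e-3)], tmp_path / "d.tsv"
        )
        catalog = classify_families(filter_hits(parse_domtblout(path)), {"g1": "g1"})
        assert catalog.entries == {"g1": "RING"}


class TestHomologyFixture:
    def test_three_shared_groups(self, tmp_path):
        groups = [
            (f"grp{i}", {"10090": [f"m{i}"], "9606": [f"h{i}"]}) for i in range(3)
        ]
        path = write_homology_fixture(groups, tmp_path / "h.tsv")
        table = parse_homologene(path)
        summary = map_homologs(
            {"m0", "m1", "m2"}, "10090", {"h0", "h1", "h2"}, "9606", table
        )
        assert summary.n_shared == 3

    def test_single_species_group_is_not_shared(self, tmp_path):
        groups = [("grp0", {"10090": ["m0"]})]
        path = write_homology_fixture(groups, tmp_path / "h.tsv")
        summary = map_homologs({"m0"}, "10090", {"h0"}, "9606", parse_homologene(path))
        assert summary.n_shared == 0

    def test_duplicate_rows_rejected(self, tmp_path):
        groups = [("grp0", {"10090": ["m0", "m0"]})]
        with pytest.raises(ValueError, match="duplicate"):
            write_homology_fixture(groups, tmp_path / "h.tsv")

    def test_planted_e3_example_reproduces_published_fraction(self, tmp_path):
        groups, mouse, human, (tax_a, tax_b) = make_e3_homology_example()
        path = write_homology_fixture(groups, tmp_path / "h.tsv")
        summary = map_homologs(mouse, tax_a, human, tax_b, parse_homologene(path))
        assert (summary.n_a, summary.n_b, summary.n_shared) == (398, 411, 335)
        assert round(100 * summary.fraction, 1) == 70.7
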