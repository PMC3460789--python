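"""Unit and property tests for the five-level tissue-specificity rater."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from e3miner.datasets import ExpressionDataset
from e3miner.tissue_rating import (
    LEVELS,
    UNCLASSIFIED,
    AttainabilityWarning,
    RatingConfig,
    ballot,
    max_zscore,
    rate_all,
    rate_one_dataset,
    zscores,
)


def _dataset(values, calls=None, kind="array", tissues=None, name="d"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    tissues = tissues or [f"t{i}" for i in range(values.shape[1])]
    genes = [f"g{i}" for i in range(values.shape[0])]
    vdf = pd.DataFrame(values, index=genes, columns=tissues)
    cdf = None
    if calls is not None:
        cdf = pd.DataFrame(np.atleast_2d(calls), index=genes, columns=tissues)
    if kind == "est_counts":
        vdf = vdf.astype(int)
    return ExpressionDataset(name, vdf, cdf, kind)


class TestZscores:
    def test_one_hot_high_ten_tissues(self):
        # frozen from direct arithmetic: mean 10.9, sample sd 31.307
        z = zscores([100] + [1] * 9)
        assert z[0] == pytest.approx(2.846, abs=5e-4)
        assert z[1:] == pytest.approx(-0.316, abs=5e-4)

    def test_two_hot_ten_tissues(self):
        z = zscores([100, 100] + [1] * 8)
        assert z[0] == pytest.approx(1.897, abs=5e-4)
        assert z[2] == pytest.approx(-0.474, abs=5e-4)

    def test_constant_vector_maps_to_zeros(self):
        assert np.all(zscores([7.0] * 10) == 0)

    def test_rejects_short_vectors(self):
        with pytest.raises(ValueError):
            zscores([1.0])

    @given(
        x=st.lists(st.floats(0.1, 1e4), min_size=3, max_size=12),
        a=st.floats(0.1, 100.0),
        b=st.floats(-10.0, 10.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_location_scale_invariance(self, x, a, b):
        x = np.asarray(x)
        np.testing.assert_allclose(
            zscores(a * x + b), zscores(x), atol=1e-6, rtol=1e-6
        )

    @given(x=st.lists(st.floats(0.0, 1e4), min_size=3, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_zero_sum_and_unit_sd(self, x):
        z = zscores(x)
        assert abs(z.sum()) < 1e-8 * max(1.0, np.abs(z).max())
        if z.any():
            assert z.std(ddof=1) == pytest.approx(1.0)

    def test_one_hot_attains_the_theoretical_maximum(self):
        for n in (5, 8, 10, 15):
            z = zscores([10.0] + [1.0] * (n - 1))
            assert z[0] == pytest.approx(max_zscore(n))


class TestRateOneDataset:
    def test_specific_gene(self):
        rated = rate_one_dataset(_dataset([100] + [1] * 9, calls=[["P"] * 10]))
        assert rated.iloc[0, 0] == "SP"
        assert set(rated.iloc[0, 1:]) == {"P"}

    def test_highly_present_gene(self):
        rated = rate_one_dataset(_dataset([100, 100] + [1] * 8, calls=[["P"] * 10]))
        assert rated.iloc[0, 0] == "HP"  # z = 1.897 in [z1, z2)

    def test_absent_call_overrides_zscore(self):
        calls = [["A"] + ["P"] * 9]
        rated = rate_one_dataset(_dataset([100] + [1] * 9, calls=calls))
        assert rated.iloc[0, 0] == "A"

    def test_constant_present_gene_is_present_everywhere(self):
        rated = rate_one_dataset(_dataset([5.0] * 10, calls=[["P"] * 10]))
        assert set(rated.iloc[0]) == {"P"}

    def test_sp_blocked_when_another_tissue_exceeds_z2(self):
        # two identical spikes: both z = 1.897 with 10 tissues → HP, not SP
        rated = rate_one_dataset(_dataset([50, 50] + [1] * 8, calls=[["P"] * 10]))
        assert rated.iloc[0, 0] == "HP"
        assert rated.iloc[0, 1] == "HP"

    def test_est_counts_use_count_gt_zero_presence(self):
        rated = rate_one_dataset(_dataset([[0] * 10], kind="est_counts"))
        assert set(rated.iloc[0]) == {"A"}

    def test_attainability_warning_for_small_panels(self):
        with pytest.warns(AttainabilityWarning):
            rate_one_dataset(_dataset([[1.0] * 8], calls=[["P"] * 8]))

    def test_no_warning_for_ten_tissues(self, recwarn):
        rate_one_dataset(_dataset([[1.0] * 10], calls=[["P"] * 10]))
        assert not [w for w in recwarn if issubclass(w.category, AttainabilityWarning)]

    def test_every_cell_receives_exactly_one_level(self):
        rng = np.random.default_rng(0)
        values = rng.lognormal(5, 1, size=(50, 10))
        calls = np.where(rng.random((50, 10)) < 0.9, "P", "A")
        rated = rate_one_dataset(_dataset(values, calls=calls))
        assert set(np.unique(rated.to_numpy())) <= set(LEVELS)


def ballot_reference(votes, min_votes=2):
    """Independent restatement of the voting rules, used as an oracle."""
    cast = [v for v in votes if v != "abstain"]
    tallies = {lvl: cast.count(lvl) for lvl in LEVELS}
    best = max(tallies.values())
    if best < min_votes:
        return UNCLASSIFIED
    for lvl in LEVELS:  # ascending specificity → least specific tied level
        if tallies[lvl] == best:
            return lvl


class TestBallot:
    def test_tie_resolves_to_less_specific(self):
        assert ballot(["SP", "SP", "MS", "MS", "P"]) == "MS"

    def test_clear_majority(self):
        assert ballot(["SP", "SP", "HP", "P", "A"]) == "SP"

    def test_insufficient_support_is_unclassified(self):
        assert ballot(["SP", "HP", "MS", "P", None]) == UNCLASSIFIED

    def test_all_abstain_is_an_error(self):
        with pytest.raises(ValueError):
            ballot([None, None, None])

    def test_exhaustive_agreement_with_reference(self):
        options = list(LEVELS) + ["abstain"]
        for combo in itertools.product(options, repeat=5):
            votes = [None if v == "abstain" else v for v in combo]
            if all(v is None for v in votes):
                continue
            assert ballot(votes) == ballot_reference(combo), combo

    @given(
        votes=st.lists(st.sampled_from(LEVELS), min_size=1, max_size=7),
        extra_abstains=st.integers(0, 4),
    )
    @settings(max_examples=300, deadline=None)
    def test_order_invariant_and_abstention_padded(self, votes, extra_abstains):
        result = ballot(votes)
        assert ballot(list(reversed(votes)) + [None] * extra_abstains) == result


class TestRateAll:
    def test_unanimous_sp_gene(self, noiseless_panel):
        _, datasets, truth = noiseless_panel
        ratings = rate_all(datasets)
        sp_genes = [g for g, c in truth.specificity.items() if c == "SP"]
        assert sp_genes
        assert all(ratings.final.loc[g, "testis"] == "SP" for g in sp_genes)

    def test_single_voter_gene_is_unclassified(self):
        base = _dataset([[10, 1, 1, 1, 1, 1, 1, 1, 1, 1]], calls=[["P"] * 10], name="a")
        lonely = pd.DataFrame(
            [[100.0] + [1.0] * 9], index=["solo"], columns=base.tissues
        )
        other = ExpressionDataset(
            "b",
            pd.concat([base.values]),
            pd.concat([base.calls]),
        )
        only_in_one = ExpressionDataset(
            "c", lonely, pd.DataFrame([["P"] * 10], index=["solo"], columns=base.tissues)
        )
        ratings = rate_all([base, other, only_in_one])
        assert ratings.final.loc["solo", base.tissues[0]] == UNCLASSIFIED

    def test_disjoint_gene_namespaces_rejected(self):
        a = _dataset([[1.0] * 10], calls=[["P"] * 10], name="a")
        b = ExpressionDataset(
            "b",
            a.values.rename(index={"g0": "other"}),
            a.calls.rename(index={"g0": "other"}),
        )
        with pytest.raises(ValueError, match="shared"):
            rate_all([a, b])

    def test_config_thresholds_validated(self):
        with pytest.raises(ValueError):
            RatingConfig(z1=2.0, z2=1.0, z3=3.0)
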