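"""Fixture reconstruction and GCM-driven survey generators."""

import numpy as np
import pytest
from scipy.stats import chisquare

from kanocca import (
    DichotomizationScheme,
    EmissionModel,
    KanoCategory,
    binary_matrix,
    case_study_fixture,
    case_study_gcm_parameters,
    classify_pair,
    fixture_from_percentages,
    generate_gcm_survey,
    generate_two_culture_survey,
    load_case_study,
    tally_attribute,
)
from kanocca.synthetic import CANONICAL_PAIRS, beta_from_moments


def test_canonical_pairs_classify_to_their_category():
    for cat, pair in CANONICAL_PAIRS.items():
        assert classify_pair(pair) is cat


class TestFixture:
    def test_trusted_messenger_row_reproduced(self):
        ds = fixture_from_percentages({"B2": (11, 12, 27, 36, 4, 10)}, 100)
        tally = tally_attribute(ds, "B2")
        assert {c.value: v for c, v in tally.counts.items()} == {
            "A": 11, "O": 12, "M": 27, "I": 36, "R": 4, "Q": 10
        }
        assert tally.n == 100

    def test_all_indifferent_row(self):
        ds = fixture_from_percentages({"X": (0, 0, 0, 100, 0, 0)}, 50)
        pairs = set(ds.pairs.values())
        assert pairs == {CANONICAL_PAIRS[KanoCategory.INDIFFERENT]}

    def test_round_trip_on_all_exact_case_study_rows(self, case_study):
        ds = case_study_fixture()
        assert len(ds.attributes) == 8  # only rows whose percentages sum to 100
        for spec in ds.attributes:
            row = case_study.loc[spec.id]
            tally = tally_attribute(ds, spec.id)
            got = {c.value: v for c, v in tally.counts.items()}
            assert got == {
                "A": row.pct_a, "O": row.pct_o, "M": row.pct_m,
                "I": row.pct_i, "R": row.pct_r, "Q": row.pct_q,
            }

    def test_non_integer_count_names_offending_row(self):
        with pytest.raises(ValueError, match="badrow"):
            fixture_from_percentages({"badrow": (12.5, 0, 0, 87.5, 0, 0)}, 10)


class TestEmission:
    def test_distributions_must_be_valid(self):
        with pytest.raises(ValueError):
            EmissionModel(high={KanoCategory.MUST_BE: 1.0})
        with pytest.raises(ValueError):
            EmissionModel(
                high={
                    KanoCategory.MUST_BE: 0.5,
                    KanoCategory.ONE_DIMENSIONAL: 0.5,
                    KanoCategory.ATTRACTIVE: 0.5,
                }
            )

    def test_emitted_frequencies_converge(self, rng):
        em = EmissionModel()
        n = 10_000
        cats = [em.emit(True, rng)[0] for _ in range(n)]
        counts = [sum(c is k for c in cats) for k in em.high]
        p = chisquare(counts, [n / 3] * 3).pvalue
        assert p > 1e-3
        cats = [em.emit(False, rng)[0] for _ in range(n)]
        counts = [sum(c is k for c in cats) for k in em.low]
        expected = [n * v for v in em.low.values()]
        assert chisquare(counts, expected).pvalue > 1e-3

    def test_uniform_cells_still_classify_consistently(self, rng):
        em = EmissionModel(uniform_cells=True)
        for _ in range(200):
            relevant = bool(rng.integers(2))
            cat, pair = em.emit(relevant, rng)
            assert classify_pair(pair) is cat


class TestGCMSurvey:
    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_survey_and_matrix_consistent_under_relevance_scheme(self, seed):
        params = case_study_gcm_parameters(seed=seed, n_respondents=25)
        survey, matrix = generate_gcm_survey(params, seed=seed)
        assert binary_matrix(survey, DichotomizationScheme.RELEVANCE).equals(matrix)

    def test_perfect_competency_tracks_truth(self):
        params = case_study_gcm_parameters(seed=0, n_respondents=10)
        params.theta[:] = 1.0
        survey, matrix = generate_gcm_survey(params, seed=3)
        assert np.array_equal(matrix.to_numpy(), np.tile(params.z, (10, 1)))


class TestTwoCultures:
    def test_labels_partition_respondents(self):
        pa = case_study_gcm_parameters(seed=1, n_respondents=40)
        pb = case_study_gcm_parameters(seed=2, n_respondents=40)
        pb.z = 1 - pb.z
        survey, labels = generate_two_culture_survey(pa, pb, mixing=0.5, seed=4)
        assert len(labels) == 40
        assert set(labels) == {"A", "B"}
        assert (labels == "A").sum() == 20

    @pytest.mark.parametrize("mixing", [0.0, 1.0, -0.2])
    def test_degenerate_mixing_rejected(self, mixing):
        pa = case_study_gcm_parameters(seed=1, n_respondents=10)
        pb = case_study_gcm_parameters(seed=2, n_respondents=10)
        with pytest.raises(ValueError):
            generate_two_culture_survey(pa, pb, mixing=mixing)

    def test_identical_truths_warn(self):
        pa = case_study_gcm_parameters(seed=1, n_respondents=10)
        pb = case_study_gcm_parameters(seed=2, n_respondents=10)
        with pytest.warns(UserWarning, match="indistinguishable"):
            generate_two_culture_survey(pa, pb, mixing=0.5)


def test_beta_from_moments_matches_study_levels(rng):
    a, b = beta_from_moments(0.34, 0.14)
    draws = rng.beta(a, b, 200_000)
    assert draws.mean() == pytest.approx(0.34, abs=0.005)
    assert draws.std() == pytest.approx(0.14, abs=0.005)


def test_case_study_table_shape():
    df = load_case_study()
    assert df.shape[0] == 14
    assert set(df["binary_truth"]) == {0, 1}
    assert df["item_truth"].between(0, 1).all()
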