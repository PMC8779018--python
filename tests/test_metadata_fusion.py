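import numpy as np
import pytest

from fungirec import (
    FrequencyModel,
    LabelSpace,
    MetadataTable,
    PosteriorMatrix,
    PriorVector,
    fit_frequency_model,
    fuse,
    species_given_metadata,
)
from fungirec.errors import AlignmentError, ShapeError, UnsupportedClassError


@pytest.fixture
def ab_space():
    return LabelSpace(("A", "B"))


@pytest.fixture
def wood_model(ab_space):
    """Substrate 'wood' seen with A x3, B x2; no other metadata."""
    labels = ["A", "A", "A", "B", "B"]
    meta = MetadataTable.from_records(
        [f"o{i}" for i in range(5)], substrate=["wood"] * 5
    )
    return labels, meta, ab_space


class TestFitFrequencyModel:
    def test_relative_frequency(self, wood_model):
        labels, meta, space = wood_model
        model = fit_frequency_model(labels, meta, space, alpha=0.0)
        np.testing.assert_allclose(model.tables["substrate"]["wood"], [0.6, 0.4])

    def test_smoothed(self, wood_model):
        labels, meta, space = wood_model
        model = fit_frequency_model(labels, meta, space, alpha=1.0)
        np.testing.assert_allclose(model.tables["substrate"]["wood"], [4 / 7, 3 / 7])

    def test_missing_excluded_from_counts(self, ab_space):
        meta = MetadataTable.from_records(
            ["o0", "o1", "o2"], substrate=["wood", None, "wood"]
        )
        model = fit_frequency_model(["A", "B", "B"], meta, ab_space)
        np.testing.assert_allclose(model.tables["substrate"]["wood"], [0.5, 0.5])

    def test_all_missing_gives_empty_table(self, ab_space):
        meta = MetadataTable.from_records(["o0", "o1"], month=[None, None])
        model = fit_frequency_model(["A", "B"], meta, ab_space)
        assert model.tables["month"] == {}
        np.testing.assert_allclose(
            species_given_metadata(model, "month", 6), model.train_prior.values
        )

    def test_alignment_error(self, ab_space):
        meta = MetadataTable.from_records(["o0"], substrate=["wood"])
        with pytest.raises(AlignmentError):
            fit_frequency_model(["A", "B"], meta, ab_space)

    def test_stored_vectors_are_distributions(self, wood_model):
        labels, meta, space = wood_model
        model = fit_frequency_model(labels, meta, space, alpha=0.5)
        for table in model.tables.values():
            for vec in table.values():
                assert vec.min() >= 0
                assert vec.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fallback_equals_train_prior(self, wood_model):
        labels, meta, space = wood_model
        model = fit_frequency_model(labels, meta, space)
        np.testing.assert_allclose(model.train_prior.values, [0.6, 0.4])


class TestSpeciesGivenMetadata:
    def test_observed_value(self, wood_model):
        labels, meta, space = wood_model
        model = fit_frequency_model(labels, meta, space)
        np.testing.assert_allclose(
            species_given_metadata(model, "substrate", "wood"), [0.6, 0.4]
        )

    def test_unseen_value_falls_back(self, wood_model):
        labels, meta, space = wood_model
        model = fit_frequency_model(labels, meta, space)
        np.testing.assert_allclose(
            species_given_metadata(model, "substrate", "never-seen"),
            model.train_prior.values,
        )

    def test_unknown_type(self, wood_model):
        labels, meta, space = wood_model
        model = fit_frequency_model(labels, meta, space)
        with pytest.raises(KeyError):
            species_given_metadata(model, "altitude", "high")

    def test_month_out_of_range(self, wood_model):
        labels, meta, space = wood_model
        model = fit_frequency_model(labels, meta, space)
        with pytest.raises(ValueError, match="month"):
            species_given_metadata(model, "month", 13)


def _freq_model(space, prior, **tables):
    return FrequencyModel(
        space,
        PriorVector(np.asarray(prior, float)),
        {t: {v: np.asarray(vec, float) for v, vec in tab.items()} for t, tab in tables.items()},
        {t: 0.0 for t in ("habitat", "substrate", "month")},
    )


class TestFuse:
    def test_single_type_uniform_prior(self, abc_space):
        post = PosteriorMatrix(np.array([[0.5, 0.3, 0.2]]), ("o1",), abc_space)
        model = _freq_model(
            abc_space, [1 / 3, 1 / 3, 1 / 3], habitat={"h": [0.1, 0.6, 0.3]}
        )
        meta = MetadataTable.from_records(["o1"], habitat=["h"])
        out = fuse(post, meta, model, ["habitat"])
        np.testing.assert_allclose(
            out.values[0], [0.05 / 0.29, 0.18 / 0.29, 0.06 / 0.29], atol=1e-9
        )

    def test_single_type_nonuniform_prior(self, row_post, abc_space):
        model = _freq_model(
            abc_space, [0.5, 0.3, 0.2], substrate={"wood": [0.2, 0.5, 0.3]}
        )
        meta = MetadataTable.from_records(["o1"], substrate=["wood"])
        out = fuse(row_post, meta, model, ["substrate"])
        np.testing.assert_allclose(
            out.values[0], [0.24 / 0.89, 0.50 / 0.89, 0.15 / 0.89], atol=1e-9
        )

    def test_two_types(self):
        space = LabelSpace(("A", "B"))
        post = PosteriorMatrix(np.array([[0.5, 0.5]]), ("o1",), space)
        model = _freq_model(
            space, [0.5, 0.5],
            habitat={"h": [0.8, 0.2]},
            substrate={"s": [0.3, 0.7]},
        )
        meta = MetadataTable.from_records(["o1"], habitat=["h"], substrate=["s"])
        out = fuse(post, meta, model, ["habitat", "substrate"])
        np.testing.assert_allclose(out.values[0], [0.48 / 0.76, 0.28 / 0.76], atol=1e-9)

    def test_uninformative_metadata_is_identity(self, row_post, abc_space):
        prior = [0.5, 0.3, 0.2]
        model = _freq_model(
            abc_space, prior,
            habitat={"h": prior}, substrate={"s": prior}, month={"6": prior},
        )
        meta = MetadataTable.from_records(["o1"], habitat=["h"], substrate=["s"], month=[6])
        out = fuse(row_post, meta, model, ["habitat", "substrate", "month"])
        np.testing.assert_allclose(out.values, row_post.values, atol=1e-9)

    def test_zero_types_is_identity(self, row_post, abc_space):
        model = _freq_model(abc_space, [0.5, 0.3, 0.2])
        meta = MetadataTable.from_records(["o1"], habitat=["h"])
        out = fuse(row_post, meta, model, [])
        np.testing.assert_array_equal(out.values, row_post.values)

    def test_all_missing_passes_row_through(self, row_post, abc_space):
        model = _freq_model(abc_space, [0.5, 0.3, 0.2], habitat={"h": [0.1, 0.6, 0.3]})
        meta = MetadataTable.from_records(["o1"], habitat=[None], month=[None])
        out = fuse(row_post, meta, model, ["habitat", "month"])
        # unchanged up to the construction-time renormalization epsilon
        np.testing.assert_allclose(out.values, row_post.values, atol=1e-15)

    def test_sequential_equals_joint_formula(self, abc_space):
        """Fusing d1 then d2 (dividing by p(s) each step) == one-shot product."""
        rng = np.random.default_rng(3)
        post = PosteriorMatrix(
            rng.dirichlet(np.ones(3), size=6), tuple(f"o{i}" for i in range(6)), abc_space
        )
        prior = rng.dirichlet(np.ones(3) * 5)
        f1 = rng.dirichlet(np.ones(3) * 2)
        f2 = rng.dirichlet(np.ones(3) * 2)
        model = _freq_model(abc_space, prior, habitat={"h": f1}, substrate={"s": f2})
        ids = post.observation_ids
        meta = MetadataTable.from_records(ids, habitat=["h"] * 6, substrate=["s"] * 6)
        joint = fuse(post, meta, model, ["habitat", "substrate"])
        seq = fuse(fuse(post, meta, model, ["habitat"]), meta, model, ["substrate"])
        np.testing.assert_allclose(seq.values, joint.values, atol=1e-9)

    def test_order_invariance(self, abc_space):
        rng = np.random.default_rng(4)
        post = PosteriorMatrix(
            rng.dirichlet(np.ones(3), size=4), tuple(f"o{i}" for i in range(4)), abc_space
        )
        prior = rng.dirichlet(np.ones(3) * 5)
        model = _freq_model(
            abc_space, prior,
            habitat={"h": rng.dirichlet(np.ones(3))},
            month={"2": rng.dirichlet(np.ones(3))},
        )
        ids = post.observation_ids
        meta = MetadataTable.from_records(ids, habitat=["h"] * 4, month=[2] * 4)
        a = fuse(post, meta, model, ["habitat", "month"])
        b = fuse(post, meta, model, ["month", "habitat"])
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_prior_zero_with_posterior_mass_errors(self, abc_space):
        post = PosteriorMatrix(np.array([[0.6, 0.3, 0.1]]), ("o1",), abc_space)
        model = _freq_model(abc_space, [0.7, 0.3, 0.0], habitat={"h": [0.5, 0.5, 0.0]})
        meta = MetadataTable.from_records(["o1"], habitat=["h"])
        with pytest.raises(UnsupportedClassError):
            fuse(post, meta, model, ["habitat"])

    def test_misalignment_errors(self, row_post, abc_space):
        model = _freq_model(abc_space, [0.5, 0.3, 0.2])
        meta = MetadataTable.from_records(["other"], habitat=["h"])
        with pytest.raises(AlignmentError):
            fuse(row_post, meta, model, ["habitat"])

    def test_wrong_space_errors(self, row_post):
        other = LabelSpace(("X", "Y", "Z"))
        model = _freq_model(other, [0.5, 0.3, 0.2])
        meta = MetadataTable.from_records(["o1"], habitat=["h"])
        with pytest.raises(ShapeError):
            fuse(row_post, meta, model, ["habitat"])


class TestJointEstimation:
    def test_joint_table_used_when_supported(self, ab_space):
        n = 20
        labels = ["A"] * 12 + ["B"] * 8
        # habitat h + substrate s always co-occur -> joint table has support
        meta = MetadataTable.from_records(
            [f"o{i}" for i in range(n)], habitat=["h"] * n, substrate=["s"] * n
        )
        model = fit_frequency_model(
            labels, meta, ab_space, joint_types=("habitat", "substrate"), min_joint_count=10
        )
        assert ("h", "s") in model.joint_tables[("habitat", "substrate")]
        post = PosteriorMatrix(np.array([[0.3, 0.7]]), ("o0",), ab_space)
        meta1 = MetadataTable.from_records(["o0"], habitat=["h"], substrate=["s"])
        joint = fuse(post, meta1, model, ["habitat", "substrate"], use_joint=True)
        # single joint factor: post * p(s|d1,d2) / p(s), both (0.6, 0.4) here
        expected = post.values[0] * np.array([0.6, 0.4]) / np.array([0.6, 0.4])
        expected /= expected.sum()
        np.testing.assert_allclose(joint.values[0], expected, atol=1e-12)

    def test_rare_pair_falls_back_to_independence(self, ab_space):
        labels = ["A", "B", "A", "B"]
        meta = MetadataTable.from_records(
            ["o0", "o1", "o2", "o3"], habitat=["h"] * 4, substrate=["s"] * 4
        )
        model = fit_frequency_model(
            labels, meta, ab_space, joint_types=("habitat", "substrate"), min_joint_count=10
        )
        assert model.joint_tables[("habitat", "substrate")] == {}
        post = PosteriorMatrix(np.array([[0.7, 0.3]]), ("o0",), ab_space)
        meta1 = MetadataTable.from_records(["o0"], habitat=["h"], substrate=["s"])
        a = fuse(post, meta1, model, ["habitat", "substrate"], use_joint=True)
        b = fuse(post, meta1, model, ["habitat", "substrate"], use_joint=False)
        np.testing.assert_array_equal(a.values, b.values)


class TestSerialization:
    def test_round_trip(self, wood_model):
        labels, meta, space = wood_model
        model = fit_frequency_model(labels, meta, space, alpha=0.5)
        clone = FrequencyModel.from_json(model.to_json())
        assert clone.space.species_ids == space.species_ids
        np.testing.assert_allclose(
            clone.tables["substrate"]["wood"], model.tables["substrate"]["wood"]
        )
        np.testing.assert_allclose(clone.train_prior.values, model.train_prior.values)
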