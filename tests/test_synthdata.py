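"""Generator: prototypes, similarity, prefix embeddings, labels, splits, serialization."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from macrolink import example_grammar
from macrolink.grammar import Grammar
from macrolink.synthdata import (
    GeneratorConfig,
    LabeledDataset,
    PrototypeSet,
    dataset_summary,
    embedding_similarity,
    fit_class_prototypes,
    generate_dataset,
    generate_subsequence_embeddings,
    n_impossible,
    random_prototypes,
    sample_embedding,
    split_repetitions,
)


class _IdentityProjector:
    def fit_transform(self, X):
        return np.asarray(X)


class TestPrototypes:
    def test_fit_means_match_per_class_average(self, rng):
        X = rng.normal(size=(20, 4))
        y = np.repeat([0, 1], 10)
        protos = fit_class_prototypes(X, y, _IdentityProjector(), sigma=0.1)
        np.testing.assert_allclose(protos.means[0], X[:10].mean(axis=0))
        np.testing.assert_allclose(protos.means[1], X[10:].mean(axis=0))
        assert protos.sigma == 0.1  # caller-supplied, never estimated

    def test_identical_windows_give_that_point(self):
        X = np.tile([1.0, 2.0], (5, 1))
        protos = fit_class_prototypes(X, [0] * 5, _IdentityProjector(), sigma=0.0)
        np.testing.assert_allclose(protos.means[0], [1.0, 2.0])

    def test_missing_class_named_in_error(self):
        with pytest.raises(ValueError, match="'b'"):
            fit_class_prototypes(
                np.ones((2, 2)), [0, 2], _IdentityProjector(), sigma=0.1,
                class_names=["a", "b", "c"],
            )

    def test_random_prototypes_min_distance(self):
        protos = random_prototypes(8, 5, sigma=0.05, seed=3, min_distance=0.5)
        assert pdist(protos.means).min() >= 0.5 - 1e-12

    def test_csv_round_trip(self, tmp_path):
        protos = random_prototypes(3, 4, sigma=0.15, seed=7, class_names=["x", "y", "z"])
        protos.save(tmp_path / "p.csv")
        back = PrototypeSet.load(tmp_path / "p.csv")
        np.testing.assert_allclose(back.means, protos.means)
        assert back.sigma == 0.15
        assert back.class_names == ["x", "y", "z"]


class TestSimilarity:
    def test_two_classes_unit_distance(self):
        protos = PrototypeSet(means=np.array([[0.0], [1.0]]), sigma=0.1)
        assert embedding_similarity(protos) == pytest.approx(0.25)

    def test_three_classes_equilateral(self):
        # unit equilateral triangle: s = (1/9) * 3
        means = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        assert embedding_similarity(PrototypeSet(means=means, sigma=0)) == pytest.approx(1 / 3)

    def test_matches_double_loop_oracle(self, rng):
        means = rng.normal(size=(8, 5))
        n = 8
        expected = sum(
            1.0 / np.linalg.norm(means[i] - means[j])
            for i in range(n)
            for j in range(i + 1, n)
        ) / n**2
        got = embedding_similarity(PrototypeSet(means=means, sigma=0.1))
        assert got == pytest.approx(expected)

    def test_rotation_invariant(self, rng):
        means = rng.normal(size=(5, 3))
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        s1 = embedding_similarity(PrototypeSet(means=means, sigma=0))
        s2 = embedding_similarity(PrototypeSet(means=means @ R.T, sigma=0))
        assert s1 == pytest.approx(s2)

    def test_identical_means_reported_with_class_pair(self):
        protos = PrototypeSet(
            means=np.array([[1.0, 1.0], [1.0, 1.0]]), sigma=0, class_names=["u", "v"]
        )
        with pytest.raises(ZeroDivisionError, match="'u'.*'v'"):
            embedding_similarity(protos)

    def test_higher_dimension_lowers_similarity_on_embedded_means(self, rng):
        # appending extra non-zero coordinates increases every pairwise distance,
        # so the similarity score strictly drops
        means5 = rng.normal(size=(6, 5))
        extra = rng.normal(size=(6, 10))
        means15 = np.hstack([means5, extra])
        s5 = embedding_similarity(PrototypeSet(means=means5, sigma=0))
        s15 = embedding_similarity(PrototypeSet(means=means15, sigma=0))
        assert s15 < s5


class TestSampling:
    def test_sigma_zero_returns_mean_exactly(self, rng):
        protos = random_prototypes(3, 4, sigma=0.0, seed=1)
        np.testing.assert_array_equal(sample_embedding(protos, 2, rng), protos.means[2])

    def test_sample_mean_within_standard_error(self):
        protos = PrototypeSet(means=np.array([[1.0, -2.0]]), sigma=0.25)
        rng = np.random.default_rng(99)
        draws = np.stack([sample_embedding(protos, 0, rng) for _ in range(10_000)])
        se = 3 * 0.25 / np.sqrt(10_000)
        assert np.all(np.abs(draws.mean(axis=0) - protos.means[0]) < se)

    def test_fixed_seed_reproducible(self):
        protos = random_prototypes(2, 3, sigma=0.2, seed=5)
        a = sample_embedding(protos, 1, np.random.default_rng(42))
        b = sample_embedding(protos, 1, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_unknown_class_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_embedding(random_prototypes(2, 3, 0.1), 5, rng)


class TestSubsequenceEmbeddings:
    def test_prefixes_share_drawn_vectors(self, rng):
        protos = random_prototypes(4, 3, sigma=0.3, seed=2)
        out = generate_subsequence_embeddings([0, 1, 2], protos, rng)
        assert [o.shape[0] for o in out] == [1, 2, 3]
        np.testing.assert_array_equal(out[1], out[2][:2])
        np.testing.assert_array_equal(out[0], out[2][:1])

    def test_single_element_sequence(self, rng):
        protos = random_prototypes(2, 3, sigma=0.1, seed=2)
        out = generate_subsequence_embeddings([1], protos, rng)
        assert len(out) == 1 and out[0].shape == (1, 3)

    def test_sigma_zero_yields_mean_rows(self, rng):
        protos = random_prototypes(3, 2, sigma=0.0, seed=2)
        out = generate_subsequence_embeddings([2, 0], protos, rng)
        np.testing.assert_array_equal(out[1], protos.means[[2, 0]])


class TestImpossibleCount:
    @pytest.mark.parametrize(
        "n_pos,n_total,n_mean,expected",
        [(0, 100, 5, 10), (3, 100, 5, 5), (0, 0, 5, 0), (0, 5, 1, 1), (0, 4, 1, 0)],
    )
    def test_piecewise_rule(self, n_pos, n_total, n_mean, expected):
        assert n_impossible(n_pos, n_total, n_mean) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            n_impossible(-1, 10, 2)


class TestSplit:
    def test_largest_remainder_five_reps(self, rng):
        out = split_repetitions(5, (0.6, 0.2, 0.2), rng)
        assert [len(out[k]) for k in ("train", "val", "test")] == [3, 1, 1]

    def test_thirty_reps(self, rng):
        out = split_repetitions(30, (0.6, 0.2, 0.2), rng)
        assert [len(out[k]) for k in ("train", "val", "test")] == [18, 6, 6]

    def test_partition_is_exact(self, rng):
        out = split_repetitions(7, (0.6, 0.2, 0.2), rng)
        union = np.concatenate([out[k] for k in out])
        assert sorted(union) == list(range(7))


class TestGenerateDataset:
    def test_cooking_grammar_counts(self):
        grammar = example_grammar("cooking")
        protos = random_prototypes(8, 5, sigma=0.15, seed=1)
        ds = generate_dataset(grammar, protos, GeneratorConfig(repetitions=30, seed=1))
        all_samples = ds.train + ds.val + ds.test
        assert len(all_samples) == 30 * 74  # R * sum of sequence lengths = 2220
        assert sum(s.validator_label for s in all_samples) == 30 * 7  # one valid per rep

    def test_labels_agree_with_oracle(self, six_seq_grammar):
        protos = random_prototypes(8, 5, sigma=0.2, seed=2)
        ds = generate_dataset(six_seq_grammar, protos, GeneratorConfig(repetitions=4, seed=2))
        for name in ("train", "val", "test"):
            for s in ds.split(name):
                assert s.validator_label == int(six_seq_grammar.is_valid_macro(s.prefix))
                for link in s.links:
                    assert link.label == int(
                        six_seq_grammar.is_possible_link(s.prefix, link.source_class)
                    )

    def test_possible_links_cover_every_successor_once(self, branching_grammar):
        protos = random_prototypes(3, 4, sigma=0.1, seed=3)
        ds = generate_dataset(branching_grammar, protos, GeneratorConfig(repetitions=5, seed=3))
        for s in ds.train:
            pos_classes = sorted(l.source_class for l in s.links if l.label == 1)
            assert pos_classes == sorted(branching_grammar.successors(s.prefix))

    def test_split_is_leak_free(self, six_seq_grammar):
        protos = random_prototypes(8, 5, sigma=0.2, seed=4)
        ds = generate_dataset(six_seq_grammar, protos, GeneratorConfig(repetitions=5, seed=4))
        seen: dict[str, set[bytes]] = {}
        for name in ("train", "val", "test"):
            seen[name] = {s.embeddings[-1].tobytes() for s in ds.split(name)}
        assert not (seen["train"] & seen["val"])
        assert not (seen["train"] & seen["test"])
        assert not (seen["val"] & seen["test"])

    def test_repetition_prefixes_stay_in_one_split(self, six_seq_grammar):
        protos = random_prototypes(8, 5, sigma=0.2, seed=5)
        ds = generate_dataset(six_seq_grammar, protos, GeneratorConfig(repetitions=5, seed=5))
        assignment = {}
        for name in ("train", "val", "test"):
            for s in ds.split(name):
                key = (s.sequence_index, s.repetition)
                assert assignment.setdefault(key, name) == name

    def test_sigma_zero_embeddings_equal_means(self, abc_grammar):
        protos = random_prototypes(3, 4, sigma=0.0, seed=6)
        ds = generate_dataset(abc_grammar, protos, GeneratorConfig(repetitions=3, seed=6))
        for s in ds.train:
            np.testing.assert_array_equal(s.embeddings, protos.means[list(s.prefix)])

    def test_class_count_mismatch_rejected(self, abc_grammar):
        with pytest.raises(ValueError, match="classes"):
            generate_dataset(abc_grammar, random_prototypes(5, 4, 0.1))


class TestSummaryAndIO:
    def test_perfect_prefix_counts(self, abc_grammar):
        protos = random_prototypes(3, 3, sigma=0.1, seed=7)
        ds = generate_dataset(abc_grammar, protos, GeneratorConfig(repetitions=10, seed=7))
        summary = dataset_summary(ds)
        # 6 train reps: one valid (length 3) + two invalid (lengths 1, 2) each
        assert summary.loc["train", "valid"] == 6
        assert summary.loc["train", "invalid"] == 12

    def test_counts_conserve_samples(self, six_seq_grammar):
        protos = random_prototypes(8, 4, sigma=0.1, seed=8)
        ds = generate_dataset(six_seq_grammar, protos, GeneratorConfig(repetitions=5, seed=8))
        summary = dataset_summary(ds)
        for name in ("train", "val", "test"):
            assert summary.loc[name, "valid"] + summary.loc[name, "invalid"] == len(
                ds.split(name)
            )

    def test_degenerate_fractions_empty_splits(self, abc_grammar):
        protos = random_prototypes(3, 3, sigma=0.1, seed=9)
        ds = generate_dataset(
            abc_grammar, protos, GeneratorConfig(repetitions=4, fractions=(1.0, 0.0, 0.0), seed=9)
        )
        summary = dataset_summary(ds)
        assert summary.loc["val", "graphs"] == 0 and summary.loc["test", "graphs"] == 0

    def test_dataset_round_trip(self, tmp_path, branching_grammar):
        protos = random_prototypes(3, 4, sigma=0.1, seed=10, class_names=["a", "b", "c"])
        ds = generate_dataset(branching_grammar, protos, GeneratorConfig(repetitions=5, seed=10))
        ds.save(tmp_path / "ds")
        back = LabeledDataset.load(tmp_path / "ds")
        assert len(back.train) == len(ds.train)
        for a, b in zip(ds.train, back.train):
            np.testing.assert_allclose(a.embeddings, b.embeddings)
            assert a.prefix == b.prefix
            assert a.validator_label == b.validator_label
            assert [l.label for l in a.links] == [l.label for l in b.links]
        assert back.grammar is not None and back.grammar.to_dict() == branching_grammar.to_dict()
        assert back.config is not None and back.config.repetitions == 5
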