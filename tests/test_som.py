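import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cluster import KMeans

from eogsacc.core_data import DiagnosisClass
from eogsacc.som import (
    CellCounts,
    SOMGrid,
    assign_bmu,
    assign_bmus,
    compute_cell_counts,
    load_som,
    quantization_error,
    relabel_saccade,
    relabel_training_set,
    save_som,
    train_som,
)
from eogsacc.synthetic import GeneratorConfig, generate_dataset

from conftest import C, P, S, make_saccade


def oracle_relabel(n_c, n_p, n_s, threshold):
    """Independent brute-force transcription of the relabeling decision
    tree: sick strict plurality, then the no-P shortcut, then the ratio."""
    if n_s > n_c and n_s > n_p:
        return S
    if n_p == 0:
        return C
    if n_c / n_p < threshold:
        return P
    return C


class TestRelabelSaccade:
    def test_sick_plurality(self):
        assert relabel_saccade((1, 2, 5), 2.0) is S
        assert relabel_saccade((1, 2, 5), 4.5) is S

    def test_no_presymptomatic(self):
        assert relabel_saccade((4, 0, 1), 2.0) is C

    def test_ratio_rule_at_two(self):
        # at threshold 2 the control count must at least double the
        # presymptomatic count for the cell to stay control
        assert relabel_saccade((2, 1, 0), 2.0) is C
        assert relabel_saccade((1, 1, 0), 2.0) is P

    def test_ratio_rule_at_four(self):
        assert relabel_saccade((3, 1, 0), 4.0) is P
        assert relabel_saccade((4, 1, 0), 4.0) is C

    def test_zero_c_with_p(self):
        assert relabel_saccade((0, 1, 0), 4.0) is P

    def test_errors(self):
        with pytest.raises(ValueError):
            relabel_saccade((0, 0, 0), 2.0)
        with pytest.raises(ValueError):
            relabel_saccade((1, 1, 0), 0.0)

    @pytest.mark.parametrize("threshold", [2.0, 3.0, 4.0, 4.5])
    def test_oracle_equivalence_exhaustive(self, threshold):
        n = 0
        for n_c in range(11):
            for n_p in range(11):
                for n_s in range(11):
                    if n_c + n_p + n_s == 0:
                        continue
                    n += 1
                    assert relabel_saccade((n_c, n_p, n_s), threshold) is \
                        oracle_relabel(n_c, n_p, n_s, threshold)
        assert n == 1330

    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
        st.floats(0.5, 10.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_threshold(self, n_c, n_p, n_s, theta):
        """Once a cell is P at some threshold it stays P at any larger one."""
        if n_c + n_p + n_s == 0:
            return
        if relabel_saccade((n_c, n_p, n_s), theta) is P:
            assert relabel_saccade((n_c, n_p, n_s), theta + 1.0) is P
            assert relabel_saccade((n_c, n_p, n_s), theta * 2.0) is P

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.floats(0.5, 10.0), st.floats(0.5, 10.0))
    @settings(max_examples=200, deadline=None)
    def test_s_branch_threshold_independent(self, n_c, n_p, n_s, t1, t2):
        if n_c + n_p + n_s == 0:
            return
        a = relabel_saccade((n_c, n_p, n_s), t1)
        b = relabel_saccade((n_c, n_p, n_s), t2)
        assert (a is S) == (b is S)


class TestTrainSOM:
    def test_fixed_point_on_constant_data(self):
        X = np.tile(np.linspace(0, 1, 192), (20, 1))
        grid = train_som(X, width=3, height=3, epochs=5, seed=0)
        assert quantization_error(grid, X) < 1e-6

    def test_1x1_grid(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 192))
        grid = train_som(X, width=1, height=1, epochs=5, seed=0)
        for x in X[:10]:
            assert assign_bmu(grid, x) == (0, 0)
        # single weight sits in the data's bulk
        assert np.linalg.norm(grid.weights[0, 0] - X.mean(axis=0)) < np.linalg.norm(X.std(axis=0)) * 3

    def test_two_clusters_match_kmeans(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 0.1, size=(40, 192))
        b = rng.normal(5.0, 0.1, size=(40, 192))
        X = np.vstack([a, b])
        grid = train_som(X, width=2, height=1, epochs=10, seed=2)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        bmus = assign_bmus(grid, X)[:, 1]
        km_labels = km.labels_
        agree = max(
            (bmus == km_labels).mean(), (bmus == 1 - km_labels).mean()
        )
        assert agree >= 0.95

    def test_determinism(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 192))
        g1 = train_som(X, width=4, height=4, epochs=3, seed=9)
        g2 = train_som(X, width=4, height=4, epochs=3, seed=9)
        np.testing.assert_array_equal(g1.weights, g2.weights)
        g3 = train_som(X, width=4, height=4, epochs=3, seed=10)
        assert not np.array_equal(g1.weights, g3.weights)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            train_som(np.zeros((0, 192)), width=2, height=2)

    def test_training_reduces_quantization_error(self):
        ds = generate_dataset(GeneratorConfig(seed=5))
        X = ds.sample_matrix()
        # untrained baseline: the same sample-based initialization
        rng = np.random.default_rng(6)
        init = X[rng.integers(0, len(X), size=16)].reshape(4, 4, 192)
        untrained = SOMGrid(4, 4, init)
        trained = train_som(X, width=4, height=4, epochs=10, seed=6)
        assert quantization_error(trained, X) <= quantization_error(untrained, X)


class TestBMU:
    def test_exact_weight_match(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(2, 3, 192))
        grid = SOMGrid(3, 2, W)
        assert assign_bmu(grid, W[1, 2]) == (1, 2)

    def test_all_equal_weights_tie_break(self):
        grid = SOMGrid(3, 2, np.zeros((2, 3, 192)))
        assert assign_bmu(grid, np.ones(192)) == (0, 0)

    def test_length_mismatch(self):
        grid = SOMGrid(2, 2, np.zeros((2, 2, 192)))
        with pytest.raises(ValueError):
            assign_bmu(grid, np.zeros(100))


class TestCellCounts:
    def test_single_cell_counting(self):
        grid = SOMGrid(1, 1, np.zeros((1, 1, 192)))
        sacs = [
            make_saccade("a", "r", C), make_saccade("b", "r", C),
            make_saccade("c", "r2", P),
        ]
        counts = compute_cell_counts(grid, sacs)
        assert counts.cell(0, 0) == (2, 1, 0)

    def test_empty_all_zeros(self):
        grid = SOMGrid(2, 2, np.zeros((2, 2, 192)))
        counts = compute_cell_counts(grid, [])
        assert counts.counts.sum() == 0

    def test_totals_conserved(self, default_dataset):
        grid = train_som(default_dataset.saccades, width=4, height=4,
                         epochs=3, seed=0)
        counts = compute_cell_counts(grid, default_dataset.saccades)
        from collections import Counter

        given = Counter(s.given_label for s in default_dataset.saccades)
        assert counts.class_totals() == (given[C], given[P], given[S])


class TestRelabelTrainingSet:
    def test_single_mixed_cell(self):
        grid = SOMGrid(1, 1, np.zeros((1, 1, 192)))
        sacs = [make_saccade("a", "r", C), make_saccade("b", "r2", P)]
        relabeled, summary = relabel_training_set(grid, sacs, 2.0)
        # counts (1,1,0): ratio 1 < 2 -> everything P
        assert all(s.working_label is P for s in relabeled)
        assert summary.count(C, P) == 1
        assert summary.n_changed == 1

    def test_given_labels_untouched(self, default_dataset):
        grid = train_som(default_dataset.saccades, width=4, height=4,
                         epochs=3, seed=1)
        before = [s.given_label for s in default_dataset.saccades]
        relabeled, _ = relabel_training_set(grid, default_dataset.saccades, 4.0)
        after = [s.given_label for s in default_dataset.saccades]
        assert before == after
        assert [s.given_label for s in relabeled] == before
        assert len(relabeled) == len(default_dataset.saccades)

    def test_pure_cells_never_change(self, separable_shapes):
        ds = generate_dataset(
            GeneratorConfig(class_shapes=separable_shapes, contamination=0.0, seed=2)
        )
        grid = train_som(ds.saccades, width=6, height=6, epochs=5, seed=3)
        counts = compute_cell_counts(grid, ds.saccades)
        occupied = counts.counts.sum(axis=2) > 0
        purity = (counts.counts > 0).sum(axis=2)
        assert (purity[occupied] == 1).all()  # fixture sanity: cells are pure
        for theta in (2.0, 4.5):
            _, summary = relabel_training_set(grid, ds.saccades, theta)
            assert summary.n_changed == 0

    def test_p_count_monotone_in_threshold(self, default_dataset):
        grid = train_som(default_dataset.saccades, width=5, height=5,
                         epochs=5, seed=4)
        previous = -1
        for theta in (2.0, 3.0, 4.0, 4.5):
            relabeled, _ = relabel_training_set(grid, default_dataset.saccades, theta)
            n_p = sum(1 for s in relabeled if s.working_label is P)
            assert n_p >= previous
            previous = n_p

    def test_determinism(self, default_dataset):
        g1 = train_som(default_dataset.saccades, width=4, height=4, epochs=3, seed=5)
        g2 = train_som(default_dataset.saccades, width=4, height=4, epochs=3, seed=5)
        r1, s1 = relabel_training_set(g1, default_dataset.saccades, 3.0)
        r2, s2 = relabel_training_set(g2, default_dataset.saccades, 3.0)
        assert [s.working_label for s in r1] == [s.working_label for s in r2]
        assert s1.transitions == s2.transitions


class TestQuantizationError:
    def test_zero_when_weights_equal_samples(self):
        X = np.tile(np.arange(192.0), (4, 1))
        grid = SOMGrid(2, 2, np.tile(np.arange(192.0), (2, 2, 1)))
        assert quantization_error(grid, X) == 0.0

    def test_homogeneity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 192))
        W = rng.normal(size=(2, 2, 192))
        e1 = quantization_error(SOMGrid(2, 2, W), X)
        e2 = quantization_error(SOMGrid(2, 2, 2 * W), 2 * X)
        assert abs(e2 - 2 * e1) < 1e-9

    def test_empty_rejected(self):
        grid = SOMGrid(1, 1, np.zeros((1, 1, 192)))
        with pytest.raises(ValueError):
            quantization_error(grid, np.zeros((0, 192)))


def test_save_load_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    grid = SOMGrid(3, 2, rng.normal(size=(2, 3, 192)), {"epochs": 5, "seed": 1})
    save_som(grid, tmp_path / "som.json")
    back = load_som(tmp_path / "som.json")
    assert (back.width, back.height) == (3, 2)
    np.testing.assert_allclose(back.weights, grid.weights)
    assert back.hyperparams["epochs"] == 5
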