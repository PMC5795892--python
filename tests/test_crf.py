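"""CRF energy, MAP inference and max-margin learning."""

import itertools

import numpy as np
import pytest

from visceraseg.crf import (CRFInstance, CRFModel, K_CLASSES, energy,
                            map_inference, train_ssvm, zero_model)


def random_model(rng, d_node=4, d_edge=3) -> CRFModel:
    m = zero_model(d_node, d_edge)
    m.unary_weights = rng.normal(size=(K_CLASSES, d_node))
    m.pair_weights = rng.normal(size=(10, d_edge))
    return m


def random_instance(rng, n_nodes, d_node=4, d_edge=3, p_edge=0.5,
                    with_gold=False) -> CRFInstance:
    edges = [(a, b) for a in range(n_nodes) for b in range(a + 1, n_nodes)
             if rng.random() < p_edge]
    edges = np.array(edges, dtype=np.int64).reshape(-1, 2)
    return CRFInstance(
        node_features=rng.normal(size=(n_nodes, d_node)),
        edges=edges,
        edge_features=rng.normal(size=(len(edges), d_edge)),
        gold=(rng.integers(1, 5, size=n_nodes) if with_gold else None))


def brute_force_energy(model, inst, labeling):
    """Hand-rolled summation oracle, independent of the vectorized path."""
    y = np.asarray(labeling) - 1
    q = (inst.node_features - model.node_mean) / model.node_scale
    f = (inst.edge_features - model.edge_mean) / model.edge_scale
    full = model.pairwise_full
    total = 0.0
    for s in range(inst.n_nodes):
        total += float(np.dot(model.unary_weights[y[s]], q[s]))
    for e, (a, b) in enumerate(inst.edges):
        total += float(np.dot(full[y[a], y[b]], f[e]))
    return -total


def brute_force_map(model, inst):
    best, best_e = None, np.inf
    for labs in itertools.product(range(1, K_CLASSES + 1),
                                  repeat=inst.n_nodes):
        e = brute_force_energy(model, inst, labs)
        if e < best_e - 1e-12:
            best, best_e = np.array(labs), e
    return best, best_e


class TestEnergy:
    def test_zero_weights_zero_energy(self, rng):
        inst = random_instance(rng, 5)
        model = zero_model(4, 3)
        for _ in range(5):
            y = rng.integers(1, 5, size=5)
            assert energy(model, inst, y) == 0.0

    def test_unary_only_argmin_is_per_node_argmax(self, rng):
        inst = random_instance(rng, 6)
        model = random_model(rng)
        model.pair_weights[:] = 0.0
        theta = ((inst.node_features - model.node_mean) / model.node_scale) \
            @ model.unary_weights.T
        expected = np.argmax(theta, axis=1) + 1
        got = map_inference(model, inst, method="icm")
        np.testing.assert_array_equal(got, expected)

    def test_three_node_path_matches_enumeration_oracle(self, rng):
        inst = CRFInstance(node_features=rng.normal(size=(3, 4)),
                           edges=np.array([[0, 1], [1, 2]]),
                           edge_features=rng.normal(size=(2, 3)))
        model = random_model(rng)
        for labs in itertools.product(range(1, 5), repeat=3):
            np.testing.assert_allclose(
                energy(model, inst, labs),
                brute_force_energy(model, inst, labs), atol=1e-10)

    def test_label_validation(self, rng):
        inst = random_instance(rng, 3)
        model = zero_model(4, 3)
        with pytest.raises(ValueError):
            energy(model, inst, [1, 2])          # wrong length
        with pytest.raises(ValueError):
            energy(model, inst, [0, 1, 2])       # invalid code


class TestMapInference:
    def test_dominant_unaries_decouple(self, rng):
        inst = random_instance(rng, 8)
        model = random_model(rng)
        model.unary_weights *= 1e4               # unary term dominates
        expected = map_inference(model, inst, method="icm")
        theta = ((inst.node_features - model.node_mean) / model.node_scale) \
            @ model.unary_weights.T
        np.testing.assert_array_equal(expected, np.argmax(theta, axis=1) + 1)
        np.testing.assert_array_equal(
            map_inference(model, inst, method="maxprod"), expected)

    def test_energy_ordering_and_exactness(self, rng):
        """exact == enumeration; maxprod and ICM never beat exact, and
        maxprod (with its ICM polish) never loses to plain ICM."""
        for _ in range(40):
            n = int(rng.integers(2, 7))
            inst = random_instance(rng, n, p_edge=0.6)
            model = random_model(rng)
            y_exact = map_inference(model, inst, method="exact")
            y_bf, e_bf = brute_force_map(model, inst)
            e_exact = energy(model, inst, y_exact)
            assert abs(e_exact - e_bf) < 1e-9
            e_mp = energy(model, inst, map_inference(model, inst, "maxprod"))
            e_icm = energy(model, inst, map_inference(model, inst, "icm"))
            assert e_exact <= e_mp + 1e-9
            assert e_mp <= e_icm + 1e-9

    def test_two_node_attractive_potential_propagates(self):
        """Strong same-label reward plus conflicting weak unaries: both
        nodes adopt the confident node's label (verified by the 16-
        labeling enumeration built into exact inference)."""
        inst = CRFInstance(node_features=np.array([[5.0, 0.1, 0, 0],
                                                   [0.0, 0.3, 0, 0]]),
                           edges=np.array([[0, 1]]),
                           edge_features=np.ones((1, 1)))
        model = zero_model(4, 1)
        model.unary_weights = np.eye(4)
        model.pair_weights[:] = 0.0
        # same-label pairs strongly rewarded
        for k in range(4):
            from visceraseg.crf import _pair_idx
            model.pair_weights[_pair_idx(k, k)] = 10.0
        y = map_inference(model, inst, method="exact")
        np.testing.assert_array_equal(y, [1, 1])

    def test_exact_refuses_large_instances(self, rng):
        inst = random_instance(rng, 13)
        with pytest.raises(ValueError, match="12"):
            map_inference(random_model(rng), inst, method="exact")

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            map_inference(random_model(rng), random_instance(rng, 3),
                          method="bogus")


def separable_instances(rng, n_instances=4, n_nodes=12):
    """Node features are (noisy) one-hot encodings of the gold labels, so
    a diagonal unary weight matrix achieves zero training loss."""
    out = []
    for _ in range(n_instances):
        gold = rng.integers(1, 5, size=n_nodes)
        q = np.eye(4)[gold - 1] + 0.01 * rng.normal(size=(n_nodes, 4))
        edges = np.array([[i, i + 1] for i in range(n_nodes - 1)])
        out.append(CRFInstance(node_features=q, edges=edges,
                               edge_features=rng.random((len(edges), 2)),
                               gold=gold))
    return out


class TestSSVM:
    def test_separable_reaches_zero_training_loss(self, rng):
        insts = separable_instances(rng)
        model = train_ssvm(insts, C=1.0, max_cutting_iters=30)
        for inst in insts:
            y = map_inference(model, inst)
            np.testing.assert_array_equal(y, inst.gold)

    def test_objective_monotone_nondecreasing(self, rng):
        insts = [random_instance(rng, 10, with_gold=True) for _ in range(3)]
        model = train_ssvm(insts, C=0.1, max_cutting_iters=15)
        hist = np.asarray(model.objective_history)
        assert len(hist) >= 2
        assert np.all(np.diff(hist) >= -1e-6)

    def test_small_c_limit_shrinks_weights(self, rng):
        insts = separable_instances(rng, n_instances=2)
        big = train_ssvm(insts, C=1.0, max_cutting_iters=10)
        tiny = train_ssvm(insts, C=1e-8, max_cutting_iters=10)
        norm_big = np.linalg.norm(big.unary_weights) + \
            np.linalg.norm(big.pair_weights)
        norm_tiny = np.linalg.norm(tiny.unary_weights) + \
            np.linalg.norm(tiny.pair_weights)
        assert norm_tiny < 1e-3
        assert norm_tiny < norm_big * 1e-2

    def test_duplicated_instances_equivalent_at_halved_c(self, rng):
        """Duplicating every instance while halving C leaves the
        objective — and hence the learned weights — unchanged."""
        insts = separable_instances(rng, n_instances=2)
        single = train_ssvm(insts, C=0.5, max_cutting_iters=12)
        doubled = train_ssvm(insts + insts, C=0.25, max_cutting_iters=12)
        np.testing.assert_allclose(single.unary_weights,
                                   doubled.unary_weights, atol=1e-4)
        np.testing.assert_allclose(single.pair_weights,
                                   doubled.pair_weights, atol=1e-4)

    def test_pair_weight_symmetry(self, rng):
        insts = [random_instance(rng, 8, with_gold=True) for _ in range(2)]
        model = train_ssvm(insts, C=0.1, max_cutting_iters=8)
        full = model.pairwise_full
        np.testing.assert_array_equal(full, np.transpose(full, (1, 0, 2)))

    def test_rf_anchored_prior_reproduces_argmax_when_unconstrained(
            self, rng):
        """With the RF-anchored prior and no learning pressure, MAP
        inference equals the per-node probability argmax."""
        insts = separable_instances(rng, n_instances=2)
        model = train_ssvm(insts, C=1e-10, max_cutting_iters=0,
                           unary_prior=1.0)
        for inst in insts:
            y = map_inference(model, inst)
            np.testing.assert_array_equal(
                y, np.argmax(inst.node_features, axis=1) + 1)

    def test_invalid_c_rejected(self, rng):
        with pytest.raises(ValueError):
            train_ssvm(separable_instances(rng, 1), C=0.0)
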