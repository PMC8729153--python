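import numpy as np
import pytest

from lncgat.data_io import AssociationMatrix, DiseaseGeneMap, GeneInteractionNetwork
from lncgat.similarity import (
    PairExcludingGip,
    disease_similarity,
    gip_bandwidth,
    gip_similarity,
    module_separation,
)

from conftest import random_association, random_network


def brute_force_gip(values, literal=False):
    """Element-wise double-loop evaluation of the GIP kernel."""
    n = values.shape[0]
    mean_sq = np.mean([np.dot(values[i], values[i]) for i in range(n)])
    beta = mean_sq if literal else 1.0 / mean_sq
    S = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            diff = values[i] - values[j]
            S[i, j] = np.exp(-beta * np.dot(diff, diff))
    return S


def floyd_warshall(net):
    genes = list(net.gene_ids)
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for e in net.edges:
        a, b = tuple(e)
        D[idx[a], idx[b]] = D[idx[b], idx[a]] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D, idx


def separation_oracle(net, A, B):
    """Nearest-neighbour separation recomputed from Floyd-Warshall distances."""
    D, idx = floyd_warshall(net)
    far = D[np.isfinite(D)].max() + 1.0

    def d_within(S):
        if len(S) < 2:
            return 0.0
        vals = []
        for a in S:
            m = min(D[idx[a], idx[b]] for b in S if b != a)
            vals.append(m if np.isfinite(m) else far)
        return float(np.mean(vals))

    def to_other(S, T):
        vals = []
        for a in S:
            m = min(D[idx[a], idx[t]] for t in T)
            vals.append(m if np.isfinite(m) else far)
        return vals

    d_ab = float(np.mean(to_other(A, B) + to_other(B, A)))
    return d_ab - (d_within(A) + d_within(B)) / 2.0


class TestGipBandwidth:
    def test_mean_squared_norm_three_profiles(self, toy_assoc):
        # profiles (1,0), (0,1), (1,1): mean squared norm (1+1+2)/3 = 4/3
        assert gip_bandwidth(toy_assoc) == pytest.approx(0.75)
        assert gip_bandwidth(toy_assoc, literal_eq3=True) == pytest.approx(4 / 3)

    def test_unit_profiles_give_unit_bandwidth(self):
        A = AssociationMatrix(["l1", "l2"], ["d1", "d2"], np.eye(2, dtype=int))
        assert gip_bandwidth(A) == pytest.approx(1.0)
        assert gip_bandwidth(A, literal_eq3=True) == pytest.approx(1.0)

    def test_zero_matrix_rejected(self):
        A = AssociationMatrix.__new__(AssociationMatrix)
        A.lncrna_ids, A.disease_ids = ["l1"], ["d1"]
        A.values = np.zeros((1, 1), dtype=np.int8)
        with pytest.raises(ValueError, match="bandwidth undefined"):
            gip_bandwidth(A)


class TestGipSimilarity:
    def test_hand_computed_entry(self, toy_assoc):
        S = gip_similarity(toy_assoc)
        # ||IP(l1) - IP(l2)||^2 = 2, beta = 0.75
        assert S.values[0, 1] == pytest.approx(np.exp(-1.5), abs=1e-12)

    def test_identical_profiles_similarity_one(self):
        A = AssociationMatrix(
            ["l1", "l2"], ["d1", "d2"], np.array([[1, 0], [1, 0]])
        )
        assert gip_similarity(A).values[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            A = random_association(rng, L=10, D=6)
            for literal in (False, True):
                S = gip_similarity(A, literal_eq3=literal)
                oracle = brute_force_gip(A.values.astype(float), literal)
                assert np.abs(S.values - oracle).max() <= 1e-12

    def test_disease_axis_transposes(self, toy_assoc):
        S = gip_similarity(toy_assoc, axis="disease")
        assert S.ids == toy_assoc.disease_ids
        oracle = brute_force_gip(toy_assoc.values.T.astype(float))
        assert np.abs(S.values - oracle).max() <= 1e-12


class TestPairExcludingGip:
    def test_matches_full_recompute_on_zeroed_matrix(self):
        rng = np.random.default_rng(11)
        A = random_association(rng, L=8, D=6, p=0.4)
        loo = PairExcludingGip(A)
        for l, d in A.pairs()[:5]:
            zeroed = A.copy()
            zeroed.values[l, d] = 0
            expect = gip_similarity(zeroed).values
            got = loo.without(l, d).values
            assert np.abs(got - expect).max() <= 1e-10

    def test_no_op_for_non_edges(self):
        rng = np.random.default_rng(12)
        A = random_association(rng, L=6, D=5, p=0.3)
        loo = PairExcludingGip(A)
        zeros = np.argwhere(A.values == 0)
        l, d = zeros[0]
        assert np.array_equal(loo.without(l, d).values, loo.base().values)


class TestModuleSeparation:
    def test_path_graph_endpoints(self, path_net):
        s = module_separation(path_net, {"g1"}, {"g4"})
        assert (s.d_aa, s.d_bb, s.d_ab, s.s_ab) == (0.0, 0.0, 3.0, 3.0)

    def test_identical_singletons(self, path_net):
        s = module_separation(path_net, {"g2"}, {"g2"})
        assert s.s_ab == 0.0

    def test_identical_connected_pair_is_negative(self, path_net):
        s = module_separation(path_net, {"g1", "g2"}, {"g1", "g2"})
        assert (s.d_aa, s.d_bb, s.d_ab) == (1.0, 1.0, 0.0)
        assert s.s_ab == -1.0

    def test_empty_set_rejected(self, path_net):
        with pytest.raises(ValueError, match="non-empty"):
            module_separation(path_net, set(), {"g1"})

    def test_symmetry_on_random_graphs(self):
        rng = np.random.default_rng(21)
        net = random_network(rng, n=18, p=0.15)
        genes = list(net.gene_ids)
        for _ in range(20):
            A = set(rng.choice(genes, size=rng.integers(1, 5), replace=False))
            B = set(rng.choice(genes, size=rng.integers(1, 5), replace=False))
            ab = module_separation(net, A, B).s_ab
            ba = module_separation(net, B, A).s_ab
            assert ab == pytest.approx(ba, abs=1e-12)

    def test_matches_floyd_warshall_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            net = random_network(rng, n=rng.integers(8, 20), p=0.2)
            genes = list(net.gene_ids)
            A = set(rng.choice(genes, size=3, replace=False))
            B = set(rng.choice(genes, size=3, replace=False))
            got = module_separation(net, A, B).s_ab
            assert got == pytest.approx(separation_oracle(net, A, B), abs=1e-12)


def three_module_setup():
    """Two overlapping modules plus one distant module on a bar-bell graph."""
    edges = {
        frozenset(("a1", "a2")), frozenset(("a2", "a3")), frozenset(("a1", "a3")),
        frozenset(("a3", "mid")), frozenset(("mid", "b1")), frozenset(("b1", "b2")),
    }
    net = GeneInteractionNetwork(["a1", "a2", "a3", "mid", "b1", "b2"], edges)
    dgmap = DiseaseGeneMap(
        {"dA": {"a1", "a2", "a3"}, "dB": {"a1", "a2", "a3"}, "dC": {"b1", "b2"}}
    )
    return net, dgmap


class TestDiseaseSimilarity:
    def test_minmax_consistency_with_separation_table(self):
        net, dgmap = three_module_setup()
        S, table = disease_similarity(net, dgmap, ["dA", "dB", "dC"])
        s = dict(zip(zip(table.disease_a, table.disease_b), table.s_ab))
        lo, hi = min(s.values()), max(s.values())
        ids = S.ids
        for (da, db), v in s.items():
            expect = 1.0 - (v - lo) / (hi - lo)
            assert S.values[ids.index(da), ids.index(db)] == pytest.approx(expect)

    def test_identical_modules_attain_max_similarity(self):
        net, dgmap = three_module_setup()
        S, table = disease_similarity(net, dgmap, ["dA", "dB", "dC"])
        assert S.values[0, 1] == pytest.approx(1.0)  # identical pair -> min S_AB
        assert S.values.min() >= 0.0 and S.values.max() <= 1.0
        # identical connected modules separate negatively
        assert table.set_index(["disease_a", "disease_b"]).loc[("dA", "dB"), "s_ab"] < 0

    def test_literal_normalization_can_escape_unit_interval(self):
        net, dgmap = three_module_setup()
        S, table = disease_similarity(
            net, dgmap, ["dA", "dB", "dC"], normalization="literal"
        )
        s = dict(zip(zip(table.disease_a, table.disease_b), table.s_ab))
        lo, hi = min(s.values()), max(s.values())
        ids = S.ids
        for (da, db), v in s.items():
            expect = 1.0 - (v - lo) / hi
            assert S.values[ids.index(da), ids.index(db)] == pytest.approx(expect)

    def test_no_gene_data_disease_gets_zero_row(self):
        net, dgmap = three_module_setup()
        S, _ = disease_similarity(net, dgmap, ["dA", "dB", "dC", "dX"])
        j = S.ids.index("dX")
        off = np.delete(S.values[j], j)
        assert np.all(off == 0.0)
        assert S.values[j, j] == 1.0

    def test_fewer_than_two_annotated_diseases_rejected(self):
        net, dgmap = three_module_setup()
        only = DiseaseGeneMap({"dA": dgmap.modules["dA"]})
        with pytest.raises(ValueError, match="at least two"):
            disease_similarity(net, only, ["dA", "dX"])

    def test_decreasing_separation_never_decreases_similarity(self):
        # move module dC closer (overlap with dA): its S_AB to dA drops,
        # and its similarity to dA must not drop
        net, dgmap = three_module_setup()
        S1, _ = disease_similarity(net, dgmap, ["dA", "dB", "dC"])
        closer = DiseaseGeneMap(
            {**{k: set(v) for k, v in dgmap.modules.items()}, "dC": {"a1", "b1"}}
        )
        S2, _ = disease_similarity(net, closer, ["dA", "dB", "dC"])
        i, j = S1.ids.index("dA"), S1.ids.index("dC")
        assert S2.values[i, j] >= S1.values[i, j]
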