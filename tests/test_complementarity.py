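"""Diet normalization, Bray–Curtis, PCoA and functional dispersion."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from landnetsim.complementarity import (
    Embedding,
    bray_curtis,
    bray_curtis_matrix,
    build_diet_matrix,
    embed,
    functional_dispersion,
    pcoa,
    pooled_visitor_network,
    site_complementarity,
)
from landnetsim.errors import UndefinedMetricError, ValidationError
from landnetsim.net_model import WeightedBipartiteNetwork

from conftest import make_site, rec


def visitor_net(weights, plants=None, visitors=None):
    w = np.asarray(weights)
    plants = plants or tuple(f"p{i}" for i in range(w.shape[0]))
    visitors = visitors or tuple(f"v{j}" for j in range(w.shape[1]))
    return WeightedBipartiteNetwork(tuple(plants), tuple(visitors), w)


class TestDietMatrix:
    def test_row_normalization(self):
        diet = build_diet_matrix(visitor_net([[3, 6], [1, 2]]))
        assert np.allclose(diet.values, [[0.75, 0.25], [0.75, 0.25]])

    def test_proportional_diets_identical(self):
        diet = build_diet_matrix(visitor_net([[6, 3], [2, 1]]))
        assert np.allclose(diet.values[0], diet.values[1])

    def test_zero_event_visitor_dropped(self):
        diet = build_diet_matrix(visitor_net([[3, 0, 1], [1, 0, 3]]))
        assert diet.visitors == ("v0", "v2")

    def test_hand_three_visitor_case(self):
        net = visitor_net([[2, 0, 1], [2, 4, 0], [0, 0, 3]])
        diet = build_diet_matrix(net)
        expected = np.array([[0.5, 0.5, 0.0], [0.0, 1.0, 0.0], [0.25, 0.0, 0.75]])
        assert np.allclose(diet.values, expected)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        assert bray_curtis([0.2, 0.8], [0.2, 0.8]) == pytest.approx(0.0)

    def test_disjoint_support_one(self):
        assert bray_curtis([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_hand_value(self):
        assert bray_curtis([0.5, 0.5, 0], [0, 0.5, 0.5]) == pytest.approx(0.5)

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedMetricError):
            bray_curtis([0, 0], [0, 0])

    def test_bounds_symmetry_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.dirichlet(np.ones(6))
            b = rng.dirichlet(np.ones(6))
            d_ab, d_ba = bray_curtis(a, b), bray_curtis(b, a)
            assert 0.0 <= d_ab <= 1.0
            assert d_ab == pytest.approx(d_ba)
        assert bray_curtis(a, a) == pytest.approx(0.0, abs=1e-12)


class TestPcoa:
    def test_two_points(self):
        coords, eigval, _ = pcoa(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert coords.shape == (2, 1)
        assert sorted(np.round(coords[:, 0], 10)) == [-0.5, 0.5]

    def test_three_equidistant_points(self):
        D = np.ones((3, 3)) - np.eye(3)
        coords, eigval, _ = pcoa(D)
        assert coords.shape[1] == 2  # two positive eigenvalues
        emb = squareform(pdist(coords))
        assert np.allclose(emb, D, atol=1e-9)

    def test_zero_matrix(self):
        coords, eigval, _ = pcoa(np.zeros((4, 4)))
        assert coords.shape[1] == 0

    def test_asymmetric_rejected(self):
        D = np.array([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValidationError):
            pcoa(D)

    def test_msd_zero_at_full_rank_for_euclidean_input(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(7, 3))
        D = squareform(pdist(pts))
        coords, eigval, msd = pcoa(D)
        # 3-dimensional configuration: from d = 3 on, deviations vanish
        assert msd[3] == pytest.approx(0.0, abs=1e-12)
        assert all(v == pytest.approx(0.0, abs=1e-12) for d, v in msd.items() if d >= 3)

    def test_matches_scikit_bio(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(9)
        x = rng.dirichlet(np.ones(5), size=8)
        D = squareform(pdist(x, metric="braycurtis"))
        coords, eigval, _ = pcoa(D)
        ref = skbio_ord.pcoa(D, method="eigh")
        n_pos = coords.shape[1]
        assert np.allclose(eigval[:n_pos], ref.eigvals.values[:n_pos], atol=1e-8)
        # coordinates agree up to per-axis sign
        ref_coords = ref.samples.values[:, :n_pos]
        for j in range(n_pos):
            assert np.allclose(coords[:, j], ref_coords[:, j], atol=1e-6) or np.allclose(
                coords[:, j], -ref_coords[:, j], atol=1e-6
            )


def toy_embedding():
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 0.5]])
    return Embedding(species=("a", "b", "c"), coordinates=coords,
                     eigenvalues=np.array([1.0, 0.5]), msd_by_dim={2: 0.0})


class TestDispersion:
    def test_single_member_zero(self):
        assert functional_dispersion(toy_embedding(), ["a"]) == pytest.approx(0.0)

    def test_two_members_sum_and_mean(self):
        e = toy_embedding()
        assert functional_dispersion(e, ["a", "b"], mode="sum") == pytest.approx(1.0)
        assert functional_dispersion(e, ["a", "b"], mode="mean") == pytest.approx(0.5)

    def test_identical_coordinates_zero(self):
        coords = np.zeros((3, 2))
        e = Embedding(("a", "b", "c"), coords, np.array([0.0]), {})
        assert functional_dispersion(e, ["a", "b", "c"]) == pytest.approx(0.0)

    def test_unknown_member_raises(self):
        with pytest.raises(ValidationError):
            functional_dispersion(toy_embedding(), ["zz"])

    def test_rotation_invariance(self):
        rng = np.random.default_rng(10)
        coords = rng.normal(size=(6, 3))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        sp = tuple("abcdef")
        e1 = Embedding(sp, coords, np.ones(3), {})
        e2 = Embedding(sp, coords @ rot, np.ones(3), {})
        assert functional_dispersion(e1, list(sp)) == pytest.approx(
            functional_dispersion(e2, list(sp)))

    def test_monotone_in_dimensionality(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(size=(8, 5))
        e = Embedding(tuple("abcdefgh"), coords, np.ones(5), {})
        vals = [functional_dispersion(e, list("abcdefgh"), d=d) for d in range(1, 6)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestSiteComplementarity:
    def test_identical_visitor_sets_equal_values(self):
        records_a = [rec("grassland", "flower_visitor", "p1", "v1", 2, site="sA"),
                     rec("grassland", "flower_visitor", "p2", "v2", 2, site="sA")]
        records_b = [rec("scrub", "flower_visitor", "p1", "v1", 1, site="sB"),
                     rec("scrub", "flower_visitor", "p2", "v2", 5, site="sB")]
        ls_a = make_site(records_a, [("grassland", "p1", 1.0), ("grassland", "p2", 1.0)],
                         ["grassland"], site="sA")
        ls_b = make_site(records_b, [("scrub", "p1", 1.0), ("scrub", "p2", 1.0)],
                         ["scrub"], site="sB")
        table = site_complementarity([ls_a, ls_b], d=2)
        assert table["value"].iloc[0] == pytest.approx(table["value"].iloc[1])

    def test_shared_diet_row_gives_zero(self):
        # both visitors have proportional (identical after normalization) diets
        records = [rec("grassland", "flower_visitor", "p1", "v1", 2, site="sA"),
                   rec("grassland", "flower_visitor", "p2", "v1", 2, site="sA"),
                   rec("grassland", "flower_visitor", "p1", "v2", 3, site="sA"),
                   rec("grassland", "flower_visitor", "p2", "v2", 3, site="sA"),
                   rec("grassland", "flower_visitor", "p1", "v3", 1, site="sB"),
                   rec("grassland", "flower_visitor", "p2", "v3", 9, site="sB")]
        ls_a = make_site(records[:4], [("grassland", "p1", 1.0), ("grassland", "p2", 1.0)],
                         ["grassland"], site="sA")
        ls_b = make_site(records[4:], [("grassland", "p1", 1.0), ("grassland", "p2", 1.0)],
                         ["grassland"], site="sB")
        table = site_complementarity([ls_a, ls_b], d=2)
        assert table.set_index("site")["value"]["sA"] == pytest.approx(0.0, abs=1e-9)

    def test_pooled_network_sums_over_sites(self, small_study):
        net = pooled_visitor_network(small_study.landscapes.values())
        total = sum(
            r.count for ls in small_study.landscapes.values() for r in ls.records()
            if r.itype.value == "flower_visitor"
        )
        assert net.total_events() == total
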