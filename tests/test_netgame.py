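"""The microarray network game value function, the LRI, and the
position-value/axiom oracles."""

from fractions import Fraction

import pytest

from genegames import MicroarrayNetworkGame, position_value_bruteforce
from genegames.netgame import check_axioms
from genegames.network import Network, link
from genegames.synthetic import clique_game, generate_random_game, path_game, star_game

F = Fraction

L12, L23, L45 = link("1", "2"), link("2", "3"), link("4", "5")


def vec(game, scores):
    return tuple(scores[i] for i in game.universe)


class TestValueFunction:
    def test_full_network_value_is_one(self, game5, net5):
        assert game5.value(net5) == 1

    @pytest.mark.parametrize(
        "links,expected",
        [
            ({L12}, F(1, 5)),
            ({L23}, F(1, 5)),
            ({L45}, F(2, 5)),
            ({L12, L23}, F(3, 5)),
            ({L12, L45}, F(3, 5)),
            ({L23, L45}, F(3, 5)),
            (set(), F(0)),
        ],
    )
    def test_subnetwork_values(self, game5, links, expected):
        assert game5.value(frozenset(links)) == expected

    def test_monotone_under_link_addition(self, game5, net5):
        for sub in net5.subnetworks():
            for extra in net5.links - sub:
                assert game5.value(sub) <= game5.value(sub | {extra})

    def test_isolated_genes_do_not_count(self):
        # gene 'c' isolated: n(g) = 2, not 3
        game = MicroarrayNetworkGame(Network.from_edges(("a", "b", "c"), [("a", "b")]))
        assert game.n_connected == 2
        assert game.value({link("a", "b")}) == 1

    def test_needs_at_least_one_link(self):
        with pytest.raises(ValueError, match="at least one link"):
            MicroarrayNetworkGame(Network(("a", "b")))


class TestAlphaCoefficients:
    def test_five_gene_weights(self, game5):
        assert game5.alpha_bar() == {
            frozenset({L12}): 1,
            frozenset({L12, L23}): 1,
            frozenset({L23}): 1,
            frozenset({L45}): 2,
        }
        assert sum(game5.alpha_bar().values()) == game5.n_connected

    def test_single_link_shared_support(self):
        game = MicroarrayNetworkGame(Network.from_edges(("a", "b"), [("a", "b")]))
        assert game.alpha_bar() == {frozenset({link("a", "b")}): 2}

    def test_star_weights(self):
        game = star_game(3)
        weights = game.alpha_bar()
        full_star = game.network.links
        assert weights[frozenset(full_star)] == 1  # the hub
        singles = [w for sp, w in weights.items() if len(sp) == 1]
        assert singles == [1, 1, 1]  # each leaf owns its own link


class TestLRI:
    def test_full_network_vector(self, game5):
        assert vec(game5, game5.lri()) == (F(3, 20), F(6, 20), F(3, 20), F(4, 20), F(4, 20))

    def test_single_link_query(self, game5):
        assert vec(game5, game5.lri({L12})) == (F(1, 10), F(1, 10), 0, 0, 0)

    def test_two_link_query(self, game5):
        assert vec(game5, game5.lri({L12, L23})) == (F(3, 20), F(6, 20), F(3, 20), 0, 0)

    def test_empty_query_all_zero(self, game5):
        assert all(x == 0 for x in game5.lri(frozenset()).values())

    def test_closed_form_matches_support_sum(self, game5):
        assert game5.lri_full() == game5.lri()

    def test_degree_closed_form_gene_2(self, game5):
        # both neighbours of gene 2 have degree 1
        assert game5.lri_full()["2"] == F(1, 10) * (1 + 1 + 1) == F(6, 20)

    def test_path_of_three(self):
        game = path_game(3)
        assert vec(game, game.lri_full()) == (F(1, 4), F(1, 2), F(1, 4))

    @pytest.mark.parametrize("k", [2, 3, 5, 8])
    def test_star_center_always_half(self, k):
        game = star_game(k)
        scores = game.lri_full()
        hub = game.universe[0]
        assert scores[hub] == F(1, 2)
        for leaf in game.universe[1:]:
            assert scores[leaf] == F(1 + F(1, k), 2 * (k + 1))
        assert sum(scores.values()) == 1

    def test_connected_floor_and_isolated_zero(self):
        net = Network.from_edges(("a", "b", "z"), [("a", "b")])
        game = MicroarrayNetworkGame(net)
        scores = game.lri_full()
        assert scores["z"] == 0
        floor = F(1, 2 * game.n_connected)
        assert all(scores[i] >= floor for i in ("a", "b"))

    def test_efficiency_on_every_subnetwork(self, game5, net5):
        for sub in net5.subnetworks():
            assert sum(game5.lri(sub).values()) == game5.value(sub)


class TestPositionValueOracle:
    def test_unanimity_single_link(self):
        net = Network.from_edges(("a", "b"), [("a", "b")])
        v = lambda links: F(int(link("a", "b") in links))
        assert position_value_bruteforce(net, v) == {"a": F(1, 2), "b": F(1, 2)}

    def test_zero_value_function(self, net5):
        scores = position_value_bruteforce(net5, lambda links: F(0))
        assert all(x == 0 for x in scores.values())

    def test_matches_lri_on_worked_example(self, game5, net5):
        assert position_value_bruteforce(net5, game5.value) == game5.lri_full()

    def test_matches_lri_on_random_games(self):
        for seed in range(25):
            game = generate_random_game(n_genes=6, n_links=6, seed=seed)
            oracle = position_value_bruteforce(game.network, game.value)
            assert oracle == game.lri_full(), f"seed {seed}"

    def test_link_guard(self):
        game = clique_game(6)  # 15 links
        with pytest.raises(ValueError, match="closed form"):
            position_value_bruteforce(game.network, game.value)


class TestAxioms:
    def test_worked_example_passes_all(self, game5):
        report = check_axioms(game5)
        assert report.efficiency and report.superfluous_link
        assert report.all_pass

    def test_superfluous_link_added_outside_supports(self, game5, net5):
        # a link absent from every support changes nothing
        grown = Network(net5.universe, net5.links | {link("1", "4")})
        assert game5.lri(grown) == game5.lri(net5)

    def test_single_link_anonymity(self):
        game = MicroarrayNetworkGame(Network.from_edges(("a", "b"), [("a", "b")]))
        report = check_axioms(game)
        assert report.link_anonymity is True

    def test_clique_anonymity(self):
        report = check_axioms(clique_game(3))
        assert report.link_anonymity is True and report.efficiency

    def test_relabelling_equivariance(self, game5):
        mapping = {"1": "e", "2": "d", "3": "c", "4": "b", "5": "a"}
        relabelled = MicroarrayNetworkGame(
            Network.from_edges(
                sorted(mapping.values()),
                [(mapping[a], mapping[b]) for a, b in game5.network.links],
            )
        )
        orig = game5.lri_full()
        perm = relabelled.lri_full()
        assert all(perm[mapping[i]] == orig[i] for i in game5.universe)
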