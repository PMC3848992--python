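import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phyloniche import charevo, simulate as sim, treeio

from conftest import random_tree


def brute_force_parsimony(tree, charmap):
    """Exhaustive minimum number of changes over all internal labelings."""
    internals = tree.internal_nodes()
    states = charmap.states
    best = None
    tip_state = {t: charmap.mapping[t.label] for t in tree.tips()}
    for combo in itertools.product(states, repeat=len(internals)):
        labeling = dict(zip(internals, combo))
        labeling.update(tip_state)
        changes = sum(
            1
            for nd in tree.postorder()
            if nd.parent is not None and labeling[nd] != labeling[nd.parent]
        )
        best = changes if best is None else min(best, changes)
    return best


def random_charmap(tree, n_states, rng):
    vocab = tuple("abc"[:n_states])
    mapping = {lab: vocab[int(rng.integers(n_states))] for lab in tree.tip_labels()}
    return charevo.CharacterMap("c", vocab, mapping)


class TestFitch:
    def test_two_clean_clades_one_step(self, balanced4):
        cm = charevo.CharacterMap("c", ("x", "y"), dict(A="x", B="x", C="y", D="y"))
        assert charevo.fitch(balanced4, cm).score == 1

    def test_interleaved_states_two_steps(self, balanced4):
        cm = charevo.CharacterMap("c", ("x", "y"), dict(A="x", B="y", C="x", D="y"))
        r = charevo.fitch(balanced4, cm)
        assert r.score == 2
        assert r.score == brute_force_parsimony(r.tree, cm)

    def test_constant_character_zero_steps(self, balanced4):
        cm = charevo.CharacterMap("c", ("x",), dict(A="x", B="x", C="x", D="x"))
        assert charevo.fitch(balanced4, cm).score == 0

    def test_missing_tips_pruned(self, balanced4):
        cm = charevo.CharacterMap("c", ("x", "y"), dict(A="x", B=None, C="y", D="y"))
        r = charevo.fitch(balanced4, cm)
        assert sorted(r.tree.tip_labels()) == ["A", "C", "D"]

    def test_all_missing_rejected(self, balanced4):
        cm = charevo.CharacterMap("c", ("x",), dict(A=None, B=None, C=None, D=None))
        with pytest.raises(ValueError, match="missing"):
            charevo.fitch(balanced4, cm)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n_tips=st.integers(4, 8), n_states=st.integers(2, 3))
    def test_score_equals_exhaustive_minimum(self, seed, n_tips, n_states):
        rng = np.random.default_rng(seed)
        tree = random_tree(n_tips, seed)
        cm = random_charmap(tree, n_states, rng)
        r = charevo.fitch(tree, cm)
        assert r.score == brute_force_parsimony(r.tree, cm)


class TestResolve:
    def test_score_zero_single_state_everywhere(self, balanced4):
        cm = charevo.CharacterMap("c", ("x", "y"), dict(A="x", B="x", C="x", D="x"))
        r = charevo.fitch(balanced4, cm)
        for mode in ("acctran", "deltran"):
            assert set(charevo.resolve(r, mode).values()) == {"x"}

    def test_both_modes_realize_score(self, balanced4):
        cm = charevo.CharacterMap("c", ("x", "y"), dict(A="x", B="y", C="x", D="y"))
        r = charevo.fitch(balanced4, cm)
        assert len(charevo.changed_edges(r, "acctran")) == 2
        assert len(charevo.changed_edges(r, "deltran")) == 2

    def test_root_tie_break_deterministic(self):
        t = treeio.parse_newick("(A:1,B:1):0;")
        cm = charevo.CharacterMap("c", ("x", "y"), dict(A="y", B="x"))
        r = charevo.fitch(t, cm)
        states = charevo.resolve(r, "acctran")
        # Fitch root set {x,y}: lowest state in vocabulary order wins
        assert states[r.tree.root] == "x"
        assert charevo.resolve(r, "acctran") == charevo.resolve(r, "acctran")

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_resolutions_are_minimum_change_labelings(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(int(rng.integers(4, 9)), seed + 1)
        cm = random_charmap(tree, int(rng.integers(2, 4)), rng)
        r = charevo.fitch(tree, cm)
        minimum = brute_force_parsimony(r.tree, cm)
        for mode in ("acctran", "deltran"):
            states = charevo.resolve(r, mode)
            changes = sum(
                1
                for nd in r.tree.postorder()
                if nd.parent is not None and states[nd] != states[nd.parent]
            )
            assert changes == r.score == minimum

    @pytest.mark.parametrize("seed", range(12))
    def test_acctran_changes_at_least_as_rootward(self, seed):
        """Aggregate depth (edges from root) of changed edges: ACCTRAN puts
        its changes no deeper than DELTRAN on the same data."""
        rng = np.random.default_rng(seed)
        tree = random_tree(8, seed + 50)
        cm = random_charmap(tree, 3, rng)
        r = charevo.fitch(tree, cm)

        def depth_sum(mode):
            states = charevo.resolve(r, mode)
            total = 0
            for nd in r.tree.postorder():
                if nd.parent is None or states[nd] == states[nd.parent]:
                    continue
                d, cur = 0, nd
                while cur.parent is not None:
                    d += 1
                    cur = cur.parent
                total += d
            return total

        assert depth_sum("acctran") <= depth_sum("deltran")


class TestCountTransitions:
    def test_rate_zero_simulated(self):
        t = sim.simulate_yule_tree(10, 1.0, seed=2)
        cm, k = sim.simulate_mk_character(t, 3, 0.0, seed=3)
        assert charevo.count_transitions(t, cm) == 0 == k

    @pytest.mark.parametrize("seed", range(5))
    def test_not_more_than_realized(self, seed):
        t = sim.simulate_yule_tree(12, 1.0, seed=seed)
        cm, k = sim.simulate_mk_character(t, 4, 2.0, seed=seed)
        assert charevo.count_transitions(t, cm) <= k


def naive_phylotype_stats(tree, states, node):
    """Independent per-node Size/Different/Persistence via direct path walks."""
    s = states[node]
    members = []
    for tip in tree.clade_tips(node):
        cur, mono = tip, True
        while cur is not node:
            if states[cur] != s:
                mono = False
                break
            cur = cur.parent
        if mono:
            members.append(tip.label)
    # maximal wrong-state subtrees by preorder descent
    different = 0
    stack = list(node.children)
    while stack:
        nd = stack.pop()
        if states[nd] != s:
            different += 1
        else:
            stack.extend(nd.children)
    # persistence: consecutive all-monochrome internal generations
    level = [c for c in node.children if c.children]
    persistence = 0
    while level and all(states[n] == s for n in level):
        persistence += 1
        level = [gc for n in level for gc in n.children if gc.children]
    return sorted(members), different, persistence


class TestPhylotypes:
    def make(self, newick, mapping, vocab=("s", "r")):
        t = treeio.parse_newick(newick)
        cm = charevo.CharacterMap("c", vocab, mapping)
        crit = charevo.PhylotypeCriteria(min_support=None)
        return charevo.phylotype_analysis(t, cm, crit)

    def test_monophyletic_unique_state_clade(self):
        """A clean 4-tip clade alone bearing its state: Size 4, Different 0,
        Persistence 1, coverage 100."""
        phylos, result, states = self.make(
            "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1):0;",
            dict(A="s", B="s", C="s", D="s", E="r", F="r", G="r", H="r"),
        )
        ph = {p.state: p for p in phylos}
        assert ph["s"].size == 4 and ph["s"].different == 0
        assert ph["s"].persistence == 1
        assert ph["s"].coverage == pytest.approx(100.0)
        assert ph["s"].members == ("A", "B", "C", "D")

    def test_embedded_foreign_subtree_counts_in_different(self):
        """7 tips of one state with one embedded single-tip subtree of
        another state: Size 7, Different 1, Size/Different 7."""
        newick = (
            "((((A:1,B:1):1,(C:2,X:2):1):1,((D:3,E:3):1,(F:2.5,G:2.5):1.5):0;"
        )
        # build explicitly: clade of 8 tips, 7 state s + 1 state r inside
        newick = "(((A:1,B:1):1,(C:1,X:1):1):2,((D:2,E:2):1,(F:2,G:2):1):1):0;"
        phylos, result, states = self.make(
            newick,
            dict(A="s", B="s", C="s", X="r", D="s", E="s", F="s", G="s"),
        )
        ph = {p.state: p for p in phylos}
        assert ph["s"].size == 7
        assert ph["s"].different == 1
        assert ph["s"].size_over_different == pytest.approx(7.0)
        assert ph["s"].coverage == pytest.approx(100.0)
        assert "X" not in ph["s"].members

    def test_low_support_node_cannot_root_phylotype(self):
        t = treeio.parse_newick("(((A:1,B:1)79:1,C:2)95:1,(D:1.5,E:1.5):1.5):0;")
        cm = charevo.CharacterMap("c", ("s", "r"), dict(A="s", B="s", C="s", D="r", E="r"))
        crit = charevo.PhylotypeCriteria(min_size=2, min_support=80.0)
        phylos, _, _ = charevo.phylotype_analysis(t, cm, crit)
        roots = {p.root_index for p in phylos}
        low = next(n for n in t.internal_nodes() if n.support == 79.0)
        # the 79-support cherry cannot root; the s phylotype roots at the
        # well-supported 3-tip clade instead
        ph = {p.state: p for p in phylos}
        assert ph["s"].size == 3
        assert ph["s"].root_index != low.index

    def test_nested_same_state_absorbed(self):
        phylos, result, states = self.make(
            "((((A:1,B:1):1,C:2):1,D:3):1,(E:2,F:2):2):0;",
            dict(A="s", B="s", C="s", D="s", E="r", F="r"),
        )
        s_phylos = [p for p in phylos if p.state == "s"]
        assert len(s_phylos) == 1
        assert s_phylos[0].size == 4

    def test_mandatory_size_criterion(self):
        with pytest.raises(ValueError, match="[Ss]ize"):
            charevo.PhylotypeCriteria(min_size=0)

    @pytest.mark.parametrize("seed", range(10))
    def test_stats_match_naive_enumeration(self, seed):
        """Size/Different/Persistence agree with independent path-walking on
        every internal node of random labeled trees."""
        rng = np.random.default_rng(seed)
        tree = random_tree(10, seed + 77)
        cm = random_charmap(tree, 3, rng)
        result = charevo.fitch(tree, cm)
        states = charevo.resolve(result, "acctran")
        crit = charevo.PhylotypeCriteria(min_size=1, min_persistence=0, min_support=None)
        phylos = charevo.enumerate_phylotypes(result.tree, states, crit)
        by_root = {p.root_index: p for p in phylos}
        seen_roots = set()
        for node in result.tree.preorder():
            if node.is_tip:
                continue
            members, diff, persist = naive_phylotype_stats(result.tree, states, node)
            if node.index in by_root:
                p = by_root[node.index]
                assert list(p.members) == members
                assert p.different == diff
                assert p.persistence == persist
                seen_roots.add(node.index)
            else:
                # legitimately missing: absorbed by a retained same-state
                # ancestor, or failing a criterion (empty member set,
                # size/different ratio below threshold)
                anc = node.parent
                absorbed = False
                while anc is not None:
                    if anc.index in by_root and states[anc] == states[node]:
                        absorbed = True
                        break
                    anc = anc.parent
                fails = len(members) < crit.min_size or (
                    diff > 0 and len(members) / diff < crit.min_size_over_different
                )
                assert absorbed or fails


class TestShuffleTest:
    def test_constant_character_p_one(self, balanced4):
        cm = charevo.CharacterMap("c", ("x",), dict(A="x", B="x", C="x", D="x"))
        crit = charevo.PhylotypeCriteria(min_size=2, min_support=None)
        res = charevo.shuffle_test(balanced4, cm, crit, n_iter=50, seed=0)
        assert res.state_p["x"]["p_raw"] == 1.0
        assert res.observed_score == 0
        assert res.score_p_low == 1.0

    @pytest.mark.parametrize("mode", ["acctran", "deltran"])
    def test_perfectly_clustered_state_significant(self, mode):
        """A monophyletic 8-tip state on a 20-tip balanced tree is detected
        (phylotype p and transition-count p both small).

        Only the clustered minority state is informative here: the
        complementary background state spans the root, and root-spanning
        monochrome-path phylotypes arise easily in shuffles, so its p-value
        is honestly large.
        """

        def clade(l):
            return (
                f"(((({l[0]}:1,{l[1]}:1):1,({l[2]}:1,{l[3]}:1):1):1,"
                f"(({l[4]}:1,{l[5]}:1):1,({l[6]}:1,{l[7]}:1):1):1):1,"
                f"({l[8]}:3,{l[9]}:3):1):1"
            )

        A = [f"a{i}" for i in range(10)]
        B = [f"b{i}" for i in range(10)]
        tree = treeio.parse_newick(f"({clade(A)},{clade(B)}):0;")
        clustered = {f"a{i}" for i in range(8)}  # one monophyletic sub-clade
        cm = charevo.CharacterMap(
            "c", ("a", "b"),
            {lab: ("a" if lab in clustered else "b") for lab in tree.tip_labels()},
        )
        crit = charevo.PhylotypeCriteria(min_support=None)
        res = charevo.shuffle_test(tree, cm, crit, n_iter=1000, seed=3, mode=mode)
        assert res.state_p["a"]["p_corrected"] <= 0.05
        assert res.score_p_low_corrected <= 0.05

    def test_invalid_iterations(self, balanced4):
        cm = charevo.CharacterMap("c", ("x", "y"), dict(A="x", B="x", C="y", D="y"))
        with pytest.raises(ValueError):
            charevo.shuffle_test(balanced4, cm, n_iter=0)

    def test_null_scores_are_reproducible(self, balanced4):
        cm = charevo.CharacterMap("c", ("x", "y"), dict(A="x", B="x", C="y", D="y"))
        crit = charevo.PhylotypeCriteria(min_size=2, min_support=None)
        a = charevo.shuffle_test(balanced4, cm, crit, n_iter=100, seed=9)
        b = charevo.shuffle_test(balanced4, cm, crit, n_iter=100, seed=9)
        assert np.array_equal(a.null_scores, b.null_scores)


class TestNiches:
    def test_disjoint_hosts_different_niches(self):
        table = charevo.code_niches(
            {"A": (frozenset({"h1"}), frozenset({"shoot"})),
             "B": (frozenset({"h2"}), frozenset({"shoot"}))}
        )
        assert table.niche_ids["A"] != table.niche_ids["B"]
        assert table.n_niches == 2

    def test_simultaneous_overlap_required(self):
        # shared host but disjoint feeding sites -> different niches
        table = charevo.code_niches(
            {"A": (frozenset({"h1"}), frozenset({"shoot"})),
             "B": (frozenset({"h1"}), frozenset({"trunk"})),
             "C": (frozenset({"h1", "h2"}), frozenset({"shoot"}))}
        )
        assert table.niche_ids["A"] == table.niche_ids["C"]
        assert table.niche_ids["A"] != table.niche_ids["B"]

    def test_bridge_species_split_policy(self):
        species = {
            "A": (frozenset({"h1"}), frozenset({"shoot"})),
            "B": (frozenset({"h1", "h2"}), frozenset({"shoot"})),
            "C": (frozenset({"h2"}), frozenset({"shoot"})),
        }
        comp = charevo.code_niches(species, policy="components")
        assert comp.bridges == ("B",)
        assert len({comp.niche_ids[s] for s in "ABC"}) == 1
        split = charevo.code_niches(species, policy="split")
        assert len(split.niche_ids["B"]) == 2
        assert split.niche_ids["A"] != split.niche_ids["C"]
        assert set(split.niche_ids["B"]) == {split.niche_ids["A"][0], split.niche_ids["C"][0]}

    def test_bridge_sister_policy_follows_cherry_partner(self):
        species = {
            "A": (frozenset({"h1"}), frozenset({"shoot"})),
            "B": (frozenset({"h1", "h2"}), frozenset({"shoot"})),
            "C": (frozenset({"h2"}), frozenset({"shoot"})),
        }
        tree = treeio.parse_newick("((B:1,C:1):1,A:2):0;")
        sis = charevo.code_niches(species, policy="sister", tree=tree)
        assert sis.niche_ids["B"] == sis.niche_ids["C"]
        assert sis.niche_ids["B"] != sis.niche_ids["A"]

    def test_empty_feeding_sites_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            table = charevo.code_niches(
                {"A": (frozenset({"h1"}), frozenset()),
                 "B": (frozenset({"h1"}), frozenset({"shoot"}))}
            )
        assert "A" not in table.niche_ids


class TestNicheStatistics:
    def test_constant_niche_no_shifts(self, balanced4):
        cm = charevo.CharacterMap("niche", ("N1",), {t: "N1" for t in "ABCD"})
        assert charevo.proportion_splits_with_shift(balanced4, cm) == 0.0

    def test_every_tip_own_niche_on_caterpillar(self, caterpillar5):
        labels = caterpillar5.tip_labels()
        cm = charevo.CharacterMap(
            "niche", tuple(f"N{i}" for i in range(5)),
            {lab: f"N{i}" for i, lab in enumerate(labels)},
        )
        assert charevo.proportion_splits_with_shift(caterpillar5, cm) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_ratio(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(7, seed + 31)
        cm = random_charmap(tree, 3, rng)
        got = charevo.proportion_splits_with_shift(tree, cm)
        want = brute_force_parsimony(tree, cm) / (tree.n_tips - 1)
        assert got == pytest.approx(want)

    def test_sister_pair_overlap_counts(self):
        tree = treeio.parse_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):2,((E:2,F:2):1,(G:1,H:1):2):1):0;"
        )
        niche_ids = {
            "A": ("N1",), "B": ("N1",),      # overlapping cherry
            "C": ("N1",), "D": ("N2",),      # non-overlapping cherry
            "E": ("N2",), "F": ("N3",),      # non-overlapping cherry
            "G": ("N3", "N4"), "H": ("N4",),  # overlap via shared id
        }
        import networkx as nx

        table = charevo.NicheTable(
            niche_ids=niche_ids, bridges=(), policy="components", graph=nx.Graph()
        )
        total, non = charevo.sister_pair_niche_overlap(tree, table)
        assert (total, non) == (4, 2)

    def test_all_one_niche_no_divergent_pairs(self, balanced4):
        import networkx as nx

        table = charevo.NicheTable(
            niche_ids={s: ("N1",) for s in "ABCD"}, bridges=(), policy="components",
            graph=nx.Graph(),
        )
        assert charevo.sister_pair_niche_overlap(balanced4, table) == (2, 0)
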