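"""Parsimony character history, phylotype detection and niche statistics.

Ancestral states are reconstructed under Fitch parsimony and resolved with
ACCTRAN (changes placed as close to the root as possible) or DELTRAN
(changes delayed toward the tips).  Both resolutions realize exactly the
Fitch minimum number of changes; ties are broken deterministically by the
character's state-vocabulary order.

A *phylotype* is a set of taxa that share one character state along every
path from each member to a common root node.  Candidate phylotypes are
scored by Size (member count), Different (number of maximal embedded
subtrees whose root carries another state), Persistence (consecutive
internal-node generations below the root in which every internal node keeps
the state) and coverage (share of all state-bearers included); significance
comes from shuffling tip states and re-running reconstruction and search.

Ecological niches are coded from species' host-plant species sets and
feeding sites: two species overlap only when both components intersect
simultaneously, and niche ids are the connected components of that overlap
graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .treeio import AnnotationTable, Node, UltrametricTree

__all__ = [
    "CharacterMap",
    "ParsimonyResult",
    "Phylotype",
    "PhylotypeCriteria",
    "ShuffleTestResult",
    "NicheTable",
    "fitch",
    "resolve",
    "count_transitions",
    "enumerate_phylotypes",
    "phylotype_analysis",
    "shuffle_test",
    "code_niches",
    "proportion_splits_with_shift",
    "sister_pair_niche_overlap",
]

_BIG = np.int32(1 << 20)
_INF_LEVELS = 1 << 20


@dataclass
class CharacterMap:
    """A named categorical character: taxon -> state (None = missing)."""

    name: str
    states: tuple[str, ...]
    mapping: dict[str, str | None]

    def __post_init__(self):
        self.states = tuple(self.states)
        extra = {s for s in self.mapping.values() if s is not None} - set(self.states)
        if extra:
            raise ValueError(f"states outside vocabulary: {sorted(extra)}")

    @classmethod
    def from_annotations(
        cls,
        table: AnnotationTable,
        column: str,
        states: Sequence[str] | None = None,
        grouping: Mapping[str, str] | None = None,
        name: str | None = None,
    ) -> "CharacterMap":
        mapping = table.character(column, grouping=grouping)
        vocab = tuple(states) if states is not None else tuple(
            sorted({v for v in mapping.values() if v is not None})
        )
        return cls(name=name or column, states=vocab, mapping=dict(mapping))

    def combine(self, other: "CharacterMap") -> "CharacterMap":
        """Cartesian-product character (state "a & b"); missing if either
        component is missing."""
        taxa = set(self.mapping) & set(other.mapping)
        mapping = {}
        for t in taxa:
            a, b = self.mapping[t], other.mapping[t]
            mapping[t] = None if (a is None or b is None) else f"{a} & {b}"
        vocab = tuple(f"{a} & {b}" for a in self.states for b in other.states)
        used = {v for v in mapping.values() if v is not None}
        vocab = tuple(v for v in vocab if v in used)
        return CharacterMap(
            name=f"{self.name} & {other.name}", states=vocab, mapping=mapping
        )

    def present_taxa(self) -> list[str]:
        return [t for t, s in self.mapping.items() if s is not None]


# ---------------------------------------------------------------------------
# Batched reconstruction engine
# ---------------------------------------------------------------------------
#
# All reconstruction paths (the observed character and every shuffled
# replicate) run through one vectorized unit-cost Sankoff implementation that
# processes B tip-state assignments at once; the observed character is simply
# the B=1 case.  This keeps the permutation test affordable and guarantees
# the null replicates use the identical resolution rules.

class _TreeArrays:
    """Postorder-indexed topology shared across batches."""

    def __init__(self, tree: UltrametricTree):
        self.tree = tree
        self.nodes = list(tree.postorder())
        self.n = len(self.nodes)
        self.children = [[c.index for c in nd.children] for nd in self.nodes]
        self.is_tip = np.array([nd.is_tip for nd in self.nodes])
        self.tip_indices = [nd.index for nd in self.nodes if nd.is_tip]
        self.internal_children = [
            [c.index for c in nd.children if c.children] for nd in self.nodes
        ]
        # max number of generations below each node that contain internal nodes
        self.levels = np.zeros(self.n, dtype=np.int64)
        for nd in self.nodes:  # postorder: children first
            ic = self.internal_children[nd.index]
            self.levels[nd.index] = 1 + max((self.levels[j] for j in ic), default=-1) if ic else 0


def _batch_reconstruct(ta: _TreeArrays, tip_states: np.ndarray, n_states: int, mode: str):
    """Vectorized Sankoff + ACCTRAN/DELTRAN over B assignments.

    ``tip_states``: (n_tips_in_postorder_order, B) int array.
    Returns (state (n,B), score (B,), cost (n,S,B)).

    Ties among equally parsimonious states are broken toward the state most
    frequent among the node's subtree tips (symmetric under state
    relabeling, unlike a fixed vocabulary order which would bias every
    reconstruction toward the first state), then by vocabulary order.
    """
    if mode not in ("acctran", "deltran"):
        raise ValueError(f"unknown resolution mode {mode!r}")
    B = tip_states.shape[1]
    n, S = ta.n, n_states
    cost = np.empty((n, S, B), dtype=np.int32)
    freq = np.empty((n, S, B), dtype=np.int32)  # subtree tip-state counts
    cols = np.arange(B)

    tip_row = 0
    for i, nd in enumerate(ta.nodes):
        if ta.is_tip[i]:
            c = np.full((S, B), _BIG, dtype=np.int32)
            c[tip_states[tip_row], cols] = 0
            cost[i] = c
            f = np.zeros((S, B), dtype=np.int32)
            f[tip_states[tip_row], cols] = 1
            freq[i] = f
            tip_row += 1
        else:
            acc = np.zeros((S, B), dtype=np.int32)
            facc = np.zeros((S, B), dtype=np.int32)
            for j in ta.children[i]:
                cj = cost[j]
                acc += np.minimum(cj, cj.min(axis=0, keepdims=True) + 1)
                facc += freq[j]
            cost[i] = acc
            freq[i] = facc

    def pick(mask, i):
        # most frequent allowed state; np.argmax keeps vocabulary order on ties
        return np.argmax(np.where(mask, freq[i] + 1, 0), axis=0)

    state = np.empty((n, B), dtype=np.int32)
    root = ta.n - 1
    score = cost[root].min(axis=0)
    state[root] = pick(cost[root] == score, root)
    for i in range(n - 1, -1, -1):  # reversed postorder: parents before children
        ps = state[i]
        for j in ta.children[i]:
            if ta.is_tip[j]:
                state[j] = np.argmin(cost[j], axis=0)  # the observed state
                continue
            t = cost[j] + 1
            t[ps, cols] -= 1
            m = t.min(axis=0)
            allowed = t == m
            if mode == "acctran":
                alt = allowed.copy()
                alt[ps, cols] = False
                any_alt = alt.any(axis=0)
                state[j] = np.where(any_alt, pick(alt, j), ps)
            else:
                ps_ok = allowed[ps, cols]
                state[j] = np.where(ps_ok, ps, pick(allowed, j))
    return state, score, cost


def _batch_phylotype_stats(ta: _TreeArrays, state: np.ndarray):
    """Size, Different and Persistence per node per batch.

    Size[v] = tips joined to v by a path monochrome in v's state;
    Different[v] = maximal embedded subtrees with another root state;
    Persistence[v] = consecutive internal-node generations below v in which
    every internal node keeps v's state (counting stops at the first
    generation containing no internal node).
    """
    n, B = state.shape
    size = np.zeros((n, B), dtype=np.int64)
    diff = np.zeros((n, B), dtype=np.int64)
    persist = np.zeros((n, B), dtype=np.int64)
    # clean levels below each node ignoring exhaustion (INF = never violated);
    # a subtree that simply runs out of internal nodes imposes no constraint
    # on its ancestors, so the uncapped value is what propagates upward
    hinf = np.zeros((n, B), dtype=np.int64)
    for i, nd in enumerate(ta.nodes):
        if ta.is_tip[i]:
            size[i] = 1
            continue
        sz = np.zeros(B, dtype=np.int64)
        df = np.zeros(B, dtype=np.int64)
        for j in ta.children[i]:
            match = state[j] == state[i]
            sz += np.where(match, size[j], 0)
            df += np.where(match, diff[j], 1)
        size[i] = sz
        diff[i] = df
        ic = ta.internal_children[i]
        if not ic:
            hinf[i] = _INF_LEVELS
            persist[i] = 0
            continue
        ok = np.ones(B, dtype=bool)
        gmin = np.full(B, _INF_LEVELS, dtype=np.int64)
        for j in ic:
            ok &= state[j] == state[i]
            gmin = np.minimum(gmin, hinf[j])
        hinf[i] = np.where(ok, np.minimum(1 + gmin, _INF_LEVELS), 0)
        persist[i] = np.minimum(hinf[i], ta.levels[i])
    return size, diff, persist


# ---------------------------------------------------------------------------
# Public parsimony API
# ---------------------------------------------------------------------------

@dataclass
class ParsimonyResult:
    """Fitch sets, parsimony score and the data needed for resolution.

    ``tree`` is the reconstruction tree: the input pruned to the taxa with an
    observed state (missing tips do not participate).
    """

    tree: UltrametricTree
    charmap: CharacterMap
    node_sets: dict[int, frozenset]          # node postorder index -> Fitch set
    score: int
    _arrays: "_TreeArrays" = field(repr=False)
    _tip_states: np.ndarray = field(repr=False)


def fitch(tree: UltrametricTree, charmap: CharacterMap) -> ParsimonyResult:
    """Classic bottom-up Fitch pass: per-node state sets and the parsimony
    score (number of union events).  Tips with missing state are pruned
    first; an all-missing character is an error."""
    tree.require_binary()
    present = [t for t in tree.tip_labels() if charmap.mapping.get(t) is not None]
    if not present:
        raise ValueError(f"character {charmap.name!r}: all tips missing")
    work = tree.prune_to_tips(present) if len(present) < tree.n_tips else tree.copy()

    state_index = {s: i for i, s in enumerate(charmap.states)}
    sets: dict[int, frozenset] = {}
    score = 0
    for node in work.postorder():
        if node.is_tip:
            sets[node.index] = frozenset({charmap.mapping[node.label]})
        else:
            a, b = (sets[c.index] for c in node.children)
            inter = a & b
            if inter:
                sets[node.index] = inter
            else:
                sets[node.index] = a | b
                score += 1

    ta = _TreeArrays(work)
    tip_states = np.array(
        [[state_index[charmap.mapping[ta.nodes[i].label]]] for i in ta.tip_indices],
        dtype=np.int32,
    )
    return ParsimonyResult(
        tree=work, charmap=charmap, node_sets=sets, score=score,
        _arrays=ta, _tip_states=tip_states,
    )


def resolve(result: ParsimonyResult, mode: str = "acctran") -> dict[Node, str]:
    """Resolve ambiguous reconstructions: ACCTRAN prefers a change on every
    edge where one is free, DELTRAN keeps the parent state whenever it is
    optimal.  Both realize exactly ``result.score`` changes."""
    state, score, _ = _batch_reconstruct(
        result._arrays, result._tip_states, len(result.charmap.states), mode.lower()
    )
    assert int(score[0]) == result.score
    vocab = result.charmap.states
    return {nd: vocab[state[nd.index, 0]] for nd in result._arrays.nodes}


def changed_edges(result: ParsimonyResult, mode: str = "acctran") -> set[tuple[int, int]]:
    """(parent index, child index) pairs whose states differ under ``mode``."""
    states = resolve(result, mode)
    return {
        (nd.parent.index, nd.index)
        for nd in result.tree.postorder()
        if nd.parent is not None and states[nd] != states[nd.parent]
    }


def count_transitions(tree: UltrametricTree, charmap: CharacterMap, mode: str = "acctran") -> int:
    """Number of character-state transitions on the tree = the parsimony
    score (identical under either resolution)."""
    result = fitch(tree, charmap)
    assert len(changed_edges(result, mode)) == result.score
    return result.score


# ---------------------------------------------------------------------------
# Phylotypes
# ---------------------------------------------------------------------------

@dataclass
class PhylotypeCriteria:
    """Selection thresholds for phylotype search.

    ``min_size`` is mandatory; ``min_size_over_different`` compares Size to
    Different (Different = 0 passes any ratio); ``min_persistence`` requires
    that many monochrome internal-node generations; ``min_support`` masks out
    phylotype roots whose support is below the threshold (nodes without a
    support value pass).
    """

    min_size: int = 3
    min_size_over_different: float = 1.0
    min_persistence: int = 1
    min_support: float | None = 80.0

    def __post_init__(self):
        if self.min_size is None or self.min_size < 1:
            raise ValueError("the Size criterion is mandatory (min_size >= 1)")


@dataclass
class Phylotype:
    root_index: int
    state: str
    members: tuple[str, ...]
    size: int
    persistence: int
    different: int
    coverage: float          # percent of all taxa bearing the state
    p_value: float | None = None
    p_value_corrected: float | None = None

    @property
    def size_over_different(self) -> float:
        return math.inf if self.different == 0 else self.size / self.different


def _support_ok(node: Node, min_support: float | None) -> bool:
    return min_support is None or node.support is None or node.support >= min_support


def _monochrome_members(tree: UltrametricTree, node: Node, states: Mapping[Node, str]) -> list[str]:
    s = states[node]
    out = []
    stack = [node] if not node.is_tip else []
    while stack:
        nd = stack.pop()
        for c in nd.children:
            if states[c] != s:
                continue
            if c.is_tip:
                out.append(c.label)
            else:
                stack.append(c)
    return out


def enumerate_phylotypes(
    tree: UltrametricTree,
    resolved_states: Mapping[Node, str],
    criteria: PhylotypeCriteria | None = None,
) -> list[Phylotype]:
    """All maximal non-nested phylotypes satisfying the criteria.

    For every internal node v with resolved state s, the candidate phylotype
    collects the tips whose whole path to v is labeled s.  Candidates whose
    root lies inside a retained phylotype of the same state are absorbed.
    Coverage is the percentage of all tips bearing s that are members.
    """
    criteria = criteria or PhylotypeCriteria()
    state_counts: dict[str, int] = {}
    for t in tree.tips():
        state_counts[resolved_states[t]] = state_counts.get(resolved_states[t], 0) + 1

    ta = _TreeArrays(tree)
    idx_state = np.array(
        [[_state_id(resolved_states[nd])] for nd in ta.nodes], dtype=np.int32
    )
    # reuse the batched stats with the already-resolved states (B=1)
    size, diff, persist = _batch_phylotype_stats(ta, idx_state)

    retained: dict[Node, str] = {}
    out: list[Phylotype] = []
    for node in tree.preorder():
        if node.is_tip:
            continue
        s = resolved_states[node]
        if not _support_ok(node, criteria.min_support):
            continue
        sz = int(size[node.index, 0])
        df = int(diff[node.index, 0])
        ps = int(persist[node.index, 0])
        if sz < criteria.min_size or ps < criteria.min_persistence:
            continue
        if df > 0 and sz / df < criteria.min_size_over_different:
            continue
        anc = node.parent
        absorbed = False
        while anc is not None:
            if anc in retained and retained[anc] == s:
                absorbed = True
                break
            anc = anc.parent
        if absorbed:
            continue
        retained[node] = s
        members = tuple(sorted(_monochrome_members(tree, node, resolved_states)))
        assert len(members) == sz
        out.append(
            Phylotype(
                root_index=node.index,
                state=s,
                members=members,
                size=sz,
                persistence=ps,
                different=df,
                coverage=100.0 * sz / state_counts.get(s, sz),
            )
        )
    return out


_STATE_IDS: dict[str, int] = {}


def _state_id(state: str) -> int:
    # stable small integers for arbitrary state labels within one call chain
    if state not in _STATE_IDS:
        _STATE_IDS[state] = len(_STATE_IDS)
    return _STATE_IDS[state]


def phylotype_analysis(
    tree: UltrametricTree,
    charmap: CharacterMap,
    criteria: PhylotypeCriteria | None = None,
    mode: str = "acctran",
) -> tuple[list[Phylotype], ParsimonyResult, dict[Node, str]]:
    """Reconstruct, resolve and enumerate phylotypes in one step."""
    result = fitch(tree, charmap)
    states = resolve(result, mode)
    phylos = enumerate_phylotypes(result.tree, states, criteria)
    return phylos, result, states


# ---------------------------------------------------------------------------
# Shuffle significance
# ---------------------------------------------------------------------------

@dataclass
class ShuffleTestResult:
    """Permutation null for phylotypes and for the parsimony score.

    Per-state p-values give the fraction of shuffled datasets containing a
    same-state criteria-passing phylotype at least as large as the observed
    one; score p-values locate the observed transition count in the null
    score distribution (low = fewer changes than chance, i.e. phylogenetic
    conservatism).  Both the raw fraction and the (count+1)/(n+1)-corrected
    value are reported.
    """

    observed_phylotypes: list[Phylotype]
    observed_score: int
    null_scores: np.ndarray
    state_p: dict[str, dict[str, float]]
    score_p_low: float
    score_p_low_corrected: float
    score_p_high: float
    score_p_high_corrected: float
    n_iter: int


def shuffle_test(
    tree: UltrametricTree,
    charmap: CharacterMap,
    criteria: PhylotypeCriteria | None = None,
    n_iter: int = 1000,
    seed: int = 0,
    mode: str = "acctran",
    chunk: int = 256,
) -> ShuffleTestResult:
    """Shuffle tip states (fixed frequencies), re-reconstruct, re-search.

    Every replicate runs the same resolution and phylotype criteria as the
    observed data.  Nested same-state candidates never exceed their
    enclosing candidate's size, so existence of a criteria-passing phylotype
    of at least the observed size can be tested without the absorption step.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    criteria = criteria or PhylotypeCriteria()
    phylos, result, states = phylotype_analysis(tree, charmap, criteria, mode)
    work = result.tree
    ta = result._arrays
    observed = result._tip_states[:, 0]
    S = len(charmap.states)
    rng = np.random.default_rng(seed)

    support_ok = np.array(
        [_support_ok(nd, criteria.min_support) and not nd.is_tip for nd in ta.nodes]
    )
    # observed target size per state (max retained phylotype size)
    obs_size: dict[str, int] = {}
    for ph in phylos:
        obs_size[ph.state] = max(obs_size.get(ph.state, 0), ph.size)

    null_scores = np.empty(n_iter, dtype=np.int64)
    exceed = {s: 0 for s in obs_size}
    done = 0
    # tip-state frequencies across the tree are invariant per column
    while done < n_iter:
        b = min(chunk, n_iter - done)
        tips = np.empty((observed.size, b), dtype=np.int32)
        for col in range(b):
            tips[:, col] = rng.permutation(observed)
        state, score, _ = _batch_reconstruct(ta, tips, S, mode)
        null_scores[done:done + b] = score
        if obs_size:
            size, diff, persist = _batch_phylotype_stats(ta, state)
            qual = (
                support_ok[:, None]
                & (size >= criteria.min_size)
                & (persist >= criteria.min_persistence)
                & ((diff == 0) | (size >= criteria.min_size_over_different * diff))
            )
            for s, target in obs_size.items():
                si = charmap.states.index(s)
                hit = ((state == si) & qual & (size >= target)).any(axis=0)
                exceed[s] += int(hit.sum())
        done += b

    state_p = {}
    for s, target in obs_size.items():
        c = exceed[s]
        state_p[s] = {
            "observed_size": float(target),
            "p_raw": c / n_iter,
            "p_corrected": (c + 1) / (n_iter + 1),
        }
    for ph in phylos:
        ph.p_value = state_p[ph.state]["p_raw"]
        ph.p_value_corrected = state_p[ph.state]["p_corrected"]

    obs_score = result.score
    lo = int((null_scores <= obs_score).sum())
    hi = int((null_scores >= obs_score).sum())
    return ShuffleTestResult(
        observed_phylotypes=phylos,
        observed_score=obs_score,
        null_scores=null_scores,
        state_p=state_p,
        score_p_low=lo / n_iter,
        score_p_low_corrected=(lo + 1) / (n_iter + 1),
        score_p_high=hi / n_iter,
        score_p_high_corrected=(hi + 1) / (n_iter + 1),
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# Niche coding
# ---------------------------------------------------------------------------

@dataclass
class NicheTable:
    """Species -> niche id(s) under the simultaneous-overlap rule.

    ``bridges`` lists species connecting otherwise-disjoint niche parts
    (articulation points of the overlap graph).  Policy ``components`` gives
    one id per connected component; ``split`` gives bridge species one id per
    part they join; ``sister`` reassigns each bridge the id of the part
    containing its sister species when a cherry partner exists.
    """

    niche_ids: dict[str, tuple[str, ...]]
    bridges: tuple[str, ...]
    policy: str
    graph: nx.Graph = field(repr=False)

    @property
    def n_niches(self) -> int:
        return len({i for ids in self.niche_ids.values() for i in ids})

    def charmap(self, name: str = "niche") -> CharacterMap:
        """Single-state character (first id for multi-id species)."""
        mapping = {sp: ids[0] for sp, ids in self.niche_ids.items()}
        vocab = tuple(sorted({i for ids in self.niche_ids.values() for i in ids}))
        return CharacterMap(name=name, states=vocab, mapping=mapping)

    def overlap(self, a: str, b: str) -> bool:
        return bool(set(self.niche_ids[a]) & set(self.niche_ids[b]))


def code_niches(
    species: Mapping[str, tuple[frozenset, frozenset]] | "pd.DataFrame",
    policy: str = "components",
    tree: UltrametricTree | None = None,
) -> NicheTable:
    """Code ecological niches from host-species sets and feeding sites.

    ``species`` maps species -> (host_species set, feeding_sites set), or is
    a species-view DataFrame with those columns.  Two species share an edge
    iff their host sets intersect AND their feeding sites intersect; niche
    ids are connected components (N1, N2, ... in sorted species order).
    Species with empty feeding sites are excluded with a warning.  The
    ``sister`` policy needs the species tree to find cherry partners.
    """
    import pandas as pd

    if isinstance(species, pd.DataFrame):
        species = {
            sp: (row["host_species"], row["feeding_sites"])
            for sp, row in species.iterrows()
        }
    usable = {}
    for sp, (hosts, sites) in species.items():
        if not sites or not hosts:
            import warnings

            warnings.warn(f"species {sp!r} has empty hosts or feeding sites; excluded from niche coding")
            continue
        usable[sp] = (frozenset(hosts), frozenset(sites))

    g = nx.Graph()
    g.add_nodes_from(sorted(usable))
    names = sorted(usable)
    for i, a in enumerate(names):
        ha, fa = usable[a]
        for b in names[i + 1:]:
            hb, fb = usable[b]
            if (ha & hb) and (fa & fb):
                g.add_edge(a, b)

    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: c[0])
    comp_id = {sp: f"N{k}" for k, comp in enumerate(components, start=1) for sp in comp}
    bridges = tuple(sorted(nx.articulation_points(g)))

    niche_ids = {sp: (comp_id[sp],) for sp in names}
    if policy == "components":
        pass
    elif policy in ("split", "sister"):
        for bridge in bridges:
            h = g.copy()
            h.remove_node(bridge)
            parts = [sorted(c) for c in nx.connected_components(h)]
            parts = [p for p in parts if set(p) & set(g[bridge])]
            part_ids = [f"{comp_id[bridge]}.{j}" for j in range(1, len(parts) + 1)]
            # re-label the members of each part with the sub-ids
            for pid, part in zip(part_ids, parts):
                for sp in part:
                    old = niche_ids[sp]
                    niche_ids[sp] = tuple(pid if o == comp_id[bridge] else o for o in old)
            if policy == "split":
                niche_ids[bridge] = tuple(part_ids)
            else:  # sister: adopt the partner's part when a cherry exists
                chosen = part_ids[0]
                if tree is not None:
                    from .treeio import sister_pairs

                    partner = None
                    for a, b, _ in sister_pairs(tree):
                        if a == bridge:
                            partner = b
                        elif b == bridge:
                            partner = a
                    if partner is not None:
                        for pid, part in zip(part_ids, parts):
                            if partner in part:
                                chosen = pid
                                break
                niche_ids[bridge] = (chosen,)
    else:
        raise ValueError(f"unknown bridge policy {policy!r}")

    return NicheTable(niche_ids=niche_ids, bridges=bridges, policy=policy, graph=g)


def proportion_splits_with_shift(
    tree: UltrametricTree, niche_charmap: CharacterMap, mode: str = "acctran"
) -> float:
    """Share of speciation events accompanied by a niche shift: parsimony
    transition count over the number of internal nodes (= tips - 1)."""
    tree.require_binary()
    k = count_transitions(tree, niche_charmap, mode)
    return k / (tree.n_tips - 1)


def sister_pair_niche_overlap(
    tree: UltrametricTree, niches: NicheTable
) -> tuple[int, int]:
    """(total cherries, cherries whose species share no niche id)."""
    from .treeio import sister_pairs

    pairs = sister_pairs(tree)
    non_overlap = 0
    for a, b, _ in pairs:
        if a in niches.niche_ids and b in niches.niche_ids and not niches.overlap(a, b):
            non_overlap += 1
        elif a not in niches.niche_ids or b not in niches.niche_ids:
            non_overlap += 0  # unknown niches are not counted as divergent
    return len(pairs), non_overlap
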