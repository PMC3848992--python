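"""Synthetic datasets with known truth.

The generators reproduce the statistical structure the downstream analyses
assume, so that every stage can be tested against ground truth:

* a pure-birth (Yule) species tree;
* a mixed tree in which each species tip is replaced by a single-population
  coalescent genealogy of its specimens, with an enforced age gap between the
  deepest within-species coalescence and the shallowest speciation -- the
  "branching-rate shift at a threshold" structure that single-threshold
  delimitation assumes;
* discrete characters evolving under a symmetric Markov chain, with the
  realized number of change events recorded;
* geographic ranges generated either by allopatric splitting followed by
  expansion, or independently of the tree.

All randomness flows from a single seed; each sub-process derives its own
named stream so components are independently reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np

from .treeio import (
    AnnotationTable,
    Node,
    UltrametricTree,
    FEEDING_SITES,
    HOST_GENERA,
    ZONES,
)

__all__ = [
    "SimTruth",
    "FixtureProfile",
    "FixtureDataset",
    "simulate_yule_tree",
    "simulate_coalescent_tree",
    "simulate_gmyc_tree",
    "simulate_mk_character",
    "simulate_ranges",
    "make_fixture_dataset",
    "substream",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of a master seed."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(name.encode())])


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    assignment: dict[str, str]                 # tip -> true species
    true_threshold_age: float | None = None    # midpoint of the separation gap
    max_coalescent_age: float | None = None    # deepest within-species node
    min_speciation_age: float | None = None    # shallowest species-tree node
    realized_transitions: dict[str, int] = field(default_factory=dict)
    range_history: dict[str, list[str]] = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_species(self) -> int:
        return len(set(self.assignment.values()))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


class SeparationError(RuntimeError):
    """Within-species coalescent heights could not be kept below the species
    divergence ages; use a smaller ``coalescent_depth_scale``."""


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_yule_tree(
    n_species: int,
    birth_rate: float = 1.0,
    seed: int | np.random.Generator = 0,
    label_prefix: str = "S",
) -> UltrametricTree:
    """Pure-birth ultrametric tree on ``n_species`` tips.

    The process starts at the root with two lineages; with ``k`` lineages the
    waiting time to the next split is exponential with rate
    ``birth_rate * k``, and a uniformly chosen lineage splits.  After the
    n-th lineage appears one further waiting time is drawn to place the
    present, so for n=2 the root age is a single Exp(2*birth_rate) draw.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    root = Node()
    t = 0.0
    active: list[tuple[Node, float]] = []  # (pendant node placeholder parent, birth time)
    for _ in range(2):
        child = Node()
        root.add_child(child)
        active.append((child, 0.0))
    k = 2
    while k < n_species:
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node, birth = active.pop(i)
        node.length = t - birth
        for _ in range(2):
            child = Node()
            node.add_child(child)
            active.append((child, t))
        k += 1
    t += rng.exponential(1.0 / (birth_rate * k))
    for node, birth in active:
        node.length = t - birth
    i = 0
    stack = [root]
    while stack:  # label tips in preorder (left-to-right) before validation
        node = stack.pop()
        if not node.children:
            i += 1
            node.label = f"{label_prefix}{i}"
        else:
            stack.extend(reversed(node.children))
    return UltrametricTree(root)


def _coalescent_subtree(
    n: int, scale: float, rng: np.random.Generator, labels: Sequence[str]
) -> tuple[Node, float]:
    """Single-population coalescent genealogy; returns (root, height).

    With ``j`` lineages the waiting time to the next coalescence is
    exponential with rate ``j*(j-1)/2 / scale`` (so ``scale`` is the expected
    pairwise coalescence time).
    """
    lineages = [(Node(label=lab), 0.0) for lab in labels]
    t = 0.0
    while len(lineages) > 1:
        j = len(lineages)
        t += rng.exponential(scale / (j * (j - 1) / 2.0))
        i1, i2 = sorted(rng.choice(j, size=2, replace=False))
        n2, b2 = lineages.pop(i2)
        n1, b1 = lineages.pop(i1)
        parent = Node()
        n1.length = t - b1
        n2.length = t - b2
        parent.add_child(n1)
        parent.add_child(n2)
        lineages.append((parent, t))
    return lineages[0][0], t


def simulate_coalescent_tree(
    n_tips: int, depth_scale: float = 1.0, seed: int | np.random.Generator = 0,
    label_prefix: str = "I",
) -> UltrametricTree:
    """Ultrametric genealogy of a single panmictic population (the
    single-process null of the mixed model)."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [f"{label_prefix}{i}" for i in range(1, n_tips + 1)]
    root, _ = _coalescent_subtree(n_tips, depth_scale, rng, labels)
    return UltrametricTree(root)


def _default_specimen_sampler(rng: np.random.Generator) -> int:
    """Zero-truncated geometric with mean 4, clipped at 18 -- a sampling
    profile of one-to-many specimens per species with most species having a
    handful of representatives."""
    return int(min(rng.geometric(1.0 / 4.0), 18))


def simulate_gmyc_tree(
    n_species: int,
    specimens_per_species: int | Sequence[int] | Callable | None = None,
    birth_rate: float = 1.0,
    coalescent_depth_scale: float | None = None,
    separation_factor: float = 1.0,
    seed: int = 0,
    max_resample: int = 1000,
) -> tuple[UltrametricTree, SimTruth]:
    """Mixed Yule-coalescent specimen tree with known species boundaries.

    Each tip of a Yule species tree is replaced by a coalescent genealogy of
    its specimens.  Genealogy heights are resampled until the deepest
    within-species coalescence is below ``min_speciation_age /
    separation_factor``, which makes the single-threshold model identifiable;
    if that fails after ``max_resample`` draws a :class:`SeparationError`
    advises a smaller ``coalescent_depth_scale``.
    When ``coalescent_depth_scale`` is None it is set adaptively to
    ``0.05 * min_speciation_age / separation_factor``.
    """
    rng_tree = substream(seed, "species-tree")
    rng_coal = substream(seed, "coalescent")
    rng_m = substream(seed, "specimen-counts")

    species_tree = simulate_yule_tree(n_species, birth_rate, rng_tree, label_prefix="SP")
    min_spec_age = min(n.age for n in species_tree.internal_nodes())
    limit = min_spec_age / separation_factor
    if coalescent_depth_scale is None:
        coalescent_depth_scale = 0.05 * limit

    if specimens_per_species is None:
        sampler = _default_specimen_sampler
    elif isinstance(specimens_per_species, int):
        sampler = lambda rng: specimens_per_species
    elif callable(specimens_per_species):
        sampler = specimens_per_species
    else:
        counts = list(specimens_per_species)
        if len(counts) != n_species:
            raise ValueError("specimen count sequence must have length n_species")
        it = iter(counts)
        sampler = lambda rng: next(it)

    root = _copy(species_tree.root)
    new_tree = UltrametricTree(root)
    assignment: dict[str, str] = {}
    max_coal = 0.0
    for tip in list(new_tree.tips()):
        sp = tip.label
        m = int(sampler(rng_m))
        if m < 1:
            raise ValueError("specimens per species must be >= 1")
        if m == 1:
            tip.label = f"{sp}_1"
            assignment[tip.label] = sp
            continue
        labels = [f"{sp}_{i}" for i in range(1, m + 1)]
        for attempt in range(max_resample):
            sub, height = _coalescent_subtree(m, coalescent_depth_scale, rng_coal, labels)
            if height < limit:
                break
        else:
            raise SeparationError(
                f"could not place a {m}-specimen genealogy below age {limit:.4g} "
                f"after {max_resample} draws; reduce coalescent_depth_scale"
            )
        if attempt > 0:
            import warnings

            warnings.warn(f"resampled genealogy for {sp} {attempt} time(s) to enforce separation")
        # graft: genealogy root sits at `height`, pendant branch shortens
        sub.length = tip.length - height
        parent = tip.parent
        parent.children[parent.children.index(tip)] = sub
        sub.parent = parent
        for lab in labels:
            assignment[lab] = sp
        max_coal = max(max_coal, height)

    tree = UltrametricTree(new_tree.root)
    truth = SimTruth(
        assignment=assignment,
        true_threshold_age=0.5 * (max_coal + min_spec_age),
        max_coalescent_age=max_coal,
        min_speciation_age=min_spec_age,
        seed=seed,
    )
    return tree, truth


def _copy(node: Node) -> Node:
    new = Node(node.label, node.length, node.support)
    for c in node.children:
        new.add_child(_copy(c))
    return new


# ---------------------------------------------------------------------------
# Characters
# ---------------------------------------------------------------------------

def simulate_mk_character(
    tree: UltrametricTree,
    n_states: int,
    rate: float,
    seed: int | np.random.Generator = 0,
    name: str = "char",
    states: Sequence[str] | None = None,
) -> tuple["CharacterMap", int]:
    """Symmetric k-state Markov character evolved along the tree.

    The root state is uniform; on each edge the number of change events is
    Poisson(rate * branch length) and every event jumps to a uniformly chosen
    different state.  Returns the tip character map and the realized number
    of change events (every event changes the state, so this equals the count
    of substitutions and is an upper bound for any parsimony score).
    """
    from .charevo import CharacterMap

    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vocab = tuple(states) if states is not None else tuple(f"s{i}" for i in range(n_states))
    if len(vocab) != n_states:
        raise ValueError("states vocabulary length must equal n_states")

    node_state: dict[Node, int] = {tree.root: int(rng.integers(n_states))}
    transitions = 0
    for node in tree.preorder():
        if node is tree.root:
            continue
        s = node_state[node.parent]
        n_events = rng.poisson(rate * node.length) if rate > 0 else 0
        for _ in range(n_events):
            jump = int(rng.integers(n_states - 1))
            s = jump if jump < s else jump + 1
            transitions += 1
        node_state[node] = s
    mapping = {t.label: vocab[node_state[t]] for t in tree.tips()}
    return CharacterMap(name=name, states=vocab, mapping=mapping), transitions


# ---------------------------------------------------------------------------
# Geographic ranges
# ---------------------------------------------------------------------------

def simulate_ranges(
    tree: UltrametricTree,
    mode: str = "allopatric",
    n_zones: int = 8,
    expansion_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    vocabulary: Sequence[str] | None = None,
) -> tuple[dict[str, frozenset], dict[int, frozenset]]:
    """Tip zone sets under an allopatric-splitting or a tree-independent model.

    Allopatric mode: the root holds the full zone vocabulary; at every split
    the parent's current set is partitioned into two disjoint nonempty random
    subsets, sized in proportion to the daughters' descendant tip counts so
    that no lineage runs out of zones while the vocabulary can still cover
    its tips (when only one zone is left both daughters inherit it --
    sympatric at birth), and along each branch lineages gain absent zones at
    ``expansion_rate`` per unit time.  Random mode: each tip draws a zone set
    independently of the tree (each zone included with probability 0.25 --
    a mean range of two zones out of eight, typical of range-restricted
    species -- resampling empty sets).

    Note that tree-independent *tip* ranges do not make clade-level overlap
    independent of node age: older nodes subtend larger clades whose zone
    unions almost surely intersect, so the overlap-age regression has a real
    positive effect even in random mode.  Calibration experiments that need
    the no-effect null must additionally permute the overlap responses
    across nodes.

    Returns ``(tip_zones, node_history)`` where ``node_history`` maps node
    postorder indices to the zone set at the *start* of each daughter lineage.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_zones < 2:
        raise ValueError("n_zones must be >= 2")
    vocab = tuple(vocabulary) if vocabulary is not None else tuple(f"Z{i}" for i in range(1, n_zones + 1))
    if len(vocab) != n_zones:
        raise ValueError("vocabulary length must equal n_zones")

    if mode == "random":
        tips = {}
        for t in tree.tips():
            while True:
                s = frozenset(z for z in vocab if rng.random() < 0.25)
                if s:
                    break
            tips[t.label] = s
        return tips, {}

    if mode != "allopatric":
        raise ValueError(f"unknown mode {mode!r}")

    def expand(zoneset: frozenset, length: float) -> frozenset:
        if expansion_rate <= 0 or length <= 0:
            return zoneset
        gains = rng.poisson(expansion_rate * length)
        s = set(zoneset)
        for _ in range(gains):
            absent = [z for z in vocab if z not in s]
            if not absent:
                break
            s.add(absent[int(rng.integers(len(absent)))])
        return frozenset(s)

    tips_below = {n: len(tree.clade_tips(n)) for n in tree.postorder()}
    tip_zones: dict[str, frozenset] = {}
    history: dict[int, frozenset] = {}
    # start set at the bottom of each branch, propagated preorder
    start: dict[Node, frozenset] = {tree.root: frozenset(vocab)}
    for node in tree.preorder():
        current = expand(start[node], node.length) if node is not tree.root else start[node]
        history[node.index] = current
        if node.is_tip:
            tip_zones[node.label] = current
            continue
        zones = sorted(current)
        L = len(zones)
        if L < 2:
            parts = (frozenset(zones), frozenset(zones))  # sympatric at birth
        else:
            c1, c2 = (tips_below[c] for c in node.children[:2])
            # daughters get zone shares able to cover their tips when possible
            lo, hi = 1, L - 1
            if L >= c1 + c2:
                lo, hi = c1, L - c2
            n1 = int(rng.integers(lo, hi + 1))
            perm = list(rng.permutation(L))
            left = frozenset(zones[i] for i in perm[:n1])
            right = frozenset(zones[i] for i in perm[n1:])
            parts = (left, right)
        for child, part in zip(node.children, parts):
            start[child] = part
    return tip_zones, history


# ---------------------------------------------------------------------------
# Complete fixture dataset
# ---------------------------------------------------------------------------

@dataclass
class FixtureProfile:
    """Study-scale template for the complete toy dataset: a few dozen species
    sampled with one-to-many specimens each, a conservative host-genus
    character, a labile feeding-site character, host species nested within
    genus, and ranges from an 8-zone vocabulary."""

    n_species: int = 56
    birth_rate: float = 1.0
    separation_factor: float = 5.0
    expected_host_genus_transitions: float = 10.0
    expected_feeding_site_transitions: float = 17.0
    hosts_per_genus: int = 6
    hosts_per_species_max: int = 3
    range_mode: str = "allopatric"
    expansion_rate: float = 1.0
    specimens_per_species: int | Sequence[int] | Callable | None = None
    zero_character_rates: bool = False


@dataclass
class FixtureDataset:
    tree: UltrametricTree
    annotations: AnnotationTable
    truth: SimTruth
    species_tree: UltrametricTree

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.tree.write(os.path.join(outdir, "specimens.nwk"))
        self.species_tree.write(os.path.join(outdir, "species.nwk"))
        self.annotations.to_tsv(os.path.join(outdir, "annotations.tsv"))
        self.truth.to_json(os.path.join(outdir, "truth.json"))


_NEARCTIC_ZONES = frozenset(ZONES[:4])
_PALEARCTIC_ZONES = frozenset(ZONES[4:7])


def _continent_of(zones: frozenset) -> str:
    if "Cosmopolitan" in zones:
        return "cosmopolitan"
    has_na = bool(zones & _NEARCTIC_ZONES)
    has_pa = bool(zones & _PALEARCTIC_ZONES)
    if has_na and has_pa:
        return "cosmopolitan"
    return "Nearctic" if has_na else "Palearctic"


def make_fixture_dataset(
    profile: FixtureProfile | None = None, seed: int = 0
) -> FixtureDataset:
    """A complete synthetic study: specimen tree, annotations, truth.

    Character rates are set so that the *expected* numbers of change events
    on the species tree match the profile (a conservative ~10-transition
    host-genus character versus a labile ~17-transition feeding-site
    character at the default 56-species scale); host species are drawn from
    per-genus pools so that ecological niches (host species set x feeding
    sites) show realistic partial overlaps.
    """
    profile = profile or FixtureProfile()
    tree, truth = simulate_gmyc_tree(
        profile.n_species,
        specimens_per_species=profile.specimens_per_species,
        birth_rate=profile.birth_rate,
        separation_factor=profile.separation_factor,
        seed=seed,
    )
    species = sorted(set(truth.assignment.values()))
    species_tree = prune_first(tree, truth.assignment)

    total_len = sum(n.length for n in species_tree.postorder() if n.parent is not None)
    if profile.zero_character_rates:
        rate_host = rate_feed = 0.0
    else:
        rate_host = profile.expected_host_genus_transitions / total_len
        rate_feed = profile.expected_feeding_site_transitions / total_len

    host_cm, k_host = simulate_mk_character(
        species_tree, len(HOST_GENERA), rate_host,
        substream(seed, "host-genus"), name="host_genus", states=HOST_GENERA,
    )
    feed_cm, k_feed = simulate_mk_character(
        species_tree, len(FEEDING_SITES), rate_feed,
        substream(seed, "feeding-site"), name="feeding_site", states=FEEDING_SITES,
    )
    truth.realized_transitions = {"host_genus": k_host, "feeding_site": k_feed}

    rng_hosts = substream(seed, "host-species")
    host_pools = {
        g: [f"{g}_sp{j}" for j in range(1, profile.hosts_per_genus + 1)]
        for g in HOST_GENERA
    }
    species_hosts: dict[str, frozenset] = {}
    for sp in species:
        genus = host_cm.mapping[sp]
        pool = host_pools[genus]
        k = 1 + int(rng_hosts.integers(profile.hosts_per_species_max))
        picks = rng_hosts.choice(len(pool), size=min(k, len(pool)), replace=False)
        species_hosts[sp] = frozenset(pool[i] for i in picks)

    tip_zones, history = simulate_ranges(
        species_tree,
        mode=profile.range_mode,
        n_zones=len(ZONES) - 1,  # "Cosmopolitan" is a policy token, not a simulated area
        expansion_rate=profile.expansion_rate,
        seed=substream(seed, "ranges"),
        vocabulary=ZONES[:-1],
    )
    truth.range_history = {str(i): sorted(z) for i, z in history.items()}

    rows = []
    for tip, sp in sorted(truth.assignment.items()):
        rows.append(
            {
                "taxon": tip,
                "species": sp,
                "host_genus": host_cm.mapping[sp],
                "host_species": species_hosts[sp],
                "feeding_sites": frozenset([feed_cm.mapping[sp]]),
                "zones": tip_zones[sp],
                "continent": _continent_of(tip_zones[sp]),
            }
        )
    import pandas as pd

    annotations = AnnotationTable(pd.DataFrame(rows))
    return FixtureDataset(tree=tree, annotations=annotations, truth=truth, species_tree=species_tree)


def prune_first(tree: UltrametricTree, assignment: Mapping[str, str]) -> UltrametricTree:
    """Species tree using the first specimen of each species (deterministic)."""
    from .treeio import prune_to_representatives

    return prune_to_representatives(tree, assignment, chooser="first")
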