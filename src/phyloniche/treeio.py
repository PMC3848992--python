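"""Ultrametric trees and specimen annotation tables.

This module provides the substrate every analysis stage consumes: a rooted
tree with branch lengths and node ages (height above the tip plane), plus the
per-specimen annotation table (species label, host plants, feeding sites,
geographic zones, continent).

Newick parsing and serialization are delegated to :mod:`dendropy`; the parsed
tree is converted into a lightweight node structure that the likelihood and
parsimony code can traverse cheaply.  Support values are read from internal
node labels when they are numeric (RAxML-style); non-numeric labels are kept
but ignored by the support mask.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "Node",
    "UltrametricTree",
    "AnnotationTable",
    "NewickError",
    "NotUltrametricError",
    "NotBinaryError",
    "parse_newick",
    "read_newick",
    "node_ages",
    "prune_to_representatives",
    "count_splits",
    "sister_pairs",
    "HOST_GENERA",
    "FEEDING_SITES",
    "CONTINENTS",
    "ZONES",
]

# Default categorical vocabularies for conifer-aphid style datasets: seven
# host-plant genus states, three feeding sites and eight geographic zones.
HOST_GENERA = (
    "Picea", "Pinus", "Abies", "Larix", "Cedrus", "Pseudotsuga", "Cupressaceae",
)
FEEDING_SITES = ("shoot", "branch", "trunk")
CONTINENTS = ("Nearctic", "Palearctic", "cosmopolitan")
ZONES = (
    "North America",
    "Western North America",
    "West of the Rockies",
    "East of the Rockies",
    "Europe",
    "Mediterranean",
    "Central Asia",
    "Cosmopolitan",
)

DEFAULT_ULTRAMETRIC_TOL = 1e-6  # relative to tree height


class NewickError(ValueError):
    """Malformed Newick input (carries the underlying parser message)."""


class NotUltrametricError(ValueError):
    """Raised when an analysis requiring equal root-to-tip depths receives a
    tree whose tip depths differ beyond tolerance."""


class NotBinaryError(ValueError):
    """Raised when an analysis requiring a fully bifurcating tree receives a
    polytomy (use :meth:`UltrametricTree.resolve_polytomies` first)."""


class Node:
    """A tree node: ``length`` is the branch to the parent (root: 0)."""

    __slots__ = ("label", "length", "support", "children", "parent", "age", "depth", "index")

    def __init__(self, label=None, length=0.0, support=None):
        self.label = label
        self.length = float(length)
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.age = 0.0
        self.depth = 0.0
        self.index = -1

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} age={self.age:.4g}>"


class UltrametricTree:
    """Rooted tree with branch lengths, node ages and optional support values.

    Node ages are heights above the tip plane (tips at ~0, root at tree
    height).  ``is_ultrametric`` records whether all root-to-tip path lengths
    agree within ``tol * height``; analyses that rely on age ordering call
    :meth:`require_ultrametric` and refuse otherwise.
    """

    def __init__(self, root: Node, tol: float = DEFAULT_ULTRAMETRIC_TOL):
        self.root = root
        self.tol = tol
        self._index()
        self._validate_labels()
        self._compute_ages()

    # -- construction ---------------------------------------------------

    def _index(self) -> None:
        self._postorder: list[Node] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                self._postorder.append(node)
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))
        for i, node in enumerate(self._postorder):
            node.index = i
        self._tips = [n for n in self._postorder if n.is_tip]

    def _validate_labels(self) -> None:
        labels = [t.label for t in self._tips]
        if any(not lab for lab in labels):
            raise ValueError("every tip must carry a nonempty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")

    def _compute_ages(self) -> None:
        for node in self.preorder():
            node.depth = 0.0 if node.parent is None else node.parent.depth + node.length
        depths = [t.depth for t in self._tips]
        self.height = max(depths) if depths else 0.0
        spread = (max(depths) - min(depths)) if depths else 0.0
        self.is_ultrametric = spread <= self.tol * max(self.height, 1e-300)
        for node in self._postorder:
            node.age = self.height - node.depth
        # snap tip ages to exactly zero when within tolerance
        if self.is_ultrametric:
            for t in self._tips:
                t.age = 0.0

    # -- basic accessors -------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    def tips(self) -> list[Node]:
        return list(self._tips)

    def tip_labels(self) -> list[str]:
        return [t.label for t in self._tips]

    def postorder(self) -> Iterator[Node]:
        return iter(self._postorder)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def internal_nodes(self) -> list[Node]:
        return [n for n in self._postorder if not n.is_tip]

    def find_tip(self, label: str) -> Node:
        for t in self._tips:
            if t.label == label:
                return t
        raise KeyError(label)

    def clade_tips(self, node: Node) -> list[Node]:
        """Tips descending from ``node`` (the node itself when it is a tip)."""
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_tip:
                out.append(n)
            else:
                stack.extend(reversed(n.children))
        return out

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def require_ultrametric(self) -> None:
        if not self.is_ultrametric:
            raise NotUltrametricError(
                "tree tip depths differ beyond tolerance; this analysis "
                "requires an ultrametric tree"
            )

    def require_binary(self) -> None:
        if not self.is_binary:
            raise NotBinaryError(
                "tree contains polytomies; call resolve_polytomies() first"
            )

    # -- manipulation ----------------------------------------------------

    def copy(self) -> "UltrametricTree":
        return UltrametricTree(_copy_subtree(self.root), tol=self.tol)

    def resolve_polytomies(self) -> "UltrametricTree":
        """Return a binary tree: polytomies split with zero-length internal
        edges in stable child order (a logged warning is emitted)."""
        root = _copy_subtree(self.root)
        changed = False
        stack = [root]
        while stack:
            node = stack.pop()
            while len(node.children) > 2:
                changed = True
                a = node.children.pop()
                b = node.children.pop()
                joint = Node(length=0.0)
                joint.add_child(b)
                joint.add_child(a)
                node.add_child(joint)
            stack.extend(node.children)
        if changed:
            warnings.warn("polytomies resolved into zero-length binary nodes")
        return UltrametricTree(root, tol=self.tol)

    def prune_to_tips(self, keep: Iterable[str]) -> "UltrametricTree":
        """Subtree induced by the tip labels in ``keep``; unary nodes are
        suppressed with branch-length addition, so node ages are preserved."""
        keep = set(keep)
        missing = keep - set(self.tip_labels())
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        if not keep:
            raise ValueError("cannot prune to an empty tip set")
        root = _copy_subtree(self.root)
        root = _prune(root, keep)
        if root.is_tip:
            warnings.warn("pruned tree is a single-tip degenerate tree")
        # suppress a unary root by re-rooting at its child
        while len(root.children) == 1:
            child = root.children[0]
            child.length += root.length
            child.parent = None
            root = child
        return UltrametricTree(root, tol=self.tol)

    # -- serialization ---------------------------------------------------

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                body = _quote_label(node.label)
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = ""
                if include_support and node.support is not None:
                    label = _fmt_number(node.support)
                elif node.label:
                    label = _quote_label(node.label)
                body = f"({inner}){label}"
            if node.parent is None:
                return f"{body}:{_fmt_number(node.length)}"
            return f"{body}:{_fmt_number(node.length)}"

        return fmt(self.root) + ";"

    def write(self, path, include_support: bool = True) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(include_support=include_support) + "\n")


def _quote_label(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_number(x: float) -> str:
    return format(float(x), ".12g")


def _copy_subtree(node: Node) -> Node:
    new = Node(node.label, node.length, node.support)
    for child in node.children:
        new.add_child(_copy_subtree(child))
    return new


def _prune(node: Node, keep: set) -> Node:
    if node.is_tip:
        return node  # caller guarantees membership
    new_children = []
    for child in node.children:
        tips_below = {t.label for t in _iter_tips(child)}
        if tips_below & keep:
            new_children.append(_prune(child, keep))
    node.children = []
    for c in new_children:
        node.add_child(c)
    if len(node.children) == 1:
        child = node.children[0]
        child.length += node.length
        child.parent = node.parent
        return child
    return node


def _iter_tips(node: Node):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_tip:
            yield n
        else:
            stack.extend(n.children)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(
    text: str,
    tol: float = DEFAULT_ULTRAMETRIC_TOL,
    keep_comments: bool = False,
) -> UltrametricTree:
    """Parse a Newick string into an :class:`UltrametricTree`.

    Internal node labels that parse as numbers are interpreted as support
    values (RAxML style).  Bracketed comments are stripped unless
    ``keep_comments`` is set (they are never interpreted).  A missing branch
    length on any non-root edge is an error naming the offending node; an
    ultrametricity violation beyond ``tol`` only flags the tree
    (``is_ultrametric=False``) so that purely topological operations remain
    available.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=keep_comments,
        )
    except Exception as exc:  # dendropy raises various DataError subclasses
        raise NewickError(f"malformed Newick: {exc}") from None

    def convert(dnode, is_root: bool) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label is not None:
            label = dnode.label
        length = dnode.edge.length
        if length is None:
            if is_root:
                length = 0.0
            else:
                name = label or "<unnamed internal node>"
                raise NewickError(f"missing branch length on edge above node {name!r}")
        support = None
        if dnode.child_nodes() and label is not None:
            try:
                support = float(label)
            except ValueError:
                support = None
        node = Node(label=label, length=length, support=support)
        for child in dnode.child_nodes():
            node.add_child(convert(child, False))
        return node

    root = convert(dtree.seed_node, True)
    tree = UltrametricTree(root, tol=tol)
    if not tree.is_ultrametric:
        warnings.warn(
            "tree is not ultrametric within tolerance; age-based analyses will refuse it"
        )
    return tree


def read_newick(path, tol: float = DEFAULT_ULTRAMETRIC_TOL) -> UltrametricTree:
    with open(path) as fh:
        return parse_newick(fh.read(), tol=tol)


# ---------------------------------------------------------------------------
# Tree algebra
# ---------------------------------------------------------------------------

def node_ages(tree: UltrametricTree) -> dict[Node, float]:
    """Map every node to its age (height above the tip plane).

    Tips map to 0, the root to the tree height, and along every edge
    ``child.age + child.length == parent.age``.  Refuses non-ultrametric
    trees, for which "age" is not well defined.
    """
    tree.require_ultrametric()
    return {node: node.age for node in tree.postorder()}


def count_splits(tree: UltrametricTree) -> int:
    """Number of internal nodes of a binary rooted tree (= tips - 1); each is
    one past lineage-splitting event."""
    tree.require_binary()
    return len(tree.internal_nodes())


def sister_pairs(tree: UltrametricTree) -> list[tuple[str, str, float]]:
    """All cherries: internal nodes whose two children are both tips,
    reported as (tipA, tipB, node age)."""
    tree.require_binary()
    out = []
    for node in tree.internal_nodes():
        a, b = node.children
        if a.is_tip and b.is_tip:
            out.append((a.label, b.label, node.age))
    return out


def prune_to_representatives(
    tree: UltrametricTree,
    assignment: Mapping[str, str],
    chooser: str = "first",
    seed: int | None = None,
) -> UltrametricTree:
    """One-tip-per-entity species tree.

    ``assignment`` maps every tip label to an entity id (e.g. a delimited
    species).  For each entity one member is kept -- the first in tip order
    (``chooser="first"``) or a seeded uniform draw (``chooser="random"``) --
    and all other tips are pruned; suppressed unary nodes are merged with
    branch-length addition so the result stays ultrametric.  The retained tip
    is relabeled with its entity id.
    """
    tips = tree.tip_labels()
    uncovered = [t for t in tips if t not in assignment]
    if uncovered:
        raise ValueError(f"assignment does not cover tips: {uncovered[:5]}")
    members: dict[str, list[str]] = {}
    for t in tips:
        members.setdefault(assignment[t], []).append(t)
    empty = [e for e, m in members.items() if not m]
    if empty:
        raise ValueError(f"entities with no member: {empty}")

    if chooser == "first":
        chosen = {e: m[0] for e, m in members.items()}
    elif chooser == "random":
        import numpy as np

        rng = np.random.default_rng(seed)
        chosen = {e: m[int(rng.integers(len(m)))] for e, m in sorted(members.items())}
    else:
        raise ValueError(f"unknown chooser {chooser!r}")

    pruned = tree.prune_to_tips(chosen.values())
    relabel = {tip: entity for entity, tip in chosen.items()}
    for t in pruned.tips():
        t.label = relabel[t.label]
    return pruned


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

_SET_COLUMNS = ("host_species", "feeding_sites", "zones")
_COLUMNS = ("taxon", "species", "host_genus", "host_species", "feeding_sites", "zones", "continent")

MISSING = ""  # explicit missing marker in TSV cells


@dataclass
class AnnotationTable:
    """Per-specimen annotations: species label, host genus and species set,
    feeding sites, geographic zones and continent.

    Set-valued fields are stored as frozensets and serialized as
    semicolon-separated sorted values.  Missing scalar values are ``None``;
    missing set values are empty frozensets -- both are written as empty
    cells and round-trip explicitly.
    """

    df: pd.DataFrame
    zone_vocabulary: tuple[str, ...] = ZONES

    def __post_init__(self):
        missing_cols = [c for c in _COLUMNS if c not in self.df.columns]
        if missing_cols:
            raise ValueError(f"annotation table missing columns: {missing_cols}")
        self.df = self.df.loc[:, list(_COLUMNS)].reset_index(drop=True)
        for col in _SET_COLUMNS:
            self.df[col] = self.df[col].map(_as_frozenset)
        for col in ("species", "host_genus", "continent"):
            self.df[col] = self.df[col].map(lambda v: None if v is None or (isinstance(v, float) and math.isnan(v)) or v == "" else str(v))
        if self.df["taxon"].duplicated().any():
            dupes = self.df.loc[self.df["taxon"].duplicated(), "taxon"].tolist()
            raise ValueError(f"duplicate taxon ids: {dupes[:5]}")
        bad = []
        vocab = set(self.zone_vocabulary)
        for taxon, zones in zip(self.df["taxon"], self.df["zones"]):
            if not zones <= vocab:
                bad.append((taxon, sorted(zones - vocab)))
        if bad:
            raise ValueError(f"zones outside configured vocabulary: {bad[:5]}")

    # -- I/O -------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path, zone_vocabulary: tuple[str, ...] = ZONES) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for col in _SET_COLUMNS:
            if col in df.columns:
                df[col] = df[col].map(lambda s: frozenset(x for x in s.split(";") if x))
        df = df.replace({"": None})
        return cls(df, zone_vocabulary=zone_vocabulary)

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        for col in _SET_COLUMNS:
            out[col] = out[col].map(lambda s: ";".join(sorted(s)))
        out = out.fillna(MISSING)
        out.to_csv(path, sep="\t", index=False)

    # -- views -----------------------------------------------------------

    def validate_against_tree(self, tree: UltrametricTree) -> None:
        """Every tree tip must have exactly one annotation row."""
        tips = set(tree.tip_labels())
        rows = set(self.df["taxon"])
        missing = sorted(tips - rows)
        if missing:
            raise ValueError(f"tips without annotation rows: {missing[:5]}")

    def subset(self, taxa: Iterable[str]) -> "AnnotationTable":
        taxa = set(taxa)
        return AnnotationTable(
            self.df[self.df["taxon"].isin(taxa)].copy(),
            zone_vocabulary=self.zone_vocabulary,
        )

    def species_view(self, grouping: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Aggregate specimen rows to one row per species-like entity.

        ``grouping`` optionally overrides the ``species`` column (e.g. with a
        delimitation result mapping taxon -> entity id).  Scalar columns take
        the most frequent non-missing value; set columns take the union.
        """
        df = self.df.copy()
        if grouping is not None:
            df["species"] = df["taxon"].map(dict(grouping))
            if df["species"].isna().any():
                missing = df.loc[df["species"].isna(), "taxon"].tolist()
                raise ValueError(f"grouping does not cover taxa: {missing[:5]}")

        def agg(group: pd.DataFrame) -> pd.Series:
            row = {}
            for col in ("host_genus", "continent"):
                vals = [v for v in group[col] if v is not None]
                row[col] = max(sorted(set(vals)), key=vals.count) if vals else None
            for col in _SET_COLUMNS:
                row[col] = frozenset().union(*group[col]) if len(group) else frozenset()
            row["n_specimens"] = len(group)
            return pd.Series(row)

        view = df.groupby("species", sort=True).apply(agg, include_groups=False)
        return view

    def character(self, column: str, grouping: Mapping[str, str] | None = None) -> dict[str, str | None]:
        """Species-level single-state character from a scalar column."""
        view = self.species_view(grouping)
        return dict(view[column])


def _as_frozenset(value) -> frozenset:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return frozenset()
    if isinstance(value, str):
        return frozenset(x for x in value.split(";") if x)
    return frozenset(value)
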