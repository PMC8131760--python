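"""Trees, tip-state tables and sympatric-pair tables.

The central container is :class:`Phylogeny`, a rooted tree with branch
lengths stored in flat arrays indexed by a stable post-order node id
(children before parents, root last).  Post-order ids make the pruning
likelihood, ancestral-state pass and tip simulation simple array sweeps and
give every internal node a reproducible identifier for reporting.

Newick/Nexus reading and writing is delegated to dendropy, which handles
TRANSLATE blocks, quoted labels and bracketed comments; everything after
parsing lives in this module's own structures.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "Phylogeny",
    "TipStates",
    "SympatricPairs",
    "parse_tree",
    "read_tree",
    "read_tip_states",
    "read_pairs",
    "preflight_report",
]


class Phylogeny:
    """Rooted phylogeny with branch lengths, in post-order array form.

    Nodes are numbered 0..n_nodes-1 in post-order: every child precedes its
    parent and the root is ``n_nodes - 1``.  Leaves carry unique non-empty
    labels; internal nodes may have any number (>= 2) of children, so
    polytomies are first-class.  ``branch_lengths[i]`` is the length of the
    edge above node *i*; a root edge length, if the source file had one, is
    kept in ``root_edge_length`` but plays no role in likelihoods.
    """

    def __init__(
        self,
        children: Sequence[Sequence[int]],
        branch_lengths: Sequence[float],
        labels: Sequence[Optional[str]],
        root_edge_length: Optional[float] = None,
    ):
        n = len(children)
        if n == 0:
            raise ValidationError("empty tree")
        if not (len(branch_lengths) == len(labels) == n):
            raise ValueError("children, branch_lengths and labels must have equal length")
        self.children: list[tuple[int, ...]] = [tuple(c) for c in children]
        self.branch_lengths: list[float] = [float(b) for b in branch_lengths]
        self.labels: list[Optional[str]] = list(labels)
        self.root_edge_length = root_edge_length
        self.root: int = n - 1

        self.parent: list[int] = [-1] * n
        for i, kids in enumerate(self.children):
            for c in kids:
                if c >= i:
                    raise ValueError("node ids must be post-ordered (children before parents)")
                self.parent[c] = i

        self._validate()
        self.leaves: tuple[int, ...] = tuple(i for i in range(n) if not self.children[i])
        self.label_to_node: dict[str, int] = {self.labels[i]: i for i in self.leaves}

    # -- construction ------------------------------------------------------

    def _validate(self) -> None:
        n = len(self.children)
        seen: set[str] = set()
        for i in range(n):
            is_leaf = not self.children[i]
            if is_leaf:
                lab = self.labels[i]
                if not lab:
                    raise ValidationError(f"leaf node {i} has an empty label")
                if lab in seen:
                    raise ValidationError(f"duplicate leaf label {lab!r}")
                seen.add(lab)
            if i != n - 1:
                b = self.branch_lengths[i]
                if b is None or b != b or b < 0:
                    raise ValidationError(
                        f"node {i} ({self.labels[i] or 'internal'}) has invalid branch length {b!r}"
                    )

    @classmethod
    def _from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        order = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(order)}
        children, blens, labels = [], [], []
        for nd in order:
            kids = [index[id(ch)] for ch in nd.child_nodes()]
            children.append(kids)
            if nd is tree.seed_node:
                blens.append(0.0)
            else:
                if nd.edge.length is None:
                    who = nd.taxon.label if nd.taxon else "an internal node"
                    raise ValidationError(f"missing branch length above {who}")
                blens.append(float(nd.edge.length))
            if nd.is_leaf():
                lab = nd.taxon.label if nd.taxon else nd.label
                labels.append(lab)
            else:
                labels.append(None)
        root_edge = tree.seed_node.edge.length
        return cls(children, blens, labels, root_edge_length=root_edge)

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    def postorder(self) -> range:
        return range(self.n_nodes)

    def preorder(self) -> range:
        return range(self.n_nodes - 1, -1, -1)

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    def depths(self) -> list[float]:
        """Root-to-node path lengths (root edge excluded)."""
        d = [0.0] * self.n_nodes
        for i in self.preorder():
            if i != self.root:
                d[i] = d[self.parent[i]] + self.branch_lengths[i]
        return d

    def subtree_leaf_span(self, node: int) -> tuple[str, str]:
        """First and last leaf label (by node id) under *node*, for reporting."""
        stack, found = [node], []
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                found.append(v)
            else:
                stack.extend(self.children[v])
        found.sort()
        return self.labels[found[0]], self.labels[found[-1]]

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths along the unique path joining leaves *a*, *b*."""
        if a == b:
            raise ValidationError(f"path_length requires two distinct leaves, got {a!r} twice")
        try:
            na, nb = self.label_to_node[a], self.label_to_node[b]
        except KeyError as exc:
            raise ValidationError(f"unknown leaf label {exc.args[0]!r}") from None
        anc = {}
        d, v = 0.0, na
        while v != -1:
            anc[v] = d
            d += self.branch_lengths[v]
            v = self.parent[v]
        d, v = 0.0, nb
        while v not in anc:
            d += self.branch_lengths[v]
            v = self.parent[v]
        return d + anc[v]

    # -- surgery -----------------------------------------------------------

    def drop_leaves(self, labels: Iterable[str]) -> "Phylogeny":
        """Remove the named leaves, splicing out unary nodes.

        When an internal node is left with a single child, the node is removed
        and the two incident branch lengths are summed, so every surviving
        leaf keeps its root-to-leaf path length.
        """
        drop = set(labels)
        unknown = sorted(d for d in drop if d not in self.label_to_node)
        if unknown:
            raise ValidationError(f"cannot drop unknown leaf label(s): {unknown}")
        if len(self.label_to_node) - len(drop) < 1:
            raise ValidationError("dropping these leaves would empty the tree")

        children: list[list[int]] = []
        blens: list[float] = []
        labs: list[Optional[str]] = []

        def emit(kids: list[int], b: float, lab: Optional[str]) -> int:
            children.append(kids)
            blens.append(b)
            labs.append(lab)
            return len(children) - 1

        def build(node: int) -> Optional[tuple[int, float]]:
            # returns (new node id, accumulated branch length above it)
            if self.is_leaf(node):
                if self.labels[node] in drop:
                    return None
                return emit([], 0.0, self.labels[node]), self.branch_lengths[node]
            kept = [r for r in (build(c) for c in self.children[node]) if r is not None]
            if not kept:
                return None
            if len(kept) == 1:  # splice: child absorbs this node's edge
                cid, clen = kept[0]
                return cid, clen + self.branch_lengths[node]
            kids = []
            for cid, clen in kept:
                blens[cid] = clen
                kids.append(cid)
            return emit(kids, 0.0, None), self.branch_lengths[node]

        res = build(self.root)
        assert res is not None
        rid, stem = res
        if rid != len(children) - 1:
            raise AssertionError("root must be emitted last")
        blens[rid] = 0.0
        # if the old root went unary and was spliced, its accumulated stem is
        # kept as a root edge: ignored by likelihoods, preserved on output
        root_edge = self.root_edge_length
        if stem > 0:
            root_edge = stem + (root_edge or 0.0)
        return Phylogeny(children, blens, labs, root_edge_length=root_edge)

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        def fmt_label(lab: str) -> str:
            if any(ch in lab for ch in " ()[]{}:;,'\t\n"):
                return "'" + lab.replace("'", "''") + "'"
            return lab

        def rec(node: int) -> str:
            if self.is_leaf(node):
                s = fmt_label(self.labels[node])
            else:
                s = "(" + ",".join(rec(c) for c in self.children[node]) + ")"
            if node != self.root:
                s += f":{self.branch_lengths[node]!r}"
            elif self.root_edge_length is not None:
                s += f":{self.root_edge_length!r}"
            return s

        return rec(self.root) + ";"

    def to_nexus(self, tree_name: str = "tree1") -> str:
        taxa = self.leaf_labels
        lines = ["#NEXUS", "", "BEGIN TAXA;", f"    DIMENSIONS NTAX={len(taxa)};"]
        lines.append("    TAXLABELS " + " ".join(_nexus_quote(t) for t in taxa) + ";")
        lines += ["END;", "", "BEGIN TREES;"]
        lines.append(f"    TREE {tree_name} = {self.to_newick()}")
        lines += ["END;", ""]
        return "\n".join(lines)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Phylogeny):
            return NotImplemented
        return (
            self.children == other.children
            and self.labels == other.labels
            and self.branch_lengths == other.branch_lengths
        )

    def __repr__(self) -> str:
        return f"<Phylogeny with {self.n_leaves} leaves, {self.n_nodes} nodes>"


def _nexus_quote(label: str) -> str:
    if any(ch in label for ch in " ()[]{}:;,'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_tree(text: str, format: str = "newick", tree_name: Optional[str] = None) -> Phylogeny:
    """Parse a Newick string or a Nexus TREES block into a :class:`Phylogeny`.

    Nexus files may carry several trees; then *tree_name* must select one.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"format must be 'newick' or 'nexus', got {format!r}")
    try:
        trees = dendropy.TreeList.get(
            data=text,
            schema=format,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises its own hierarchy
        raise ParseError(f"could not parse {format} input: {exc}") from exc
    if len(trees) == 0:
        raise ParseError(f"no tree found in {format} input")
    if tree_name is not None:
        matches = [t for t in trees if (t.label or "") == tree_name]
        if not matches:
            raise ValidationError(f"no tree named {tree_name!r} in input")
        tree = matches[0]
    elif len(trees) > 1:
        raise ValidationError(
            f"input contains {len(trees)} trees; select one with tree_name"
        )
    else:
        tree = trees[0]
    return Phylogeny._from_dendropy(tree)


def read_tree(path: str, tree_name: Optional[str] = None) -> Phylogeny:
    """Read a tree file, inferring Newick vs Nexus from content."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    fmt = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    return parse_tree(text, format=fmt, tree_name=tree_name)


# ---------------------------------------------------------------------------
# Tip states


@dataclass
class TipStates:
    """Binary phenotype per taxon: 0 (absent), 1 (present) or None (unknown).

    For the beetle data the trait is the major male horn morph: 1 marks a
    population where males with a thoracic horn longer than the cephalic
    horn occur, 0 one where they do not.
    """

    states: dict[str, Optional[int]]

    def __post_init__(self) -> None:
        for taxon, s in self.states.items():
            if s not in (0, 1, None):
                raise ValidationError(f"state for {taxon!r} must be 0, 1 or missing, got {s!r}")

    @property
    def n_present(self) -> int:
        return sum(1 for s in self.states.values() if s == 1)

    @property
    def n_absent(self) -> int:
        return sum(1 for s in self.states.values() if s == 0)

    @property
    def n_missing(self) -> int:
        return sum(1 for s in self.states.values() if s is None)

    def missing_taxa(self) -> list[str]:
        return [t for t, s in self.states.items() if s is None]

    def observed(self) -> "TipStates":
        return TipStates({t: s for t, s in self.states.items() if s is not None})

    def subset(self, taxa: Iterable[str]) -> "TipStates":
        return TipStates({t: self.states[t] for t in taxa})

    def summary(self) -> dict[str, int]:
        return {
            "n_taxa": len(self.states),
            "n_present": self.n_present,
            "n_absent": self.n_absent,
            "n_missing": self.n_missing,
        }

    def validate_against(self, tree: Phylogeny) -> None:
        extra = sorted(set(self.states) - set(tree.leaf_labels))
        missing = sorted(set(tree.leaf_labels) - set(self.states))
        if extra or missing:
            raise ValidationError(
                "tip-state table does not match tree leaves; "
                f"in table only: {extra}; in tree only: {missing}"
            )

    def __getitem__(self, taxon: str) -> Optional[int]:
        return self.states[taxon]

    def __len__(self) -> int:
        return len(self.states)

    def to_csv(self) -> str:
        out = ["taxon,state"]
        for t, s in self.states.items():
            out.append(f"{t},{'NA' if s is None else s}")
        return "\n".join(out) + "\n"


_STATE_TOKENS = {"0": 0, "1": 1, "NA": None, "": None}


def read_tip_states(source) -> TipStates:
    """Read a ``taxon,state`` CSV (path, file object or literal text).

    State cells must be ``0``, ``1``, ``NA`` or empty (the latter two mean
    unknown).  Anything else, or a repeated taxon, is a validation error
    naming the offending row.
    """
    if hasattr(source, "read"):
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    elif isinstance(source, str) and ("\n" in source or "," in source and not _looks_like_path(source)):
        df = pd.read_csv(io.StringIO(source), dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): i for i, c in enumerate(df.columns)}
    if "taxon" not in cols or "state" not in cols:
        raise ValidationError(
            f"tip-state table needs 'taxon' and 'state' columns, found {list(df.columns)}"
        )
    states: dict[str, Optional[int]] = {}
    for idx, row in enumerate(df.itertuples(index=False, name=None), start=2):  # header is line 1
        taxon = str(row[cols["taxon"]]).strip()
        raw = str(row[cols["state"]]).strip()
        if taxon in states:
            raise ValidationError(f"duplicate taxon {taxon!r} at line {idx}")
        if raw not in _STATE_TOKENS:
            raise ValidationError(
                f"line {idx}: state for {taxon!r} must be one of 0/1/NA/empty, got {raw!r}"
            )
        states[taxon] = _STATE_TOKENS[raw]
    if not states:
        raise ValidationError("tip-state table is empty")
    return TipStates(states)


def _looks_like_path(s: str) -> bool:
    return "/" in s or s.endswith((".csv", ".tsv", ".txt"))


# ---------------------------------------------------------------------------
# Sympatric pairs


@dataclass
class SympatricPairs:
    """Unordered pairs of co-occurring taxa, optionally tagged with a locality."""

    pairs: list[tuple[str, str]]
    localities: list[Optional[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.localities:
            self.localities = [None] * len(self.pairs)
        if len(self.localities) != len(self.pairs):
            raise ValidationError("localities must align with pairs")
        seen = set()
        for a, b in self.pairs:
            key = frozenset((a, b))
            if len(key) != 2:
                raise ValidationError(f"pair ({a!r}, {b!r}) must name two distinct taxa")
            if key in seen:
                raise ValidationError(f"duplicate pair ({a!r}, {b!r})")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def validate_against(self, tree: Phylogeny) -> None:
        leaves = set(tree.leaf_labels)
        bad = sorted({t for p in self.pairs for t in p if t not in leaves})
        if bad:
            raise ValidationError(f"pair member(s) not found among tree leaves: {bad}")

    def to_csv(self) -> str:
        out = ["taxon_a,taxon_b,locality"]
        for (a, b), loc in zip(self.pairs, self.localities):
            out.append(f"{a},{b},{loc or ''}")
        return "\n".join(out) + "\n"


def read_pairs(source) -> SympatricPairs:
    """Read a ``taxon_a,taxon_b[,locality]`` CSV (path, file object or text)."""
    if hasattr(source, "read"):
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    elif isinstance(source, str) and "\n" in source:
        df = pd.read_csv(io.StringIO(source), dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): i for i, c in enumerate(df.columns)}
    if "taxon_a" not in cols or "taxon_b" not in cols:
        raise ValidationError(
            f"pair table needs 'taxon_a' and 'taxon_b' columns, found {list(df.columns)}"
        )
    pairs, locs = [], []
    for row in df.itertuples(index=False, name=None):
        a = str(row[cols["taxon_a"]]).strip()
        b = str(row[cols["taxon_b"]]).strip()
        loc = str(row[cols["locality"]]).strip() if "locality" in cols else ""
        pairs.append((a, b))
        locs.append(loc or None)
    return SympatricPairs(pairs, locs)


def preflight_report(
    tree: Phylogeny,
    states: Optional[TipStates] = None,
    pairs: Optional[SympatricPairs] = None,
) -> dict:
    """Cross-check labels between tree, states and pairs without raising.

    Silent label mismatches are the dominant failure mode in comparative
    pipelines, so every mismatch is listed explicitly.
    """
    leaves = set(tree.leaf_labels)
    report: dict = {"n_leaves": tree.n_leaves, "ok": True}
    if states is not None:
        extra = sorted(set(states.states) - leaves)
        absent = sorted(leaves - set(states.states))
        report["states_not_in_tree"] = extra
        report["leaves_without_state_row"] = absent
        report.update(states.summary())
        if extra or absent:
            report["ok"] = False
    if pairs is not None:
        bad = sorted({t for p in pairs for t in p if t not in leaves})
        report["pair_members_not_in_tree"] = bad
        report["n_pairs"] = len(pairs)
        if bad:
            report["ok"] = False
    return report
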