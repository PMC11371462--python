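"""Trees, alignments, and site-pattern compression.

Newick parsing/writing is delegated to dendropy and the results are held in
a small array-friendly ``Tree`` structure suited to repeated pruning passes.
Alignments are read with Biopython (FASTA and relaxed PHYLIP) into a plain
``Alignment`` record.  ``compress_patterns`` collapses identical columns so
the likelihood is a weighted sum over distinct site patterns.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO

from .core_model import ALPHABET, MISSING_CHARS

__all__ = [
    "TreeNode",
    "Tree",
    "parse_newick",
    "read_newick",
    "Alignment",
    "read_alignment",
    "write_alignment",
    "SitePatternTable",
    "compress_patterns",
]


class TreeNode:
    __slots__ = ("children", "parent", "length", "label")

    def __init__(self, label=None, length=None):
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.length = length
        self.label = label

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child


class Tree:
    """A rooted tree with branch lengths in expected substitutions per site.

    Likelihoods under reversible models are invariant to the root position,
    so the stored root only matters for simulation and display.  Internal
    multifurcations (other than at the root) are resolved into binary nodes
    with zero-length branches; ``had_multifurcations`` records whether any
    resolution happened.
    """

    def __init__(self, root: TreeNode, had_multifurcations: bool = False):
        self.root = root
        self.had_multifurcations = had_multifurcations
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Tree":
        def convert(dnode) -> TreeNode:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.is_leaf():
                label = dnode.label
            length = dnode.edge.length
            node = TreeNode(label=label, length=length)
            for child in dnode.child_nodes():
                node.add(convert(child))
            return node

        root = convert(dtree.seed_node)
        had_multi = cls._resolve_multifurcations(root)
        return cls(root, had_multifurcations=had_multi)

    @staticmethod
    def _resolve_multifurcations(root: TreeNode) -> bool:
        changed = False
        stack = [root]
        while stack:
            node = stack.pop()
            # root may keep 3 children (unrooted convention); others become binary
            limit = 3 if node is root else 2
            while len(node.children) > limit:
                changed = True
                merged = TreeNode(length=0.0)
                for child in node.children[-2:]:
                    merged.add(child)
                del node.children[-2:]
                node.add(merged)
            stack.extend(node.children)
        return changed

    def _validate(self):
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels in tree")
        for node in self.postorder():
            if node is self.root:
                continue
            if node.length is None:
                warnings.warn("branch without length, defaulting to 0")
                node.length = 0.0
            if not np.isfinite(node.length) or node.length < 0:
                raise ValueError(f"negative or non-finite branch length {node.length}")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> list[TreeNode]:
        out, stack = [], [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def n_branches(self) -> int:
        return sum(1 for n in self.postorder() if n is not self.root)

    def branch_lengths(self) -> np.ndarray:
        return np.array([n.length for n in self.postorder() if n is not self.root])

    def set_branch_lengths(self, lengths) -> None:
        """Assign lengths in postorder-branch order (as ``branch_lengths``)."""
        lengths = np.asarray(lengths, float)
        branches = [n for n in self.postorder() if n is not self.root]
        if lengths.shape != (len(branches),):
            raise ValueError("length vector does not match branch count")
        if np.any(lengths < 0) or not np.all(np.isfinite(lengths)):
            raise ValueError("branch lengths must be finite and non-negative")
        for node, t in zip(branches, lengths):
            node.length = float(t)

    def copy(self) -> "Tree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(label=node.label, length=node.length)
            for child in node.children:
                new.add(clone(child))
            return new

        return Tree(clone(self.root), self.had_multifurcations)

    def reroot_on_branch(self, leaf_label: str) -> "Tree":
        """Return a copy rooted at the midpoint of the branch above a leaf."""
        tree = self.copy()
        target = next((n for n in tree.postorder() if n.label == leaf_label), None)
        if target is None or not target.is_leaf:
            raise ValueError(f"no leaf named {leaf_label!r}")
        if target.parent is tree.root and len(tree.root.children) <= 2:
            return tree
        half = (target.length or 0.0) / 2.0
        new_root = TreeNode()
        old_parent = target.parent
        old_parent.children.remove(target)
        # re-hang the path from old_parent up to the old root
        node, carry = old_parent, half
        new_root.add(target).length = half
        prev = new_root
        while node is not None:
            parent = node.parent
            length_up = node.length
            node.parent = None
            node.length = carry
            prev.add(node)
            if parent is not None:
                parent.children.remove(node)
            prev, node, carry = node, parent, length_up
        # drop a degree-1 old root if created
        for n in prev.children[:]:
            if not n.children and n.label is None:
                prev.children.remove(n)
        t = Tree(new_root, self.had_multifurcations)
        t._suppress_unifurcations()
        return t

    def _suppress_unifurcations(self):
        for node in self.postorder():
            for i, child in enumerate(node.children):
                while len(child.children) == 1:
                    grand = child.children[0]
                    grand.length = (grand.length or 0.0) + (child.length or 0.0)
                    grand.parent = node
                    node.children[i] = grand
                    child = grand

    # -- output ------------------------------------------------------------

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                body = _quote_label(node.label)
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    body += _quote_label(node.label)
            if node.parent is not None:
                body += f":{node.length:.10g}"
            return body

        return fmt(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions (as the smaller-side frozensets)."""
        all_leaves = frozenset(self.leaf_labels())
        out = set()
        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(leaf.label for leaf in _subtree_leaves(node))
            other = all_leaves - side
            if len(side) > 1 and len(other) > 1:
                out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out


def _subtree_leaves(node: TreeNode):
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


def _quote_label(label: str) -> str:
    if label is None:
        return ""
    if any(ch in label for ch in "(),:;[] \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Labels may be quoted; ``[...]`` comments are skipped; missing branch
    lengths default to zero with a warning.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    tree = Tree.from_dendropy(dtree)
    if not tree.root.children:
        raise ValueError("malformed Newick: empty tree")
    return tree


def read_newick(path) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

_ALLOWED = set(ALPHABET.symbols) | MISSING_CHARS


@dataclass
class Alignment:
    """An amino-acid multiple sequence alignment."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("one row per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = {t for t in self.taxa if self.taxa.count(t) > 1}
            raise ValueError(f"duplicate taxon names: {sorted(dupes)}")
        if not self.rows or not self.rows[0]:
            raise ValueError("alignment must contain at least one site")
        n = len(self.rows[0])
        cleaned = []
        for taxon, row in zip(self.taxa, self.rows):
            row = row.upper().replace(".", "-")
            if len(row) != n:
                raise ValueError(f"ragged alignment: row {taxon!r} has length "
                                 f"{len(row)}, expected {n}")
            bad = set(row) - _ALLOWED
            if bad:
                raise ValueError(f"unknown characters {sorted(bad)} in record {taxon!r}")
            cleaned.append(row)
        self.rows = cleaned

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def codes(self) -> np.ndarray:
        """Integer matrix (n_taxa, n_sites): 0..19 residues, -1 missing."""
        lut = np.full(128, -1, dtype=np.int8)
        for i, ch in enumerate(ALPHABET.symbols):
            lut[ord(ch)] = i
        mat = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
        return lut[mat].reshape(self.n_taxa, self.n_sites)

    def reorder(self, taxa: list[str]) -> "Alignment":
        pos = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in pos]
        if missing:
            raise ValueError(f"taxa absent from alignment: {missing}")
        return Alignment(list(taxa), [self.rows[pos[t]] for t in taxa])


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read a FASTA or relaxed-PHYLIP alignment."""
    if format not in ("fasta", "phylip"):
        raise ValueError("format must be 'fasta' or 'phylip'")
    schema = "fasta" if format == "fasta" else "phylip-relaxed"
    try:
        if format == "fasta":
            records = list(SeqIO.parse(str(path), "fasta"))
        else:
            records = list(next(AlignIO.parse(str(path), schema)))
    except StopIteration:
        raise ValueError(f"{path}: no alignment found")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse as {format}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no sequences found")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_alignment(path, aln: Alignment, format: str = "fasta") -> None:
    with open(path, "w") as fh:
        if format == "fasta":
            for taxon, row in zip(aln.taxa, aln.rows):
                fh.write(f">{taxon}\n")
                for i in range(0, len(row), 60):
                    fh.write(row[i:i + 60] + "\n")
        elif format == "phylip":
            fh.write(f"{aln.n_taxa} {aln.n_sites}\n")
            width = max(len(t) for t in aln.taxa) + 2
            for taxon, row in zip(aln.taxa, aln.rows):
                fh.write(taxon.ljust(width) + row + "\n")
        else:
            raise ValueError("format must be 'fasta' or 'phylip'")


# ---------------------------------------------------------------------------
# Site-pattern compression
# ---------------------------------------------------------------------------

@dataclass
class SitePatternTable:
    """Distinct alignment columns with multiplicities.

    ``patterns`` is (n_taxa, n_patterns) with codes 0..19 and -1 for missing;
    ``site_map[p]`` is the pattern index of original column ``p``.
    """

    patterns: np.ndarray
    counts: np.ndarray
    site_map: np.ndarray

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Spread a per-pattern vector back to original site order."""
        return np.asarray(per_pattern)[self.site_map]


def compress_patterns(aln: Alignment | np.ndarray) -> SitePatternTable:
    codes = aln.codes() if isinstance(aln, Alignment) else np.asarray(aln)
    uniq, site_map, counts = np.unique(
        codes, axis=1, return_inverse=True, return_counts=True)
    return SitePatternTable(uniq, counts, site_map.ravel())
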