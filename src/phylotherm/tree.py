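"""Rooted phylogeny container and tree metrics.

The :class:`Phylogeny` is a lightweight array-backed rooted tree: nodes are
integer ids ``0..n_nodes-1`` with the root at id 0, stored as parent pointers,
children lists and branch lengths.  Newick input is parsed with dendropy and
converted; output is serialized locally so branch lengths round-trip at full
float precision.

Branch lengths are in whatever units the input tree carries (time or expected
substitutions); nothing here assumes ultrametricity, but
:meth:`Phylogeny.is_ultrametric` lets callers that need it check explicitly.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .errors import NewickParseError, TreeValidationError, MonophylyError

__all__ = ["Phylogeny", "parse_newick", "patristic_matrix"]


def _check_parentheses(text: str) -> None:
    """Cheap pre-scan so malformed bracketing reports a character offset."""
    depth = 0
    in_quote = False
    for i, ch in enumerate(text):
        if ch == "'":
            in_quote = not in_quote
        elif not in_quote:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise NewickParseError("unbalanced ')'", offset=i)
    if in_quote:
        raise NewickParseError("unterminated quoted label", offset=len(text) - 1)
    if depth != 0:
        raise NewickParseError("unbalanced '(': %d unclosed" % depth,
                               offset=len(text) - 1)


class Phylogeny:
    """Rooted tree with branch lengths and unique tip labels.

    Parameters
    ----------
    parent : array of int
        Parent id per node; -1 for the root (node 0).
    lengths : array of float
        Branch length of the edge above each node; 0.0 for the root.
    labels : sequence of str or None
        Tip labels (required, unique, non-empty) and optional internal labels.
    """

    def __init__(self, parent: Sequence[int], lengths: Sequence[float],
                 labels: Sequence[str | None]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        n = len(self.parent)
        if not (len(self.lengths) == len(self.labels) == n):
            raise TreeValidationError("parent/lengths/labels size mismatch")
        if n == 0 or self.parent[0] != -1 or np.any(self.parent[1:] < 0):
            raise TreeValidationError("node 0 must be the unique root")
        if np.any(self.lengths < 0):
            raise TreeValidationError("negative branch length")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for v in range(1, n):
            p = int(self.parent[v])
            if p >= v:
                raise TreeValidationError("parents must precede children "
                                          "(preorder ids required)")
            self.children[p].append(v)
        self._validate_tips()

    # -- construction ------------------------------------------------------

    def _validate_tips(self) -> None:
        tips = self.tip_ids
        seen: set[str] = set()
        for v in tips:
            lab = self.labels[v]
            if not lab:
                raise TreeValidationError(f"tip node {v} has no label")
            if lab in seen:
                raise TreeValidationError(f"duplicate tip label {lab!r}")
            seen.add(lab)
        for v in range(self.n_nodes):
            if self.children[v] and len(self.children[v]) < 2:
                raise TreeValidationError(
                    f"internal node {v} has a single child (unifurcation)")

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        """Parse a Newick string (quoted labels supported)."""
        _check_parentheses(text)
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"dendropy could not parse Newick: {exc}") \
                from exc
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "Phylogeny":
        order = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(order)}
        parent, lengths, labels = [], [], []
        for nd in order:
            if nd.parent_node is None:
                parent.append(-1)
                lengths.append(0.0)
            else:
                parent.append(index[id(nd.parent_node)])
                lengths.append(float(nd.edge.length or 0.0))
            if nd.taxon is not None:
                labels.append(nd.taxon.label)
            else:
                labels.append(nd.label)
        return cls(parent, lengths, labels)

    @classmethod
    def read(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_ids(self) -> np.ndarray:
        """Node ids of the leaves, in preorder."""
        return np.array([v for v in range(self.n_nodes) if not self.children[v]],
                        dtype=np.int64)

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[v] for v in self.tip_ids]

    def tip_index(self) -> dict[str, int]:
        """Map tip label -> node id."""
        return {self.labels[v]: int(v) for v in self.tip_ids}

    def preorder(self) -> np.ndarray:
        return np.arange(self.n_nodes, dtype=np.int64)

    def postorder(self) -> np.ndarray:
        return np.arange(self.n_nodes - 1, -1, -1, dtype=np.int64)

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def depths(self) -> np.ndarray:
        """Distance from the root to every node (root depth 0)."""
        d = np.zeros(self.n_nodes)
        for v in range(1, self.n_nodes):
            d[v] = d[self.parent[v]] + self.lengths[v]
        return d

    @property
    def height(self) -> float:
        """Maximum root-to-tip distance."""
        return float(self.depths()[self.tip_ids].max())

    def total_length(self) -> float:
        return float(self.lengths[1:].sum())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        hd = self.depths()[self.tip_ids]
        h = hd.max()
        if h == 0:
            return True
        return bool((hd.max() - hd.min()) <= rel_tol * h)

    # -- editing -----------------------------------------------------------

    def with_lengths(self, new_lengths: np.ndarray) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), np.asarray(new_lengths, float),
                         list(self.labels))

    def resolve_polytomies(self) -> "Phylogeny":
        """Return a strictly bifurcating tree.

        Multifurcations are resolved deterministically by child order: the
        first two children are joined under a new zero-length internal node,
        repeatedly, yielding a caterpillar of zero-length edges.  Binary trees
        are returned unchanged (same object).
        """
        if self.is_binary():
            return self
        # Build nested child structure, then re-emit in preorder.
        def emit(v, parent_new, length, out):
            my = len(out["parent"])
            out["parent"].append(parent_new)
            out["lengths"].append(length)
            out["labels"].append(self.labels[v])
            kids = list(self.children[v])
            # stack of (node_id_or_None, length); None means synthetic node
            while len(kids) > 2:
                # join first two children under a synthetic zero-length node
                a, b = kids[0], kids[1]
                kids = [("synth", a, b)] + kids[2:]
            for kid in kids:
                if isinstance(kid, tuple):
                    emit_synth(kid, my, out)
                else:
                    emit(kid, my, self.lengths[kid], out)
            return my

        def emit_synth(spec, parent_new, out):
            my = len(out["parent"])
            out["parent"].append(parent_new)
            out["lengths"].append(0.0)
            out["labels"].append(None)
            for kid in spec[1:]:
                if isinstance(kid, tuple):
                    emit_synth(kid, my, out)
                else:
                    emit(kid, my, self.lengths[kid], out)

        out: dict = {"parent": [], "lengths": [], "labels": []}
        emit(0, -1, 0.0, out)
        return Phylogeny(out["parent"], out["lengths"], out["labels"])

    # -- queries -----------------------------------------------------------

    def clade_tips(self, node: int) -> list[int]:
        """Tip ids descending from ``node`` (preorder)."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if not self.children[v]:
                out.append(v)
            else:
                stack.extend(reversed(self.children[v]))
        return out

    def mrca(self, tip_labels: Iterable[str]) -> int:
        """Most recent common ancestor of a set of tip labels."""
        idx = self.tip_index()
        try:
            want = {idx[lab] for lab in tip_labels}
        except KeyError as exc:
            raise TreeValidationError(f"unknown tip label {exc.args[0]!r}")
        if not want:
            raise TreeValidationError("empty tip set")
        # count, per node, how many wanted tips are below it (postorder)
        count = np.zeros(self.n_nodes, dtype=np.int64)
        for v in self.postorder():
            if not self.children[v]:
                count[v] = 1 if v in want else 0
            else:
                count[v] = sum(count[c] for c in self.children[v])
        target = len(want)
        # deepest node containing all wanted tips
        best = 0
        for v in range(self.n_nodes):
            if count[v] == target:
                best = v  # preorder: later qualifying node is deeper
        return int(best)

    def check_monophyletic(self, tip_labels: Iterable[str]) -> int:
        """Return the MRCA if the tip set is monophyletic, else raise
        :class:`MonophylyError` naming the intruding tips."""
        want = set(tip_labels)
        node = self.mrca(want)
        spanned = {self.labels[t] for t in self.clade_tips(node)}
        extra = sorted(spanned - want)
        if extra:
            raise MonophylyError(
                "tip set is not monophyletic; clade also spans: "
                + ", ".join(extra))
        return node

    def path_to_root(self, node: int) -> list[int]:
        """Nodes from the root down to ``node`` inclusive."""
        path = []
        v = node
        while v != -1:
            path.append(v)
            v = int(self.parent[v]) if v != 0 else -1
        return path[::-1]

    # -- metrics -----------------------------------------------------------

    def patristic_matrix(self) -> "tuple[np.ndarray, list[str]]":
        """Tip-to-tip path-length matrix.

        Returns ``(D, labels)`` with ``D[i, j]`` the patristic distance
        between ``labels[i]`` and ``labels[j]``; symmetric, zero diagonal.
        """
        tips = self.tip_ids
        n = len(tips)
        pos = {int(t): i for i, t in enumerate(tips)}
        depth = self.depths()
        D = np.zeros((n, n))
        # tips below each node, accumulated postorder; MRCA depth subtracted
        below: dict[int, list[int]] = {}
        for v in self.postorder():
            if not self.children[v]:
                below[v] = [pos[int(v)]]
                continue
            kids = [below.pop(c) for c in self.children[v]]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ia = np.asarray(kids[a])
                    ib = np.asarray(kids[b])
                    dd = (depth[tips[ia]][:, None] + depth[tips[ib]][None, :]
                          - 2.0 * depth[v])
                    D[ia[:, None], ib[None, :]] = dd
                    D[ib[:, None], ia[None, :]] = dd.T
            below[v] = [i for k in kids for i in k]
        return D, self.tip_labels

    # -- serialization -----------------------------------------------------

    def to_newick(self, node_labels: Mapping[int, str] | None = None) -> str:
        """Serialize to Newick with full float precision.

        ``node_labels`` optionally overrides internal-node labels (e.g. ASR
        annotations)."""
        buf = io.StringIO()

        def needs_quote(lab: str) -> bool:
            return any(c in lab for c in " ()[]:;,'\t\n")

        def fmt_label(lab: str | None) -> str:
            if lab is None:
                return ""
            if needs_quote(lab):
                return "'" + lab.replace("'", "''") + "'"
            return lab

        def write(v: int) -> None:
            if self.children[v]:
                buf.write("(")
                for i, c in enumerate(self.children[v]):
                    if i:
                        buf.write(",")
                    write(c)
                buf.write(")")
            if node_labels is not None and v in node_labels:
                buf.write(fmt_label(node_labels[v]))
            else:
                buf.write(fmt_label(self.labels[v]))
            if v != 0:
                buf.write(":%.17g" % self.lengths[v])

        write(0)
        buf.write(";")
        return buf.getvalue()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Phylogeny: {self.n_tips} tips, {self.n_nodes} nodes>"


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`."""
    return Phylogeny.from_newick(text)


def patristic_matrix(tree: Phylogeny):
    """Symmetric tip-to-tip path-length matrix; see
    :meth:`Phylogeny.patristic_matrix`."""
    return tree.patristic_matrix()
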