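"""Phylogenetic independent contrasts (Felsenstein pruning).

For a binary tree, each internal node contributes one contrast: the
difference between its two daughter values, with variance proportional to the
sum of the (adjusted) daughter branch lengths.  The node itself carries the
inverse-variance weighted average of the daughters, and its parent branch is
extended by ``t_i * t_j / (t_i + t_j)`` to account for the estimation error —
the standard REML recursion.  Under Brownian motion the contrasts are
independent Normal(0, sigma^2 * T) variables, which is the likelihood
currency used by every trait-evolution model in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import MissingTraitError
from .tree import Phylogeny

__all__ = ["ContrastSet", "compute_contrasts", "pruning_downpass",
           "branch_length_floor"]


def branch_length_floor(tree: Phylogeny) -> float:
    """Default floor replacing zero-length branches inside likelihoods."""
    return 1e-8 * max(tree.height, np.finfo(float).tiny)


@dataclass
class ContrastSet:
    """Contrasts and pruning by-products for one (tree, trait) pair.

    Attributes
    ----------
    node_ids : internal-node id per contrast (n_tips - 1 of them)
    contrasts : daughter trait differences, in trait units
    variances : effective time T per contrast (sum of adjusted daughter
        branch lengths)
    estimates : weighted-average trait value at each internal node
    root_estimate : the pruning value at the root (the GLS/REML root state)
    """

    node_ids: np.ndarray
    contrasts: np.ndarray
    variances: np.ndarray
    estimates: np.ndarray
    root_estimate: float
    tree: Phylogeny = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.contrasts)

    def standardized(self) -> np.ndarray:
        """Contrasts divided by their Brownian standard deviations (at
        sigma^2 = 1)."""
        return self.contrasts / np.sqrt(self.variances)


def _as_tip_values(tree: Phylogeny, traits) -> np.ndarray:
    """Values ordered as tree.tip_ids; raises naming any missing tip."""
    if isinstance(traits, pd.Series):
        traits = traits.to_dict()
    if isinstance(traits, Mapping):
        vals = []
        for lab in tree.tip_labels:
            if lab not in traits or traits[lab] is None or \
                    (isinstance(traits[lab], float) and np.isnan(traits[lab])):
                raise MissingTraitError(f"tip {lab!r} has no trait value")
            vals.append(float(traits[lab]))
        return np.asarray(vals)
    arr = np.asarray(traits, dtype=float)
    if arr.shape[0] != tree.n_tips:
        raise MissingTraitError(
            f"expected {tree.n_tips} tip values, got {arr.shape[0]}")
    if np.isnan(arr).any():
        lab = tree.tip_labels[int(np.flatnonzero(np.isnan(arr))[0])]
        raise MissingTraitError(f"tip {lab!r} has no trait value")
    return arr


def pruning_downpass(tree: Phylogeny, tip_matrix: np.ndarray,
                     min_branch: float | None = None):
    """Vectorized Felsenstein downpass over one or many trait columns.

    Parameters
    ----------
    tree : binary Phylogeny
    tip_matrix : (n_tips, m) array of tip values, rows ordered as
        ``tree.tip_ids``
    min_branch : floor applied to raw branch lengths (default
        :func:`branch_length_floor`)

    Returns
    -------
    values : (n_nodes, m) nodal values (tips = inputs, internals = weighted
        daughter averages)
    extra : (n_nodes,) accumulated branch-length extension per node
    contrast_nodes, contrasts (m columns), variances : per internal node
    """
    if not tree.is_binary():
        tree = tree.resolve_polytomies()
    if min_branch is None:
        min_branch = branch_length_floor(tree)
    tip_matrix = np.atleast_2d(np.asarray(tip_matrix, float))
    if tip_matrix.shape[0] != tree.n_tips:
        tip_matrix = tip_matrix.T
    m = tip_matrix.shape[1]
    n = tree.n_nodes
    values = np.zeros((n, m))
    extra = np.zeros(n)
    values[tree.tip_ids] = tip_matrix
    blen = np.maximum(tree.lengths, min_branch)
    cn, cc, cv = [], [], []
    for v in tree.postorder():
        kids = tree.children[v]
        if not kids:
            continue
        i, j = kids
        ti = blen[i] + extra[i]
        tj = blen[j] + extra[j]
        wi, wj = 1.0 / ti, 1.0 / tj
        values[v] = (values[i] * wi + values[j] * wj) / (wi + wj)
        extra[v] = ti * tj / (ti + tj)
        cn.append(v)
        cc.append(values[i] - values[j])
        cv.append(ti + tj)
    return (values, extra, np.asarray(cn, dtype=np.int64),
            np.asarray(cc), np.asarray(cv))


def compute_contrasts(tree: Phylogeny, traits,
                      min_branch: float | None = None) -> ContrastSet:
    """Independent contrasts for one trait.

    ``traits`` may be a mapping/Series keyed by tip label or an array ordered
    as ``tree.tip_ids``.  Multifurcations are resolved deterministically into
    zero-length bifurcations first; a floor (default 1e-8 x tree height)
    replaces zero branch lengths so contrast weights stay finite.
    """
    if not tree.is_binary():
        tree = tree.resolve_polytomies()
    x = _as_tip_values(tree, traits)
    values, extra, cn, cc, cv = pruning_downpass(tree, x[:, None], min_branch)
    return ContrastSet(node_ids=cn, contrasts=cc[:, 0], variances=cv,
                       estimates=values[cn, 0],
                       root_estimate=float(values[0, 0]), tree=tree)
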