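"""Brownian-motion ancestral state reconstruction.

Marginal (empirical-Bayes / GLS) reconstruction of a continuous trait at
every internal node under Brownian motion with a flat prior on the root
state: a downpass collects each subtree's conditional mean and effective
variance (the contrast recursion), an uppass combines the message from the
rest of the tree, and the two are pooled by inverse variance.  Node means do
not depend on the diffusion rate sigma2; variances scale linearly in it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contrasts import _as_tip_values, branch_length_floor
from .errors import ParameterDomainError
from .models import TraitEvolution
from .tree import Phylogeny

__all__ = ["AncestralStates", "asr_bm", "lineage_trend"]


@dataclass
class AncestralStates:
    """Marginal BM reconstruction: per-internal-node mean and variance.

    ``table`` is indexed by node id with columns ``estimate`` (trait units)
    and ``variance`` (trait^2, proportional to sigma2).
    """

    table: pd.DataFrame
    sigma2: float
    root_estimate: float
    tree: Phylogeny

    def estimate(self, node: int) -> float:
        return float(self.table.loc[node, "estimate"])

    def annotated_newick(self, fmt: str = "{est:.4g}") -> str:
        """Newick with internal nodes labeled by their estimates."""
        labels = {int(v): fmt.format(est=e)
                  for v, e in self.table["estimate"].items()}
        return self.tree.to_newick(node_labels=labels)

    def summary(self) -> str:
        head = (f"BM ancestral state reconstruction "
                f"(sigma2 = {self.sigma2:.6g})\n"
                f"root estimate: {self.root_estimate:.6g}\n")
        return head + self.table.to_string()


def asr_bm(tree: Phylogeny, traits, sigma2: float | None = None, *,
           min_branch: float | None = None) -> AncestralStates:
    """Marginal ancestral states under Brownian motion.

    ``sigma2`` defaults to the REML estimate from a BM fit.  Two-pass
    message passing: the downpass conditional mean/variance per subtree, an
    uppass carrying the rest-of-tree message, pooled by inverse variance at
    each internal node.
    """
    tree = tree.resolve_polytomies()
    x = _as_tip_values(tree, traits)
    if sigma2 is None:
        sigma2 = TraitEvolution(tree, x, "BM").fit().params["sigma2"]
    if sigma2 <= 0:
        raise ParameterDomainError("sigma2 must be > 0")
    if min_branch is None:
        min_branch = branch_length_floor(tree)
    n = tree.n_nodes
    blen = np.maximum(tree.lengths, min_branch)

    # downpass: mean and extra variance (in branch-length units) per subtree
    mean_dn = np.zeros(n)
    var_dn = np.zeros(n)  # effective extra length
    mean_dn[tree.tip_ids] = x
    for v in tree.postorder():
        kids = tree.children[v]
        if not kids:
            continue
        i, j = kids
        ti = blen[i] + var_dn[i]
        tj = blen[j] + var_dn[j]
        mean_dn[v] = (mean_dn[i] / ti + mean_dn[j] / tj) / (1 / ti + 1 / tj)
        var_dn[v] = ti * tj / (ti + tj)

    # uppass: message from the rest of the tree (mean, variance-length);
    # root has no up message (flat prior)
    mean_up = np.zeros(n)
    var_up = np.full(n, np.inf)
    for v in tree.preorder():
        kids = tree.children[v]
        if not kids:
            continue
        i, j = kids
        for c, s in ((i, j), (j, i)):
            ts = blen[s] + var_dn[s]
            if np.isinf(var_up[v]):
                m, w = mean_dn[s], ts
            else:
                wv = var_up[v]
                m = (mean_up[v] / wv + mean_dn[s] / ts) / (1 / wv + 1 / ts)
                w = wv * ts / (wv + ts)
            mean_up[c] = m
            var_up[c] = w + blen[c]

    est = np.zeros(n)
    var = np.zeros(n)
    # pool down and up messages at internal nodes
    internal = [v for v in range(n) if tree.children[v]]
    for v in internal:
        if np.isinf(var_up[v]):  # root
            est[v] = mean_dn[v]
            var[v] = var_dn[v]
        else:
            a, b = var_dn[v], var_up[v]
            est[v] = (mean_dn[v] / a + mean_up[v] / b) / (1 / a + 1 / b)
            var[v] = a * b / (a + b)
    table = pd.DataFrame({"estimate": est[internal],
                          "variance": sigma2 * var[np.array(internal)]},
                         index=pd.Index(internal, name="node"))
    return AncestralStates(table=table, sigma2=float(sigma2),
                           root_estimate=float(mean_dn[0]), tree=tree)


def lineage_trend(states: AncestralStates, tree: Phylogeny,
                  focal_clade) -> pd.DataFrame:
    """Ancestral estimates along the path root -> MRCA of a clade.

    The focal clade must be monophyletic (checked; intruding tips are named
    otherwise).  Returns the ordered estimates with a ``monotone_decreasing``
    attribute reported, not assumed.
    """
    node = tree.check_monophyletic(focal_clade)
    path = [v for v in tree.path_to_root(node) if tree.children[v]]
    est = [states.estimate(v) for v in path]
    df = pd.DataFrame({"node": path, "estimate": est})
    df.attrs["monotone_decreasing"] = bool(
        np.all(np.diff(est) < 0)) if len(est) > 1 else True
    return df
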