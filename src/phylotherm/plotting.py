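"""Minimal plotting helpers: trait-on-tree dot plot and group boxplots.

These are conveniences for quick inspection; figure aesthetics beyond the
basics are out of scope.
"""

from __future__ import annotations

import numpy as np

from .tree import Phylogeny


def plot_group_boxplot(values, groups, ax=None, ylabel=""):
    """Boxplot of a per-tip quantity split by group label."""
    import matplotlib.pyplot as plt
    import pandas as pd

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    s = pd.Series(np.asarray(values, float),
                  index=pd.Index(np.asarray(groups))).dropna()
    names = sorted(s.index.unique())
    ax.boxplot([s.loc[g] for g in names], tick_labels=names)
    ax.set_ylabel(ylabel)
    return ax


def plot_trait_on_tree(tree: Phylogeny, traits, ax=None, label=""):
    """Tips ordered as in the tree against their trait values."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 0.12 * tree.n_tips + 1))
    labs = tree.tip_labels
    vals = [traits[l] for l in labs]
    y = np.arange(len(labs))
    ax.scatter(vals, y, s=8)
    ax.set_yticks(y)
    ax.set_yticklabels(labs, fontsize=5)
    ax.invert_yaxis()
    ax.set_xlabel(label)
    return ax
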