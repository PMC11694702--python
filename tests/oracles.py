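"""Independent oracles used by the test suite.

Everything here is deliberately naive (brute-force path search, dense
matrix algebra, closed-form special functions) and shares no code path with
the implementations it checks.
"""

import numpy as np
from scipy import special, stats

from phylotherm.tree import Phylogeny


def brute_force_patristic(tree: Phylogeny) -> np.ndarray:
    """Per-pair path search: sum branch lengths along root paths minus twice
    the shared prefix."""
    tips = tree.tip_ids
    paths = {int(v): tree.path_to_root(int(v)) for v in tips}
    depth = tree.depths()
    n = len(tips)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = paths[int(tips[i])], paths[int(tips[j])]
            shared = [a for a, b in zip(pi, pj) if a == b]
            mrca = shared[-1]
            D[i, j] = D[j, i] = (depth[tips[i]] + depth[tips[j]]
                                 - 2 * depth[mrca])
    return D


def phylo_cov(tree: Phylogeny) -> np.ndarray:
    """Phylogenetic covariance at sigma2=1: depth of the pairwise MRCA."""
    tips = tree.tip_ids
    depth = tree.depths()
    paths = {int(v): set(tree.path_to_root(int(v))) for v in tips}
    n = len(tips)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            common = paths[int(tips[i])] & paths[int(tips[j])]
            C[i, j] = max(depth[c] for c in common)
        C[i, i] = depth[tips[i]]
    return C


def mvn_reml(values: np.ndarray, cov: np.ndarray, sigma2: float) -> float:
    """Dense-matrix REML log-likelihood with the root state profiled out."""
    n = len(values)
    V = sigma2 * cov
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    mu = one @ Vi @ values / (one @ Vi @ one)
    r = values - mu
    _, ld = np.linalg.slogdet(V)
    return float(-0.5 * ((n - 1) * np.log(2 * np.pi) + ld
                         + np.log(one @ Vi @ one) + r @ Vi @ r))


def ou_cov(tree: Phylogeny, alpha: float) -> np.ndarray:
    """Stationary OU tip covariance (sigma2 factored out) directly from the
    closed form on the original ultrametric tree."""
    tips = tree.tip_ids
    depth = tree.depths()
    h = tree.height
    paths = {int(v): set(tree.path_to_root(int(v))) for v in tips}
    n = len(tips)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            common = paths[int(tips[i])] & paths[int(tips[j])]
            s = max(depth[c] for c in common)
            C[i, j] = np.exp(-2 * alpha * (h - s)) \
                * -np.expm1(-2 * alpha * s) / (2 * alpha)
        s = depth[tips[i]]
        C[i, i] = -np.expm1(-2 * alpha * s) / (2 * alpha)
    return C


def jn_mixture_pdf(x, T, jump_rate, jump_var, nugget=0.0, mmax=80):
    """Compound-Poisson-normal closed form (atom smeared by the nugget)."""
    x = np.asarray(x, float)
    m = np.arange(mmax + 1)
    w = stats.poisson.pmf(m, jump_rate * T)
    var = m[:, None] * jump_var + nugget
    return (w[:, None] * stats.norm.pdf(x[None, :],
                                        scale=np.sqrt(var))).sum(axis=0)


def vg_pdf(x, T, sigma2, nu):
    """Symmetric variance-gamma density via the Bessel-K closed form; the
    x = 0 limit uses f(0) = Gamma(c - 1/2) / (Gamma(c) sqrt(2 pi sigma2 nu))
    for shape c = T/nu > 1/2."""
    x = np.asarray(x, float)
    c = T / nu
    a = x ** 2 / (2 * sigma2)
    b = 1.0 / nu
    pref = 2.0 / (np.sqrt(2 * np.pi * sigma2) * special.gamma(c) * nu ** c)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = pref * (a / b) ** ((c - 0.5) / 2) \
            * special.kv(c - 0.5, 2 * np.sqrt(a * b))
    at0 = special.gamma(c - 0.5) / (special.gamma(c)
                                    * np.sqrt(2 * np.pi * sigma2 * nu))
    return np.where(x == 0.0, at0, out)


def nig_pdf(x, T, alpha, delta):
    """Symmetric normal-inverse-Gaussian density (Bessel-K closed form)."""
    x = np.asarray(x, float)
    dT = delta * T
    g = np.sqrt(dT ** 2 + x ** 2)
    return alpha * dT / np.pi * np.exp(dT * alpha) * special.kv(1, alpha * g) / g


def all_clades(tree: Phylogeny):
    """Every clade as (node, frozenset of tip labels)."""
    return [(v, frozenset(tree.labels[t] for t in tree.clade_tips(v)))
            for v in range(tree.n_nodes) if tree.children[v]]


def brute_force_cold_clades(tree: Phylogeny, flags: dict, min_size: int):
    """Maximal all-cold clades by exhaustive enumeration over all clades."""
    clades = all_clades(tree)
    qualifying = [(v, tips) for v, tips in clades
                  if all(flags[t] for t in tips)]
    # plus single cold tips (for min_size = 1)
    out = []
    qual_sets = [tips for _, tips in qualifying]
    for v, tips in qualifying:
        if not any(tips < other for other in qual_sets):
            if len(tips) >= min_size:
                out.append(tips)
    if min_size <= 1:
        covered = set().union(*out) if out else set()
        for t in tree.tip_labels:
            if flags[t] and t not in covered:
                out.append(frozenset([t]))
    return sorted(out, key=lambda s: (-len(s), sorted(s)[0]))
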