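"""Synthetic data with the statistical structure the analyses assume.

Generators for: Yule (pure-birth) ultrametric trees; tip traits under every
implemented trait-evolution family (exact per-branch increment sampling, no
Euler discretization); binary cold-adaptation states from a thresholded
Brownian liability or from random placement; proteomes with controlled
arginine/lysine frequencies; and gene-family presence/absence matrices with
planted clade-specific families.

Reproducibility: one global seed expands into independent per-generator
substreams via ``numpy.random.SeedSequence`` spawn keys, so adding a
generator never perturbs the stream of an existing one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterDomainError
from .models import ALL_FAMILIES, GAUSSIAN_FAMILIES, EvolModelSpec, \
    transform_tree
from .tree import Phylogeny

__all__ = ["substream", "sim_yule", "sim_trait", "sim_threshold_binary",
           "sim_random_binary", "sim_proteome", "sim_pa_matrix",
           "make_demo_dataset", "write_fasta", "AMINO_ACIDS"]

_STREAMS = {"yule": 0, "trait": 1, "binary": 2, "proteome": 3, "pa": 4,
            "user": 99}


def substream(seed: int | None, stage: str,
              index: int = 0) -> np.random.Generator:
    """Independent RNG for one generator invocation.

    ``(seed, stage, index)`` fully determines the stream; streams for
    different stages or indices never overlap.
    """
    key = _STREAMS.get(stage, _STREAMS["user"])
    ss = np.random.SeedSequence(seed, spawn_key=(key, index))
    return np.random.default_rng(ss)


# --------------------------------------------------------------------------
# trees


def sim_yule(n_tips: int, birth_rate: float = 1.0, seed: int | None = None,
             *, rescale_height: float | None = None,
             index: int = 0) -> Phylogeny:
    """Ultrametric pure-birth tree with ``n_tips`` leaves.

    Lineages split at rate ``birth_rate`` each; after the last split the
    process runs one further exponential waiting time so terminal branches
    are not degenerate.  ``rescale_height`` optionally rescales all branch
    lengths so the root-to-tip height equals the given value.
    """
    if n_tips < 2:
        raise ParameterDomainError("need n_tips >= 2")
    if birth_rate <= 0:
        raise ParameterDomainError("birth_rate must be > 0")
    rng = substream(seed, "yule", index)
    # active lineages: (parent_slot, birth_time); tree assembled as child
    # lists keyed by provisional ids
    next_id = 0

    def new_id():
        nonlocal next_id
        next_id += 1
        return next_id - 1

    root = new_id()
    birth = {root: 0.0}
    children: dict[int, list[int]] = {root: []}
    a, b = new_id(), new_id()
    t = 0.0
    for c in (a, b):
        birth[c] = 0.0
        children[root].append(c)
        children[c] = []
    active = [a, b]
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        parent = active.pop(rng.integers(len(active)))
        for _ in range(2):
            c = new_id()
            birth[c] = t
            children[parent].append(c)
            children[c] = []
            active.append(c)
    t += rng.exponential(1.0 / (birth_rate * n_tips))

    # emit preorder
    parent_arr, lengths, labels = [], [], []
    label_iter = iter(range(1, n_tips + 1))

    # branch above node v spans from birth[v] to v's own split time
    split_time = {v: (birth[children[v][0]] if children[v] else t)
                  for v in birth}

    def emit2(v, parent_new):
        my = len(parent_arr)
        parent_arr.append(parent_new)
        lengths.append(0.0 if parent_new == -1
                       else split_time[v] - birth[v])
        labels.append(None if children[v] else f"t{next(label_iter)}")
        for c in children[v]:
            emit2(c, my)

    emit2(root, -1)
    tree = Phylogeny(parent_arr, lengths, labels)
    if rescale_height is not None:
        tree = tree.with_lengths(tree.lengths * rescale_height / tree.height)
    return tree


# --------------------------------------------------------------------------
# traits


def _branch_increments(family: str, params: dict, blen: np.ndarray,
                       rng: np.random.Generator):
    """Additive per-branch increments for Levy/BM-type families."""
    n = len(blen)
    pos = blen > 0  # zero-length branches (incl. the root slot) get 0
    inc = np.zeros(n)
    jumps = np.zeros(n, dtype=np.int64)
    if "sigma2" in params and params["sigma2"] > 0:
        inc[pos] += rng.normal(0.0, np.sqrt(params["sigma2"] * blen[pos]))
    if family in ("JN", "BMJN"):
        lam, sj2 = params["jump_rate"], params["jump_var"]
        jumps[pos] = rng.poisson(lam * blen[pos])
        inc += rng.normal(0.0, 1.0, n) * np.sqrt(jumps * sj2)
    elif family in ("VG", "BMVG"):
        s2, nu = params["vg_sigma2"], params["vg_nu"]
        g = np.zeros(n)
        g[pos] = rng.gamma(blen[pos] / nu, nu)
        inc += rng.normal(0.0, 1.0, n) * np.sqrt(s2 * g)
    elif family in ("NIG", "BMNIG"):
        al, de = params["nig_alpha"], params["nig_delta"]
        # inverse-Gaussian subordinator: mean de*t/al, shape (de*t)^2
        ig = np.zeros(n)
        mean = de * blen[pos] / al
        shape = (de * blen[pos]) ** 2
        ig[pos] = stats.invgauss.rvs(mean / shape, scale=shape,
                                     random_state=rng)
        inc += rng.normal(0.0, 1.0, n) * np.sqrt(ig)
    return inc, jumps


def sim_trait(tree: Phylogeny, spec: EvolModelSpec, root_state: float = 0.0,
              seed: int | None = None, *, return_details: bool = False,
              index: int = 0):
    """Simulate one continuous trait under any of the 13 families.

    Per-branch increments are drawn from the exact transition law of each
    process (Poisson-mixed normals for JN, gamma / inverse-Gaussian
    subordinated normals for VG / NIG, the exact OU transition, and plain
    Gaussians on the transformed tree for the Pagel / EB / trend families).

    Returns a Series of tip values keyed by label; with
    ``return_details=True`` also a dict with per-node values and per-branch
    jump counts.
    """
    if spec.family not in ALL_FAMILIES:
        raise ParameterDomainError(f"unknown family {spec.family!r}")
    rng = substream(seed, "trait", index)
    n = tree.n_nodes
    x = np.zeros(n)
    x[0] = root_state
    jumps = np.zeros(n, dtype=np.int64)

    if spec.family == "OU":
        if not tree.is_ultrametric():
            raise ParameterDomainError("OU simulation requires an "
                                       "ultrametric tree")
        s2, al = spec.params["sigma2"], spec.params["ou_alpha"]
        theta = root_state
        for v in range(1, n):
            t = tree.lengths[v]
            e = np.exp(-al * t)
            var = s2 * (1 - e * e) / (2 * al) if al > 0 else s2 * t
            x[v] = x[tree.parent[v]] * e + theta * (1 - e) \
                + rng.normal(0.0, np.sqrt(var))
    elif spec.family in GAUSSIAN_FAMILIES:
        # time-inhomogeneous / transformed BM: Gaussian increments with the
        # transformed branch lengths as variances
        wt = transform_tree(tree, spec.family, spec.params) \
            if spec.family != "BM" else tree
        s2 = spec.params["sigma2"]
        inc = rng.normal(0.0, 1.0, n) * np.sqrt(s2 * np.maximum(wt.lengths, 0))
        inc[0] = 0.0
        for v in range(1, n):
            x[v] = x[tree.parent[v]] + inc[v]
    else:
        inc, jumps = _branch_increments(spec.family, spec.params,
                                        tree.lengths, rng)
        inc[0] = 0.0
        for v in range(1, n):
            x[v] = x[tree.parent[v]] + inc[v]

    tips = tree.tip_ids
    series = pd.Series(x[tips], index=tree.tip_labels, name="trait")
    if return_details:
        return series, {"node_values": x, "jump_counts": jumps}
    return series


def sim_threshold_binary(tree: Phylogeny, prevalence: float,
                         seed: int | None = None, *, sigma2: float = 1.0,
                         index: int = 0) -> pd.Series:
    """Binary states from a thresholded Brownian liability.

    The ``round(prevalence * n)`` tips with the highest liability get state
    1, so the realized prevalence is exact — the construction conditioning
    the Brownian-threshold null of the D statistic on observed prevalence.
    """
    n = tree.n_tips
    n1 = int(round(prevalence * n))
    if not 1 <= n1 <= n - 1:
        raise ParameterDomainError(
            f"prevalence {prevalence} not achievable on {n} tips")
    liab = sim_trait(tree, EvolModelSpec("BM", {"sigma2": sigma2}),
                     seed=seed, index=index)
    order = np.argsort(-liab.values, kind="stable")
    states = np.zeros(n, dtype=int)
    states[order[:n1]] = 1
    return pd.Series(states, index=liab.index, name="state")


def sim_random_binary(tree: Phylogeny, prevalence: float,
                      seed: int | None = None, *,
                      index: int = 0) -> pd.Series:
    """Binary states placed uniformly at random at exact prevalence."""
    n = tree.n_tips
    n1 = int(round(prevalence * n))
    if not 1 <= n1 <= n - 1:
        raise ParameterDomainError(
            f"prevalence {prevalence} not achievable on {n} tips")
    rng = substream(seed, "binary", index)
    states = np.zeros(n, dtype=int)
    states[rng.choice(n, n1, replace=False)] = 1
    return pd.Series(states, index=tree.tip_labels, name="state")


# --------------------------------------------------------------------------
# proteomes and presence/absence matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def sim_proteome(n_proteins: int = 100, length: int = 300,
                 freq_arg: float = 0.05, freq_lys: float = 0.05,
                 seed: int | None = None, *, genome_id: str = "genome",
                 index: int = 0) -> list[tuple[str, str]]:
    """Random protein sequences with controlled Arg (R) and Lys (K)
    frequencies; the remaining 18 residues share the leftover mass
    uniformly.  Returns ``(record_id, sequence)`` pairs.
    """
    if freq_arg < 0 or freq_lys < 0 or freq_arg + freq_lys > 1:
        raise ParameterDomainError("invalid R/K frequencies")
    rng = substream(seed, "proteome", index)
    probs = np.full(20, (1.0 - freq_arg - freq_lys) / 18.0)
    probs[AMINO_ACIDS.index("R")] = freq_arg
    probs[AMINO_ACIDS.index("K")] = freq_lys
    aa = np.array(list(AMINO_ACIDS))
    out = []
    for i in range(n_proteins):
        seq = "".join(rng.choice(aa, size=length, p=probs))
        out.append((f"{genome_id}|protein_{i + 1:04d}", seq))
    return out


def write_fasta(records: list[tuple[str, str]], path, *,
                header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f";{header_comment}\n")
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def make_demo_dataset(outdir, kind: str = "clustered", n_tips: int = 200,
                      seed: int = 0, *, cold_threshold: float = 5.0) -> dict:
    """Write a complete synthetic genus-scale dataset to ``outdir``.

    ``kind="clustered"`` emulates a genus whose cold-adapted species form a
    conserved clade: minimum growth temperature follows a Brownian liability
    on the tree (so cold tips clump phylogenetically), proteomes of cold
    strains carry a depressed Arg/(Arg+Lys) ratio, and the presence/absence
    matrix has families planted in the largest cold clade.
    ``kind="sporadic"`` emulates the contrasting genus: the same temperature
    values are reassigned to tips uniformly at random, so cold adaptation is
    scattered and no composition skew or planted families exist.

    Returns a dict of written paths plus the realized cold prevalence.
    """
    from pathlib import Path

    from .composition import find_cold_clades

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind not in ("clustered", "sporadic"):
        raise ParameterDomainError("kind must be 'clustered' or 'sporadic'")
    tree = sim_yule(n_tips, 1.0, seed=seed)
    liab = sim_trait(tree, EvolModelSpec("BM", {"sigma2": 1.0}), seed=seed)
    z = (liab - liab.mean()) / liab.std()
    # map the liability to degrees C so roughly a quarter of tips fall at or
    # below the cold threshold
    tmin = 9.0 + 6.0 * z
    if kind == "sporadic":
        rng = substream(seed, "user", 1)
        tmin = pd.Series(rng.permutation(tmin.values), index=tmin.index)
    cold = tmin <= cold_threshold
    tree_path = outdir / "tree.nwk"
    tree.write(tree_path)
    traits_path = outdir / "traits.tsv"
    with open(traits_path, "w") as fh:
        fh.write("tip\tt_min\tsource\n")
        for lab in tree.tip_labels:
            src = "glacier" if cold[lab] else "soil"
            fh.write(f"{lab}\t{tmin[lab]:.4f}\t{src}\n")
    # proteomes: depressed Arg fraction in cold strains of the clustered
    # genus (a genuine composition signal); uniform otherwise
    proteome_paths = []
    pdir = outdir / "proteomes"
    pdir.mkdir(exist_ok=True)
    for i, lab in enumerate(tree.tip_labels):
        if kind == "clustered" and cold[lab]:
            f_arg, f_lys = 0.040, 0.060
        else:
            f_arg, f_lys = 0.050, 0.050
        recs = sim_proteome(30, 200, f_arg, f_lys, seed=seed, index=i,
                            genome_id=lab)
        p = pdir / f"{lab}.faa"
        write_fasta(recs, p)
        proteome_paths.append(str(p))
    # presence/absence with families planted in the largest cold clade
    clades = find_cold_clades(tree, {l: bool(cold[l])
                                     for l in tree.tip_labels}, min_size=2)
    planted_in = clades[0].tips if (kind == "clustered" and clades) else []
    n_planted = 20 if planted_in else 0
    pa = sim_pa_matrix(tree, planted_in, n_families=500,
                       background_p=0.5, n_planted=n_planted, seed=seed)
    pa_path = outdir / "pa_matrix.tsv"
    pa.to_csv(pa_path, sep="\t")
    return {"tree": str(tree_path), "traits": str(traits_path),
            "proteomes": proteome_paths, "pa_matrix": str(pa_path),
            "n_cold": int(cold.sum()), "largest_cold_clade":
            clades[0].size if clades else 0}


def sim_pa_matrix(tree: Phylogeny, clade_tips, n_families: int = 2000,
                  background_p: float = 0.5, n_planted: int = 20,
                  out_noise: float = 0.0, in_prob: float = 1.0,
                  seed: int | None = None, *, index: int = 0) -> pd.DataFrame:
    """Gene-family presence/absence matrix with planted clade-specific rows.

    Background families are Bernoulli(``background_p``) in every genome;
    planted families (ids ``planted_####``) are present in clade members
    with probability ``in_prob`` and outside with probability ``out_noise``.
    Rows are families, columns are tree tip labels.
    """
    rng = substream(seed, "pa", index)
    genomes = tree.tip_labels
    clade = set(clade_tips)
    unknown = clade - set(genomes)
    if unknown:
        raise ParameterDomainError(f"clade tips not in tree: {sorted(unknown)}")
    in_mask = np.array([g in clade for g in genomes])
    bg = rng.binomial(1, background_p, size=(n_families, len(genomes)))
    planted = np.where(in_mask[None, :],
                       rng.binomial(1, in_prob, (n_planted, len(genomes))),
                       rng.binomial(1, out_noise, (n_planted, len(genomes))))
    mat = np.vstack([planted, bg])
    ids = [f"planted_{i + 1:04d}" for i in range(n_planted)] + \
        [f"fam_{i + 1:05d}" for i in range(n_families)]
    return pd.DataFrame(mat, index=ids, columns=genomes)
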