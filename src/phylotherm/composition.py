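"""Arg/(Arg+Lys) proteome composition, cold-clade detection, clade-specific
gene families, and group comparisons.

The arginine fraction among arginine+lysine residues is a proteome-level
cold-adaptation marker: it decreases in cold-adapted lineages (lysine is
favored at low temperature).  A genome's value is the mean of per-protein
ratios over its core proteins (not pooled residue counts); the pooled-count
variant is available behind a flag since both arithmetics are in use.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterDomainError
from .tree import Phylogeny

__all__ = ["arg_lys_ratios", "protein_rk_ratio", "find_cold_clades",
           "ColdClade", "clade_specific_families", "group_compare",
           "GroupComparison"]

_NUCLEOTIDES = set("ACGTNU")


def protein_rk_ratio(seq: str) -> tuple[int, int, float | None]:
    """(Arg count, Lys count, ratio) for one sequence; ratio None when the
    sequence has neither residue.  Case-insensitive; residues other than
    R/K are ignored for the counts."""
    s = seq.upper()
    n_r = s.count("R")
    n_k = s.count("K")
    tot = n_r + n_k
    return n_r, n_k, (n_r / tot if tot else None)


def _iter_genome_fastas(proteomes):
    """Yield (genome_id, iterable of (record_id, sequence))."""
    if isinstance(proteomes, dict):
        for gid, src in proteomes.items():
            if isinstance(src, (str, Path)):
                yield gid, ((r.id, str(r.seq))
                            for r in SeqIO.parse(str(src), "fasta"))
            else:  # in-memory records
                yield gid, iter(src)
    else:  # iterable of paths; genome id = file stem
        for src in proteomes:
            p = Path(src)
            yield p.stem, ((r.id, str(r.seq))
                           for r in SeqIO.parse(str(p), "fasta"))


def arg_lys_ratios(proteomes, *, pooled: bool = False,
                   return_proteins: bool = False):
    """Per-genome Arg/(Arg+Lys) statistics over core proteins.

    Parameters
    ----------
    proteomes : dict of genome id -> FASTA path or ``(id, seq)`` records,
        or an iterable of FASTA paths (genome id = file stem)
    pooled : also meaningful: with ``pooled=False`` (default) the genome
        value is the mean of per-protein ratios; ``pooled=True`` uses
        total R / (total R + total K) instead
    return_proteins : also return the per-protein table

    Returns a DataFrame indexed by genome id with columns ``n_proteins``,
    ``n_excluded`` (proteins with no R or K), ``mean_ratio``,
    ``pooled_ratio`` and ``ratio`` (the one selected by ``pooled``).
    Sequences that look nucleotide (>95% ACGTNU) trigger a warning.
    """
    genome_rows = []
    protein_rows = []
    for gid, records in _iter_genome_fastas(proteomes):
        ratios = []
        tot_r = tot_k = excluded = count = 0
        for rid, seq in records:
            s = str(seq).upper()
            if s and sum(c in _NUCLEOTIDES for c in s) > 0.95 * len(s):
                warnings.warn(f"record {rid!r} in genome {gid!r} looks like "
                              "a nucleotide sequence", stacklevel=2)
            n_r, n_k, ratio = protein_rk_ratio(s)
            count += 1
            tot_r += n_r
            tot_k += n_k
            if ratio is None:
                excluded += 1
            else:
                ratios.append(ratio)
            if return_proteins:
                protein_rows.append({"genome": gid, "protein": rid,
                                     "n_arg": n_r, "n_lys": n_k,
                                     "ratio": ratio})
        mean_ratio = float(np.mean(ratios)) if ratios else np.nan
        pooled_ratio = tot_r / (tot_r + tot_k) if tot_r + tot_k else np.nan
        genome_rows.append({"genome": gid, "n_proteins": count,
                            "n_excluded": excluded, "mean_ratio": mean_ratio,
                            "pooled_ratio": pooled_ratio})
    df = pd.DataFrame(genome_rows).set_index("genome")
    df["ratio"] = df["pooled_ratio"] if pooled else df["mean_ratio"]
    if return_proteins:
        return df, pd.DataFrame(protein_rows)
    return df


@dataclass
class ColdClade:
    """A maximal monophyletic clade whose analyzed tips are all
    cold-adapted."""

    node: int
    tips: list[str]

    @property
    def size(self) -> int:
        return len(self.tips)


def find_cold_clades(tree: Phylogeny, cold_flags, min_size: int = 2, *,
                     ignore_unclassified: bool = False) -> list[ColdClade]:
    """Maximal all-cold monophyletic clades, largest first.

    ``cold_flags`` maps tip label -> True/False/None (None = unclassified:
    missing minimum growth temperature).  Unclassified tips break clade
    exclusivity by default (conservative); ``ignore_unclassified=True``
    instead treats them as transparent, as if pruned before the scan.
    Ties in size break by first tip label.
    """
    if isinstance(cold_flags, pd.Series):
        cold_flags = {k: (None if pd.isna(v) else bool(v))
                      for k, v in cold_flags.items()}
    flags = {}
    for lab in tree.tip_labels:
        if lab not in cold_flags:
            raise ParameterDomainError(f"tip {lab!r} has no cold flag")
        flags[lab] = cold_flags[lab]

    n = tree.n_nodes
    all_cold = np.zeros(n, dtype=bool)
    has_cold = np.zeros(n, dtype=bool)
    for v in tree.postorder():
        if not tree.children[v]:
            f = flags[tree.labels[v]]
            if f is None:
                all_cold[v] = ignore_unclassified
                has_cold[v] = False
            else:
                all_cold[v] = bool(f)
                has_cold[v] = bool(f)
        else:
            kids = tree.children[v]
            all_cold[v] = all(all_cold[c] for c in kids)
            has_cold[v] = any(has_cold[c] for c in kids)

    out = []
    for v in range(n):
        parent_ok = v != 0 and all_cold[tree.parent[v]]
        if all_cold[v] and has_cold[v] and not parent_ok:
            tips = [tree.labels[t] for t in tree.clade_tips(v)]
            if ignore_unclassified:
                tips_classified = [t for t in tips if flags[t] is not None]
            else:
                tips_classified = tips
            if len(tips_classified) >= min_size:
                out.append(ColdClade(node=v, tips=tips))
    out.sort(key=lambda c: (-c.size, c.tips[0]))
    return out


def clade_specific_families(pa: pd.DataFrame, clade, in_min: float = 0.9,
                            out_max: float = 0.05) -> pd.DataFrame:
    """Gene families enriched in a clade and rare outside it.

    ``pa`` is a families x genomes 0/1 DataFrame.  Families with in-clade
    presence frequency >= ``in_min`` and out-clade frequency <= ``out_max``
    are returned with both frequencies and a specificity score
    (in-freq - out-freq), sorted by score descending then family id.
    """
    clade = [str(c) for c in clade]
    unknown = set(clade) - set(pa.columns)
    if unknown:
        raise ParameterDomainError(
            f"clade genomes not in matrix: {sorted(unknown)}")
    if not clade or len(clade) == len(pa.columns):
        raise ParameterDomainError(
            "clade must be a non-empty strict subset of the genomes")
    vals = pa.astype(float)
    if not vals.isin([0.0, 1.0]).all().all():
        raise ParameterDomainError("presence/absence matrix must be 0/1")
    out_cols = [c for c in pa.columns if c not in set(clade)]
    in_freq = vals[clade].mean(axis=1)
    out_freq = vals[out_cols].mean(axis=1)
    df = pd.DataFrame({"in_freq": in_freq, "out_freq": out_freq,
                       "score": in_freq - out_freq})
    hit = df[(df["in_freq"] >= in_min) & (df["out_freq"] <= out_max)].copy()
    hit = hit.sort_values(["score"], ascending=False, kind="stable")
    return hit


@dataclass
class GroupComparison:
    """Nonparametric group comparison with BH-corrected pairwise tests."""

    overall_test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame
    group_medians: pd.Series

    def summary(self) -> str:
        lines = [f"Group comparison ({self.overall_test})",
                 f"  statistic = {self.statistic:.4f}   "
                 f"p = {self.p_value:.4g}",
                 "  group medians:"]
        for g, m in self.group_medians.items():
            lines.append(f"    {g}: {m:.4g}")
        if len(self.pairwise):
            lines.append(self.pairwise.to_string(index=False,
                         float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def group_compare(values, groups) -> GroupComparison:
    """Kruskal-Wallis across >= 3 groups (rank-sum for 2), with pairwise
    Mann-Whitney tests under Benjamini-Hochberg correction and effect
    directions (sign of the median difference).

    ``values`` and ``groups`` are aligned sequences/Series; every group
    needs n >= 2.
    """
    s = pd.Series(np.asarray(values, dtype=float),
                  index=pd.Index(np.asarray(groups)))
    s = s.dropna()
    by = {g: v.values for g, v in s.groupby(level=0)}
    if len(by) < 2:
        raise ParameterDomainError("need at least 2 groups")
    for g, v in by.items():
        if len(v) < 2:
            raise ParameterDomainError(f"group {g!r} has n < 2")
    names = sorted(by)

    def mwu(a, b):
        # all-tied samples sit exactly at the null center: U = n1 n2 / 2,
        # p reported as the 1.0 boundary
        if np.ptp(np.concatenate([a, b])) == 0:
            return len(a) * len(b) / 2.0, 1.0
        r = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(r.statistic), float(r.pvalue)

    if len(by) == 2:
        st, p = mwu(by[names[0]], by[names[1]])
        overall = ("Wilcoxon rank-sum (Mann-Whitney)", st, p)
    elif np.ptp(s.values) == 0:
        overall = ("Kruskal-Wallis", 0.0, 1.0)
    else:
        res = stats.kruskal(*[by[n] for n in names])
        overall = ("Kruskal-Wallis", float(res.statistic), float(res.pvalue))
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        st, p = mwu(by[g1], by[g2])
        med1, med2 = np.median(by[g1]), np.median(by[g2])
        rows.append({"group1": g1, "group2": g2,
                     "statistic": st,
                     "p": p,
                     "direction": (f"{g1} < {g2}" if med1 < med2
                                   else f"{g1} > {g2}" if med1 > med2
                                   else "equal medians")})
    pw = pd.DataFrame(rows)
    pw["p_adj"] = multipletests(pw["p"], method="fdr_bh")[1]
    medians = pd.Series({g: float(np.median(by[g])) for g in names})
    return GroupComparison(overall_test=overall[0], statistic=overall[1],
                           p_value=overall[2], pairwise=pw,
                           group_medians=medians)
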