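"""One-config orchestration of the full analysis.

Stages run in dependency order: classify -> clade_scan -> {fit_models, asr,
d_test, mantel} -> composition -> group_compare -> clade_families.  A
failure in one stage does not abort stages that do not depend on it; the
machine-readable run report records per-stage status, parameters, seeds and
the SHA-256 digest of every input, and embeds the fully resolved
configuration so a run can be reproduced exactly.  Outputs are plain TSV /
JSON and are byte-identical across runs with the same config and seed
(timestamps only ever go to the log).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asr import asr_bm
from .composition import (arg_lys_ratios, clade_specific_families,
                          find_cold_clades, group_compare)
from .errors import ConfigError, PhylothermError
from .models import fit_all
from .signal import d_statistic, distance_trait_correlation
from .traits import align_to_tree, classify_cold, read_trait_table
from .tree import Phylogeny

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("classify", "clade_scan", "fit_models", "asr", "d_test", "mantel",
          "composition", "group_compare", "clade_families")

_REQUIRES = {
    "classify": ("traits",),
    "clade_scan": ("tree", "traits"),
    "fit_models": ("tree", "traits"),
    "asr": ("tree", "traits"),
    "d_test": ("tree", "traits"),
    "mantel": ("tree", "traits"),
    "composition": ("proteomes",),
    "group_compare": ("traits",),
    "clade_families": ("tree", "traits", "pa_matrix"),
}


@dataclass
class RunConfig:
    """Resolved pipeline configuration.

    Input paths may be omitted for stages that are not enabled.  All
    randomized stages derive their streams from ``seed``.
    """

    tree: str | None = None
    traits: str | None = None
    proteomes: list[str] | None = None
    pa_matrix: str | None = None
    outdir: str = "phylotherm_out"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    cold_threshold: float = 5.0
    trait_column: str = "t_min"
    families: object = "all"
    restarts: int = 5
    n_perm: int = 1000
    n_sim: int = 1000
    mantel_perm: int = 999
    mantel_method: str = "pearson"
    min_clade_size: int = 2
    in_min: float = 0.9
    out_max: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.stages:
            raise ConfigError("no stages enabled")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")
        if not np.isfinite(self.cold_threshold):
            raise ConfigError("cold_threshold must be finite")
        for stage in self.stages:
            for need in _REQUIRES[stage]:
                if getattr(self, need) in (None, []):
                    raise ConfigError(
                        f"stage {stage!r} requires input {need!r}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run report (also written
    to ``<outdir>/report.json``)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {},
        "stages": {},
    }
    for name in ("tree", "traits", "pa_matrix"):
        p = getattr(config, name)
        if p:
            report["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}
    if config.proteomes:
        report["inputs"]["proteomes"] = [
            {"path": str(p), "sha256": _sha256(p)} for p in config.proteomes]

    state: dict = {}

    def load_shared():
        if config.tree and "tree" not in state:
            state["tree"] = Phylogeny.read(config.tree)
        if config.traits and "traits" not in state:
            tbl = read_trait_table(config.traits)
            tbl = classify_cold(tbl, config.cold_threshold)
            if "tree" in state:
                tbl = align_to_tree(tbl, state["tree"])
            state["traits"] = tbl

    def record(stage, status, outputs=None, **extra):
        report["stages"][stage] = {"status": status,
                                   "outputs": outputs or [], **extra}

    def run_stage(stage, fn):
        if stage not in config.stages:
            record(stage, "skipped")
            return
        try:
            fn()
        except PhylothermError as exc:
            logger.error("stage %s failed: %s", stage, exc)
            record(stage, "failed", error=str(exc))
        except Exception as exc:  # keep siblings running
            logger.error("stage %s crashed: %s\n%s", stage, exc,
                         traceback.format_exc())
            record(stage, "failed", error=f"{type(exc).__name__}: {exc}")

    # ---- classify -------------------------------------------------------
    def st_classify():
        load_shared()
        tbl = state["traits"]
        out = outdir / "classified_traits.tsv"
        _write_tsv(tbl, out)
        n_cold = int((tbl["cold"] == True).sum())  # noqa: E712
        record("classify", "ok", [str(out)], n_cold=n_cold,
               n_unclassified=int(tbl["cold"].isna().sum()),
               threshold=config.cold_threshold)

    # ---- clade scan -----------------------------------------------------
    def st_clade_scan():
        load_shared()
        tbl = state["traits"]
        clades = find_cold_clades(state["tree"], tbl["cold"],
                                  min_size=config.min_clade_size)
        state["cold_clades"] = clades
        rows = [{"clade": i + 1, "size": c.size,
                 "tips": ",".join(c.tips)} for i, c in enumerate(clades)]
        out = outdir / "cold_clades.tsv"
        _write_tsv(pd.DataFrame(rows, columns=["clade", "size", "tips"]),
                   out, index=False)
        record("clade_scan", "ok", [str(out)], n_clades=len(clades),
               largest=clades[0].size if clades else 0)

    # ---- model fitting --------------------------------------------------
    def st_fit():
        load_shared()
        vals = state["traits"][config.trait_column].dropna()
        sel = fit_all(state["tree"], vals, families=config.families,
                      restarts=config.restarts, seed=config.seed)
        state["model_selection"] = sel
        out = outdir / "aic_table.tsv"
        _write_tsv(sel.table, out, index=False)
        record("fit_models", "ok", [str(out)],
               best_family=sel.table.iloc[0]["family"], seed=config.seed,
               restarts=config.restarts)

    # ---- ASR ------------------------------------------------------------
    def st_asr():
        load_shared()
        vals = state["traits"][config.trait_column].dropna()
        states = asr_bm(state["tree"], vals)
        out = outdir / "ancestral_states.tsv"
        _write_tsv(states.table, out)
        nwk = outdir / "ancestral_states.nwk"
        nwk.write_text(states.annotated_newick() + "\n")
        record("asr", "ok", [str(out), str(nwk)],
               root_estimate=states.root_estimate, sigma2=states.sigma2)

    # ---- D statistic ----------------------------------------------------
    def st_d():
        load_shared()
        tbl = state["traits"]
        flags = tbl["cold"].dropna().astype(int)
        keep = [l for l in state["tree"].tip_labels if l in flags.index]
        # prune unclassified tips is out of scope here: require full cover
        res = d_statistic(state["tree"], flags.reindex(keep),
                          n_perm=config.n_perm, n_sim=config.n_sim,
                          seed=config.seed)
        out = outdir / "d_statistic.json"
        out.write_text(json.dumps({
            "d_obs": res.d_obs, "D": res.D, "p_random": res.p_random,
            "p_brownian": res.p_brownian, "prevalence": res.prevalence,
            "n_tips": res.n_tips, "n_perm": res.n_perm, "n_sim": res.n_sim,
            "seed": res.seed}, indent=2) + "\n")
        state["d_result"] = res
        record("d_test", "ok", [str(out)], D=res.D, p_random=res.p_random,
               seed=config.seed)

    # ---- Mantel ---------------------------------------------------------
    def st_mantel():
        load_shared()
        vals = state["traits"][config.trait_column].dropna()
        res = distance_trait_correlation(
            state["tree"], vals, method=config.mantel_method,
            n_perm=config.mantel_perm, seed=config.seed)
        out = outdir / "mantel.json"
        out.write_text(json.dumps({
            "statistic": res.statistic, "p_value": res.p_value,
            "method": res.method, "n_perm": res.n_perm,
            "seed": res.seed}, indent=2) + "\n")
        record("mantel", "ok", [str(out)], statistic=res.statistic,
               p_value=res.p_value, seed=config.seed)

    # ---- composition ----------------------------------------------------
    def st_comp():
        ratios = arg_lys_ratios(list(config.proteomes))
        state["ratios"] = ratios
        out = outdir / "rk_ratios.tsv"
        _write_tsv(ratios, out)
        record("composition", "ok", [str(out)],
               n_genomes=len(ratios))

    # ---- group comparisons ---------------------------------------------
    def st_groups():
        load_shared()
        tbl = state["traits"]
        outputs, info = [], {}
        comparisons = []  # (values Series, groups Series, tag)
        if "group" in tbl.columns and tbl["group"].notna().any():
            comparisons.append((tbl[config.trait_column], tbl["group"],
                                "by_group"))
        flags = tbl["cold"].map({True: "cold", False: "not_cold"})
        comparisons.append((tbl[config.trait_column], flags, "by_cold"))
        if "ratios" in state:
            merged = state["ratios"].join(tbl, how="inner")
            fl = merged["cold"].map({True: "cold", False: "not_cold"})
            comparisons.append((merged["ratio"], fl, "ratio_by_cold"))
        for vals, grp, tag in comparisons:
            mask = vals.notna() & grp.notna()
            if mask.sum() < 4 or grp[mask].nunique() < 2:
                continue
            gc = group_compare(vals[mask].values, grp[mask].values)
            out = outdir / f"group_compare_{tag}.tsv"
            _write_tsv(gc.pairwise, out, index=False)
            outputs.append(str(out))
            info[tag] = {"test": gc.overall_test, "p": gc.p_value}
        record("group_compare", "ok", outputs, **info)

    # ---- clade-specific families ---------------------------------------
    def st_families():
        load_shared()
        pa = pd.read_csv(config.pa_matrix, sep="\t", index_col=0,
                         comment="#")
        clades = state.get("cold_clades")
        if not clades:
            tbl = state["traits"]
            clades = find_cold_clades(state["tree"], tbl["cold"],
                                      min_size=config.min_clade_size)
        if not clades:
            record("clade_families", "ok", [], n_hits=0,
                   note="no cold clade found")
            return
        clade = [t for t in clades[0].tips if t in pa.columns]
        hits = clade_specific_families(pa, clade, in_min=config.in_min,
                                       out_max=config.out_max)
        out = outdir / "clade_specific_families.tsv"
        _write_tsv(hits, out)
        record("clade_families", "ok", [str(out)], n_hits=len(hits),
               clade_size=len(clade))

    runners = {"classify": st_classify, "clade_scan": st_clade_scan,
               "fit_models": st_fit, "asr": st_asr, "d_test": st_d,
               "mantel": st_mantel, "composition": st_comp,
               "group_compare": st_groups, "clade_families": st_families}
    for stage in STAGES:
        run_stage(stage, runners[stage])

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, default=str) + "\n")
    return report
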