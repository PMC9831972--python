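"""Configuration-driven orchestration of the full analysis graph.

One YAML config drives, in order: per-site diversity statistics (with the
simulation-based Tajima's D significance test), landscape permeability
optimization, the range-expansion origin map, per-site ABC-RF model choice
and parameter estimation, and the F_ST / Mantel isolation-by-distance
analysis. Each stage writes plain-text artifacts (TSV/JSON/ASCII grid) into
the output directory; a manifest records inputs, seeds, stage wall-clocks
and the artifact list. A stage failure aborts the run with a stage-tagged
error, preserving the artifacts written so far.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .abcrf import (
    PriorSpec,
    SimConfig,
    append_lda_axes,
    build_reference_table,
    rf_model_select,
    rf_param_estimate,
    summarize_sfs,
)
from .errors import ConfigError
from .landscape import (
    PermeabilityConfig,
    build_cost_surface,
    lc_distance_matrix,
    optimize_permeability,
    origin_map,
    read_ascii_grid,
    write_ascii_grid,
)
from .popstruct import fst_perm_test, ibd_fit, mantel, pairwise_fst_matrix
from .sfs import tajimas_d, td_significance, theta_pi, theta_w

__all__ = ["RunConfig", "run_pipeline", "load_config"]

ALL_STAGES = ("diversity", "permeability", "origin", "abc", "popstruct")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    stages: tuple = ALL_STAGES
    sfs: dict = dc_field(default_factory=dict)  # site id -> path
    raster: str | None = None
    site_table: str | None = None
    fst_matrix: str | None = None
    genotypes: dict = dc_field(default_factory=dict)  # site id -> 012 TSV path
    diversity: dict = dc_field(default_factory=dict)
    abc: dict = dc_field(default_factory=dict)
    landscape: dict = dc_field(default_factory=dict)

    def validate(self) -> None:
        problems: list[str] = []
        for st in self.stages:
            if st not in ALL_STAGES:
                problems.append(f"unknown stage {st!r}")
        for sid, path in {**self.sfs, **self.genotypes}.items():
            if not os.path.exists(path):
                problems.append(f"input for site {sid!r} missing: {path}")
        for name in ("raster", "site_table", "fst_matrix"):
            p = getattr(self, name)
            if p is not None and not os.path.exists(p):
                problems.append(f"{name} path missing: {p}")
        if "diversity" in self.stages and not self.sfs:
            problems.append("diversity stage needs at least one SFS input")
        if "permeability" in self.stages and not (self.raster and self.site_table):
            problems.append("permeability stage needs a raster and a site table")
        if "origin" in self.stages and not (self.raster and self.site_table):
            problems.append("origin stage needs a raster and a site table")
        if "popstruct" in self.stages and not (self.genotypes or self.fst_matrix):
            problems.append("popstruct stage needs genotypes or an F_ST matrix")
        if problems:
            raise ConfigError("invalid run configuration:\n  - " + "\n  - ".join(problems))


def load_config(path: str | os.PathLike) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = Path(path).parent

    def _abs(p):
        return str(base / p) if p is not None and not os.path.isabs(str(p)) else p

    raw["sfs"] = {str(k): _abs(v) for k, v in (raw.get("sfs") or {}).items()}
    raw["genotypes"] = {str(k): _abs(v) for k, v in (raw.get("genotypes") or {}).items()}
    for key in ("raster", "site_table", "fst_matrix"):
        if raw.get(key):
            raw[key] = _abs(raw[key])
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    known = RunConfig.__dataclass_fields__.keys()
    unknown = [k for k in raw if k not in known]
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    return RunConfig(**raw)


def run_pipeline(config: RunConfig, log=print) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    stage_seeds = {st: int(s.generate_state(1)[0] % (2**31 - 1)) for st, s in
                   zip(ALL_STAGES, master.spawn(len(ALL_STAGES)))}
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "stages": {},
        "artifacts": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    state: dict = {}

    def _artifact(path: Path) -> None:
        manifest["artifacts"].append(str(path.relative_to(out)))

    runners = {
        "diversity": _stage_diversity,
        "permeability": _stage_permeability,
        "origin": _stage_origin,
        "abc": _stage_abc,
        "popstruct": _stage_popstruct,
    }
    for st in ALL_STAGES:
        if st not in config.stages:
            continue
        t0 = time.time()
        log(f"[{st}] starting (seed={stage_seeds[st]})")
        try:
            runners[st](config, out, stage_seeds[st], state, _artifact)
        except Exception as exc:
            manifest["stages"][st] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage '{st}' failed: {exc}") from exc
        dt = time.time() - t0
        manifest["stages"][st] = {"status": "ok", "seconds": round(dt, 3)}
        log(f"[{st}] done in {dt:.1f}s")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _load_sites(config: RunConfig, state: dict) -> pd.DataFrame:
    if "sites" in state:
        return state["sites"]
    sites = rio.read_site_table(config.site_table)
    if "diversity" in state:
        div = state["diversity"].set_index("id")["theta_pi"]
        sites = sites.copy()
        sites["theta_pi"] = sites["id"].map(div).fillna(sites.get("theta_pi"))
    state["sites"] = sites
    return sites


def _stage_diversity(config, out, seed, state, artifact):
    opts = config.diversity
    nsim = int(opts.get("td_nsim", 1000))
    gen = np.random.default_rng(seed)
    rows = []
    for sid, path in sorted(config.sfs.items()):
        sfs = rio.read_sfs(path)
        n_loci_null = int(opts.get("n_loci", 1))
        p = (td_significance(sfs, nsim=nsim, rng=gen, n_loci=n_loci_null)
             if sfs.S > 0 and nsim > 0 else None)
        rows.append({
            "id": sid, "n": sfs.n, "L": sfs.L, "S": sfs.S,
            "theta_pi": theta_pi(sfs), "theta_w": theta_w(sfs),
            "tajimas_d": tajimas_d(sfs) if sfs.S > 0 else np.nan,
            "td_p": p,
        })
    df = pd.DataFrame(rows)
    df.to_csv(out / "diversity.tsv", sep="\t", index=False)
    artifact(out / "diversity.tsv")
    state["diversity"] = df
    state["sfs"] = {sid: rio.read_sfs(path) for sid, path in config.sfs.items()}


def _stage_permeability(config, out, seed, state, artifact):
    raster = read_ascii_grid(config.raster)
    sites = _load_sites(config, state)
    if config.fst_matrix:
        fst = rio.read_distance_matrix(config.fst_matrix).loc[sites["id"], sites["id"]].to_numpy()
    else:
        raise ConfigError("permeability optimization needs an F_ST matrix input")
    opts = config.landscape
    best, profile = optimize_permeability(
        raster, sites, fst,
        objective=opts.get("objective", "fst_lin"),
        refine_step=float(opts.get("refine_step", 0.01)),
    )
    pd.DataFrame(profile, columns=["p_reef", "p_seamount", "r"]).to_csv(
        out / "perm_profile.tsv", sep="\t", index=False)
    artifact(out / "perm_profile.tsv")
    r_best = max(p[2] for p in profile)
    (out / "permeability.json").write_text(json.dumps({
        "p_reef": best.p_reef, "p_seamount": best.p_seamount, "r": r_best}, indent=2))
    artifact(out / "permeability.json")
    state["perm"] = best
    state["raster"] = raster


def _stage_origin(config, out, seed, state, artifact):
    raster = state.get("raster") or read_ascii_grid(config.raster)
    sites = _load_sites(config, state)
    perm = state.get("perm")
    if perm is None:
        opts = config.landscape
        perm = PermeabilityConfig(float(opts.get("p_reef", 1.0)), float(opts.get("p_seamount", 1.0)))
    om = origin_map(raster, sites, perm)
    write_ascii_grid(om, out / "origin_map.asc")
    artifact(out / "origin_map.asc")
    r, c = om.argmin
    (out / "origin.json").write_text(json.dumps({
        "argmin_row": int(r), "argmin_col": int(c),
        "r_min": float(np.nanmin(om.values))}, indent=2))
    artifact(out / "origin.json")
    state["origin"] = om


def _stage_abc(config, out, seed, state, artifact):
    opts = config.abc
    prior = PriorSpec()
    nsim = int(opts.get("nsim_per_model", 1000))
    trees = int(opts.get("n_trees", 500))
    models = list(opts.get("models", ["NS", "FIM", "SST"]))
    gen = np.random.default_rng(seed)
    sfs_by_site = state.get("sfs") or {sid: rio.read_sfs(p) for sid, p in config.sfs.items()}
    for sid, sfs in sorted(sfs_by_site.items()):
        cfg = SimConfig(
            n_dip=sfs.n // 2,
            n_loci=int(opts.get("n_loci", 500)),
            locus_len=int(opts.get("locus_len", 100)),
        )
        table = build_reference_table(models, prior, nsim, cfg, rng=gen)
        table.df.to_csv(out / f"abc_table_{sid}.tsv", sep="\t", index=False)
        artifact(out / f"abc_table_{sid}.tsv")
        obs = summarize_sfs(sfs)
        table_l, obs_l = append_lda_axes(table, obs)
        post = rf_model_select(table_l, obs_l, n_trees=trees, rng=gen)
        report = {
            "site": sid,
            "selected": post.selected,
            "posterior_probability": post.posterior_probability,
            "votes": post.votes,
            "oob_error": post.oob_error,
            "confusion": post.confusion.to_dict(),
            "params": {},
        }
        from .abcrf import MODEL_PARAMS, ReferenceTable

        sub = table_l.df[table_l.df["model"] == post.selected].reset_index(drop=True)
        sub_table = ReferenceTable(df=sub, n_haploid=table_l.n_haploid, config=cfg)
        for param in MODEL_PARAMS[post.selected]:
            pp = rf_param_estimate(sub_table, obs_l, param, n_trees=trees, rng=gen)
            report["params"][param] = {
                "median": pp.median, "q025": pp.q025, "q975": pp.q975,
                "oob_rmse": pp.oob_rmse,
            }
        (out / f"abc_{sid}.json").write_text(json.dumps(report, indent=2))
        artifact(out / f"abc_{sid}.json")


def _stage_popstruct(config, out, seed, state, artifact):
    gen = np.random.default_rng(seed)
    report: dict = {}
    sites = None
    if config.site_table:
        sites = _load_sites(config, state)
    if config.genotypes:
        ids = sorted(config.genotypes)
        pops = []
        for sid in ids:
            G = rio.read_012(config.genotypes[sid]).to_numpy()
            pops.append(rio.genotypes_to_haplotypes(G, rng=gen))
        # align site columns: generated fixtures share columns; otherwise F_ST
        # is computed on the shared leading columns
        ncol = min(p.shape[1] for p in pops)
        pops = [p[:, :ncol] for p in pops]
        F, overall = pairwise_fst_matrix(pops)
        rio.write_distance_matrix(F, ids, out / "fst_matrix.tsv")
        artifact(out / "fst_matrix.tsv")
        pvals = {}
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                res = fst_perm_test(pops[i], pops[j], n_perm=1000, rng=gen)
                pvals[f"{ids[i]}|{ids[j]}"] = {"fst": res.fst, "p": res.p_value}
        report["overall_fst"] = overall
        report["pairwise"] = pvals
        fst_df = pd.DataFrame(F, index=ids, columns=ids)
    if config.fst_matrix:
        # an explicitly supplied matrix (e.g. full-panel F_ST) takes precedence
        # for the IBD analysis, keeping it consistent with the landscape stages
        fst_df = rio.read_distance_matrix(config.fst_matrix)
        ids = list(fst_df.index)
    if sites is not None and config.raster is not None:
        raster = state.get("raster") or read_ascii_grid(config.raster)
        perm = state.get("perm") or PermeabilityConfig(1.0, 1.0)
        surf = build_cost_surface(raster, perm)
        s = sites.set_index("id").loc[[i for i in ids if i in set(sites["id"])]]
        cells = [(int(r), int(c)) for r, c in zip(s["row"], s["col"])]
        if len(cells) >= 3:
            D = lc_distance_matrix(surf, cells)
            Fsub = fst_df.loc[s.index, s.index].to_numpy()
            Flin = np.clip(Fsub, 0.0, None)
            mres = mantel(Flin / (1.0 - Flin), D, rng=gen)
            slope, intercept, r = ibd_fit(Fsub, D)
            report["ibd"] = {
                "mantel_r": mres.r, "mantel_p": mres.p_value,
                "slope": slope, "intercept": intercept, "pearson_r": r,
            }
    (out / "popstruct.json").write_text(json.dumps(report, indent=2))
    artifact(out / "popstruct.json")
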