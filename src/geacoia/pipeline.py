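"""End-to-end orchestration: simulate/load -> variable reduction -> RDA ->
candidate split -> co-inertia -> divergence -> diversity regression, driven
by one YAML config, with per-stage seeds derived deterministically from a
single global seed and a run manifest recording every threshold, seed and
output hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from geacoia import __version__, coia, data_io, divergence, diversity_regression
from geacoia import rda_gea, synthetic_data, variable_reduction

log = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "stage_seed", "run_all"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": None,        # dict of SimConfig fields, or None when inputs given
    "inputs": None,          # {"genotypes":…, "format":"vcf", "samples":…, "climate":…}
    "predictors": ["BIO12", "BIO01", "BIO02"],
    "variable_reduction": {
        "enabled": False, "k": "auto", "drop_fraction": 0.10, "max_vif": 10.0,
    },
    "rda": {
        "n_perm": 999, "sd_mult": 2.5, "alpha": 0.05, "scale": False, "impute": "mode",
    },
    "split": {"known_outliers": []},
    "coia": {
        "retain": 0.90, "truncate": True, "n_perm": 999, "n_boot": 1000,
        "disjoint": True,
    },
    "divergence": {"coverage": 0.947, "k_axes": None},
    "regression": {
        "climate_vars": ["BIO01", "BIO12"], "min_n": 4, "unbiased_he": False,
    },
}

_STAGES = ["data", "reduce", "rda", "split", "coia", "divergence", "regression"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed and stage index mixed
    through SHA-256, truncated below 2^31."""
    i = _STAGES.index(stage)
    h = hashlib.sha256(f"{seed}:{i}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def validate_config(config: dict, schema: dict | None = None, path: str = "") -> None:
    """Reject unknown keys anywhere in the config, naming the key."""
    schema = DEFAULT_CONFIG if schema is None else schema
    for key, val in config.items():
        if key not in schema:
            raise ValueError(f"unknown config key: {path + key}")
        ref = schema[key]
        if isinstance(ref, dict) and isinstance(val, dict) and key != "simulate" \
                and key != "inputs":
            validate_config(val, ref, path=f"{path}{key}.")


def _merge(default: dict, user: dict) -> dict:
    out = {}
    for k, v in default.items():
        if k in user and isinstance(v, dict) and isinstance(user[k], dict):
            out[k] = _merge(v, user[k])
        elif k in user:
            out[k] = user[k]
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    if overrides:
        user = _merge(user, overrides) if user else dict(overrides)
    validate_config(user)
    return _merge(DEFAULT_CONFIG, user)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj: Any, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


@dataclasses.dataclass
class RunResult:
    out_dir: Path
    manifest: dict
    tables: dict[str, Any]


def _load_data(config: dict, out: Path, seed: int):
    if config["simulate"] is not None and config["inputs"] is not None:
        raise ValueError("give either 'simulate' or 'inputs', not both")
    if config["simulate"] is not None:
        sim_kwargs = dict(config["simulate"])
        if isinstance(sim_kwargs.get("inds_per_site"), list):
            sim_kwargs["inds_per_site"] = tuple(sim_kwargs["inds_per_site"])
        sim_kwargs.setdefault("seed", seed)
        sim = synthetic_data.SimConfig(**sim_kwargs)
        g, samples, climate, truth = synthetic_data.simulate_dataset(sim)
        synthetic_data.write_fixture((g, samples, climate, truth), out / "data", force=True)
        return g, samples, climate, truth
    if config["inputs"] is None:
        raise ValueError("config needs either 'simulate' or 'inputs'")
    inp = config["inputs"]
    g = data_io.read_genotypes(inp["genotypes"], format=inp.get("format", "vcf"))
    samples = data_io.read_samples(inp["samples"])
    climate = data_io.read_climate(inp["climate"])
    # hard error on genotyped individuals without metadata
    samples.site_of(g.individual_ids)
    return g, samples, climate, None


def run_all(config: dict, out_dir: str | Path) -> RunResult:
    """Execute every stage in order, writing tables, stage summaries and
    a manifest under ``out_dir``.  Halts on the first stage error; the
    manifest records the status of every stage reached."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": config,
        "stage_seeds": {s: stage_seed(seed, s) for s in _STAGES},
        "stages": {},
        "outputs": {},
    }
    tables: dict[str, Any] = {}
    current = "data"
    try:
        # ---- data ------------------------------------------------------
        g, samples, climate, truth = _load_data(config, out, stage_seed(seed, "data"))
        tables.update(genotypes=g, samples=samples, climate=climate, truth=truth)
        manifest["stages"]["data"] = {
            "status": "ok", "n_individuals": g.n_individuals, "n_loci": g.n_loci,
            "n_sites": int(samples.df["site_id"].nunique()),
            "n_basins": int(samples.df["basin_id"].nunique()),
        }

        # ---- variable reduction ---------------------------------------
        current = "reduce"
        vr = config["variable_reduction"]
        predictors = list(config["predictors"])
        if vr["enabled"]:
            clv = variable_reduction.clv_cluster(
                climate, k=vr["k"], drop_fraction=vr["drop_fraction"])
            reps = [clv.representatives[c] for c in sorted(clv.representatives)]
            if len(reps) >= 2:
                kept, vif_table = variable_reduction.vif_screen(
                    climate, reps, max_vif=vr["max_vif"])
                vif_table.to_csv(out / "vif_trace.tsv", sep="\t", index=False)
            else:
                kept = reps
            predictors = kept
            manifest["stages"]["reduce"] = {
                "status": "ok", "k": clv.k, "representatives": reps,
                "kept_after_vif": kept, "criterion": clv.criterion,
            }
        else:
            manifest["stages"]["reduce"] = {
                "status": "skipped", "predictors": predictors}
        tables["predictors"] = predictors

        # ---- RDA -------------------------------------------------------
        current = "rda"
        rcfg = config["rda"]
        Y, _ = data_io.impute_and_center(g, impute=rcfg["impute"], scale=rcfg["scale"])
        clim_ind = data_io.climate_for_individuals(
            climate, samples, g.individual_ids, predictors)
        res = rda_gea.run_rda(
            Y, clim_ind.to_numpy(), n_perm=rcfg["n_perm"],
            seed=stage_seed(seed, "rda"), predictor_names=predictors,
            locus_ids=g.locus_ids)
        sig_axes = res.significant_axes(rcfg["alpha"])
        candidates = rda_gea.detect_outlier_loci(res, sig_axes, rcfg["sd_mult"])
        if len(candidates):
            assign = rda_gea.assign_driving_variable(
                g, list(candidates.index), clim_ind)
            candidates = candidates.join(assign)
        candidates.to_csv(out / "candidates.tsv", sep="\t")
        pd.DataFrame(res.locus_loadings,
                     index=g.locus_ids,
                     columns=[f"RDA{a + 1}" for a in range(res.n_axes)]
                     ).to_csv(out / "rda_loadings.tsv", sep="\t")
        manifest["stages"]["rda"] = {
            "status": "ok", "r2": res.r2, "adj_r2": res.adj_r2,
            "pseudo_f": res.pseudo_f, "global_p": res.global_p,
            "axis_p": list(res.axis_p), "significant_axes": sig_axes,
            "n_candidates": int(len(candidates)), "n_perm": rcfg["n_perm"],
            "sd_mult": rcfg["sd_mult"],
        }
        tables["rda"] = res
        tables["candidates"] = candidates
        if len(candidates) < 2:
            raise RuntimeError("fewer than 2 candidate loci detected; "
                               "co-inertia coupling is not meaningful")

        # ---- split -----------------------------------------------------
        current = "split"
        split = rda_gea.split_candidates(
            g, list(candidates.index), config["split"]["known_outliers"],
            seed=stage_seed(seed, "split"))
        manifest["stages"]["split"] = {
            "status": "ok", "pool_size": len(split.noncandidate_pool),
            "sample_size": len(split.noncandidate_sample),
            "seed": split.sample_seed,
        }
        tables["split"] = split

        # ---- co-inertia ------------------------------------------------
        current = "coia"
        ccfg = config["coia"]
        Xc, _ = data_io.impute_and_center(g.subset_loci(list(candidates.index)))
        Xn, _ = data_io.impute_and_center(g.subset_loci(split.noncandidate_sample))
        tri_n = coia.pca_triplet(Xn, retain=ccfg["retain"], row_ids=g.individual_ids)
        tri_c = coia.pca_triplet(Xc, retain=ccfg["retain"], row_ids=g.individual_ids)
        cres = coia.coinertia(tri_n, tri_c, truncate=ccfg["truncate"],
                              n_perm=ccfg["n_perm"], seed=stage_seed(seed, "coia"))
        pool_table = g.subset_loci(split.noncandidate_pool)
        boot = coia.bootstrap_rv_null(
            pool_table, subset_size=len(candidates), n_boot=ccfg["n_boot"],
            disjoint=ccfg["disjoint"], seed=stage_seed(seed, "coia"),
            observed_rv=cres.rv)
        arrows = pd.DataFrame(
            np.hstack([cres.rowscores_A, cres.rowscores_B]),
            index=g.individual_ids,
            columns=[f"noncand_ax{a + 1}" for a in range(cres.n_axes)]
            + [f"cand_ax{a + 1}" for a in range(cres.n_axes)])
        arrows.to_csv(out / "coia_arrows.tsv", sep="\t")
        manifest["stages"]["coia"] = {
            "status": "ok", "rv": cres.rv, "rv_p": cres.rv_p,
            "total_coinertia": cres.total_coinertia,
            "cum_frac_3axes": float(cres.cum_coinertia_frac[min(2, cres.n_axes - 1)]),
            "retained_axes": [tri_n.retained_axes, tri_c.retained_axes],
            "bootstrap": {"p_low": boot.p_low, **boot.quantiles,
                          "n_boot": boot.n_boot, "disjoint": boot.disjoint},
        }
        tables["coia"] = cres
        tables["bootstrap"] = boot

        # ---- divergence ------------------------------------------------
        current = "divergence"
        dcfg = config["divergence"]
        div = divergence.individual_divergence(
            cres, k_axes=dcfg["k_axes"],
            coverage=dcfg["coverage"] if dcfg["k_axes"] is None else None,
            samples=samples)
        div.df.to_csv(out / "divergence.tsv", sep="\t")
        anova = divergence.geographic_anova(div)
        manifest["stages"]["divergence"] = {
            "status": "ok", "axes_used": div.axes_used,
            "coverage": div.coinertia_fraction_covered,
            "F_basin": anova["F_basin"], "df_basin": anova["df_basin"],
            "p_basin": anova["p_basin"],
            "F_site_within_basin": anova["F_site_within_basin"],
            "df_site_within_basin": anova["df_site_within_basin"],
            "p_site_within_basin": anova["p_site_within_basin"],
        }
        tables["divergence"] = div
        tables["anova"] = anova

        # ---- regression ------------------------------------------------
        current = "regression"
        gcfg = config["regression"]
        he_n = diversity_regression.expected_heterozygosity(
            g, samples, split.noncandidate_sample, min_n=gcfg["min_n"],
            unbiased=gcfg["unbiased_he"])
        he_c = diversity_regression.expected_heterozygosity(
            g, samples, list(candidates.index), min_n=gcfg["min_n"],
            unbiased=gcfg["unbiased_he"])
        he_cor = diversity_regression.he_correlation(he_c, he_n)
        summary = diversity_regression.population_summary(
            div.df, he_n, he_c, climate, gcfg["climate_vars"])
        summary.to_csv(out / "population_summary.tsv", sep="\t")
        report = diversity_regression.best_subset_aicc(
            summary, climate_vars=gcfg["climate_vars"])
        report.aicc_table.to_csv(out / "aicc_table.tsv", sep="\t", index=False)
        clim_sel = [t for t in report.selected_terms
                    if not t.startswith("He_")]
        he_sel = [t for t in report.selected_terms if t.startswith("He_")]
        varpart = None
        if clim_sel and he_sel:
            varpart = diversity_regression.variation_partition(
                summary, clim_sel, he_sel)
        confound = diversity_regression.confound_check(summary)
        manifest["stages"]["regression"] = {
            "status": "ok", "he_correlation": he_cor,
            "selected_terms": report.selected_terms, "adj_r2": report.adj_r2,
            "f_stat": report.f_stat, "df": list(report.df), "p": report.p,
            "varpart": varpart, "confound": confound,
        }
        tables["regression"] = report
        tables["summary"] = summary
    except Exception as exc:
        manifest["stages"].setdefault(current, {})
        manifest["stages"][current]["status"] = "failed"
        manifest["stages"][current]["error"] = str(exc)
        _finalize_manifest(manifest, out)
        raise RuntimeError(f"stage '{current}' failed: {exc}") from exc

    _finalize_manifest(manifest, out)
    return RunResult(out_dir=out, manifest=manifest, tables=tables)


def _finalize_manifest(manifest: dict, out: Path) -> None:
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
    _write_json(manifest, out / "manifest.json")
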