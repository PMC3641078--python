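"""End-to-end analysis pipeline: filter -> additive fit -> bin transform ->
epistatic path fit -> selection -> noise accounting -> classification ->
landscape exploration (-> two-environment Pareto analysis).

`run_pipeline` composes the library modules into one reproducible run; a
config object carries every tunable and every seed, and each artifact is
written into the run directory with the config echoed alongside so a run
can be regenerated byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import additive, classify, codec, epistasis, landscape, noise
from .codec import RegionMap

log = logging.getLogger("promland.pipeline")


@dataclass
class PipelineConfig:
    wildtype: str
    K: int = 9
    conditions: list[str] | None = None        # None -> use all present
    max_mutations: int = 20
    collapse_same_bin_duplicates: bool = True
    region_map_report: dict | None = None      # -L..-1 half-open coords
    # epistatic fit
    order: int = 2
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    n_folds: int = 10
    n_random: int = 1000
    variance_cap_ratio: float = 2.0
    fit_third_order_subset: list[int] | None = None
    # landscape exploration
    n_walks: int = 200
    n_phenotype_sample: int = 10_000
    # seeds
    seed: int = 0

    def region_map(self) -> RegionMap:
        if self.region_map_report is None:
            return RegionMap.default(len(self.wildtype))
        return RegionMap.from_report_coords(
            {k: tuple(v) for k, v in self.region_map_report.items()},
            len(self.wildtype),
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _fit_one_condition(records: pd.DataFrame, config: PipelineConfig) -> dict:
    """Additive + transform + epistatic fit for one condition's records."""
    wt = config.wildtype
    X1, _ = codec.build_design_matrix(records, wt, order=1)
    bins = records["bin"].to_numpy()

    _, raw_summary = additive.fit_additive_ols(X1, bins.astype(float))
    g, add_model, add_summary = additive.optimize_bin_transform(X1, bins, K=config.K)
    gy = additive.transform_response(bins, g)

    path, selection = epistasis.fit_epistatic(
        records["sequence"].tolist(),
        gy,
        wt,
        order=config.order,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
        n_folds=config.n_folds,
        n_random=config.n_random,
        variance_cap_ratio=config.variance_cap_ratio,
        seed=config.seed,
    )
    return {
        "g": g,
        "gy": gy,
        "r2_raw": raw_summary.r_squared,
        "r2_transformed": add_summary.r_squared,
        "additive_model": add_model,
        "path": path,
        "selection": selection,
        "variance_raw": float(np.var(bins, ddof=1)),
        "variance_gy": float(np.var(gy, ddof=1)),
    }


def run_pipeline(
    records: pd.DataFrame,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    control_g_bins: np.ndarray | None = None,
) -> dict:
    """Execute the full analysis and return (and optionally write) the bundle.

    ``control_g_bins`` are optional replicate wild-type bin measurements
    used for the control-based noise estimate.  Stages abort with a
    stage-labeled error; every random stage draws from ``config.seed``.
    """
    t0 = time.time()
    bundle: dict = {"config": asdict(config), "config_hash": config.config_hash()}
    wt = config.wildtype
    region_map = config.region_map()

    def stage(name):
        log.info("stage %-12s t=%.1fs", name, time.time() - t0)

    try:
        stage("filter")
        conditions = config.conditions or sorted(records["condition"].unique())
        records = records[records["condition"].isin(conditions)]
        filtered, filter_report = codec.filter_records(
            records, wt, config.max_mutations, config.collapse_same_bin_duplicates
        )
        bundle["filter_report"] = filter_report
    except Exception as e:
        raise RuntimeError(f"stage 'filter' failed: {e}") from e

    per_condition: dict[str, dict] = {}
    for cond in conditions:
        sub = filtered[filtered["condition"] == cond].reset_index(drop=True)
        if len(sub) == 0:
            continue
        try:
            stage(f"fit[{cond}]")
            per_condition[cond] = _fit_one_condition(sub, config)
            per_condition[cond]["records"] = sub
        except Exception as e:
            raise RuntimeError(f"stage 'fit[{cond}]' failed: {e}") from e

    main_cond = conditions[0]
    main = per_condition[main_cond]
    sel_model = main["selection"].model

    try:
        stage("noise")
        g = main["g"]
        ctrl = (
            additive.transform_response(np.asarray(control_g_bins), g)
            if control_g_bins is not None
            else None
        )
        bundle["noise"] = noise.noise_report(main["records"], g, ctrl)
        nf_hi = bundle["noise"]["duplicate_upper_bound"]
        nf_lo = bundle["noise"]["control_lower_estimate"]
        shares = {}
        k = main["selection"].selected_index
        r2_add = main["r2_transformed"]
        r2_epi = float(main["path"].r2_in[k])
        for tag, nf in (("upper_noise", nf_hi), ("lower_noise", nf_lo)):
            if nf is not None and 0 <= nf < 1:
                shares[tag] = {
                    "noise_fraction": nf,
                    "additive_share": noise.explainable_variance_share(r2_add, nf),
                    "epistasis_share": noise.epistasis_variance_share(
                        r2_epi, r2_add, nf
                    ),
                }
        bundle["explainable_variance"] = shares
    except Exception as e:
        raise RuntimeError(f"stage 'noise' failed: {e}") from e

    try:
        stage("classify")
        bundle["census"] = classify.census(sel_model)
        bundle["zero_beta_cases"] = len(classify.classify_zero_beta_cases(sel_model))
        bundle["block_table"] = classify.grouped_block_table(sel_model, region_map)
        bundle["profiles"] = classify.sitewise_magnitude_profiles(sel_model)
    except Exception as e:
        raise RuntimeError(f"stage 'classify' failed: {e}") from e

    try:
        stage("explore")
        bundle["random_phenotypes"] = {
            k: v
            for k, v in landscape.random_phenotype_sample(
                sel_model, wt, n=config.n_phenotype_sample, seed=config.seed + 2
            ).items()
            if k != "predictions"
        }
        bundle["walk_census"] = landscape.walk_census(
            sel_model, wt, n_walks=config.n_walks, seed=config.seed + 3
        )
    except Exception as e:
        raise RuntimeError(f"stage 'explore' failed: {e}") from e

    if len(per_condition) >= 2:
        try:
            stage("pareto")
            cond_a, cond_b = conditions[0], conditions[1]
            rep = landscape.pareto_analysis(
                per_condition[cond_a]["selection"].model,
                per_condition[cond_b]["selection"].model,
                per_condition[cond_a]["records"]["sequence"].tolist(),
                wt,
                seed=config.seed + 4,
            )
            bundle["pareto"] = {
                "conditions": (cond_a, cond_b),
                "wildtype_pred": rep.wildtype_pred,
                "fraction_dominating": rep.fraction_dominating,
                "random_fraction_dominating": rep.random_fraction_dominating,
            }
        except Exception as e:
            raise RuntimeError(f"stage 'pareto' failed: {e}") from e

    bundle["per_condition"] = per_condition
    bundle["main_condition"] = main_cond
    if out_dir is not None:
        write_bundle(bundle, out_dir, wildtype=wt)
    stage("done")
    return bundle


def write_bundle(bundle: dict, out_dir: str | Path, wildtype: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dict(bundle["config"])
    cfg["config_hash"] = bundle["config_hash"]
    (out / "config.json").write_text(json.dumps(cfg, indent=1))
    (out / "filter_report.json").write_text(json.dumps(bundle["filter_report"], indent=1))
    (out / "noise.json").write_text(json.dumps(bundle["noise"], indent=1))
    (out / "explainable_variance.json").write_text(
        json.dumps(bundle["explainable_variance"], indent=1)
    )
    bundle["block_table"].to_csv(out / "block_table.tsv", sep="\t")
    bundle["walk_census"].to_csv(out / "walk_census.tsv", sep="\t", index=False)
    for cond, res in bundle["per_condition"].items():
        res["path"].to_table().to_csv(out / f"path_{cond}.tsv", sep="\t", index=False)
        res["selection"].model.save_json(out / f"model_{cond}.json", wildtype)
        fit_report = {
            "condition": cond,
            "r2_raw": res["r2_raw"],
            "r2_transformed": res["r2_transformed"],
            "g": res["g"].values.tolist(),
            "variance_raw_bins": res["variance_raw"],
            "variance_g_y": res["variance_gy"],
            "selected_lambda": res["selection"].selected_lambda,
            "cv_optimal_lambda": res["selection"].cv_optimal_lambda,
            "alpha": res["additive_model"].alpha,
        }
        (out / f"fit_{cond}.json").write_text(json.dumps(fit_report, indent=1))


def summarize(bundle: dict) -> str:
    """One-page human-readable summary of a report bundle."""
    lines: list[str] = []
    missing: list[str] = []
    main = bundle.get("per_condition", {}).get(bundle.get("main_condition", ""), {})

    lines.append("== Promoter landscape analysis summary ==")
    lines.append(f"config hash: {bundle.get('config_hash', '?')}")

    if main:
        lines.append("\n-- Fit --")
        lines.append(
            f"R^2 raw bins:         {main['r2_raw']:.3f}\n"
            f"R^2 transformed g(y): {main['r2_transformed']:.3f}"
        )
        k = main["selection"].selected_index
        lines.append(
            f"epistatic R^2 (selected lambda={main['selection'].selected_lambda:.4g}): "
            f"{main['path'].r2_in[k]:.3f}  [CV {main['path'].r2_cv[k]:.3f}]"
        )
        lines.append(
            f"bin variance raw -> transformed: {main['variance_raw']:.2f} -> "
            f"{main['variance_gy']:.2f}"
        )
    else:
        missing.append("fit")

    if "noise" in bundle:
        nz = bundle["noise"]
        hi = nz["duplicate_upper_bound"]
        lo = nz["control_lower_estimate"]
        lines.append("\n-- Intrinsic noise --")
        lines.append(
            f"noise interval: {'' if lo is None else f'{100 * lo:.0f}%'}"
            f"-{'' if hi is None else f'{100 * hi:.0f}%'} "
            f"({nz['n_duplicate_groups']} duplicate groups)"
        )
    else:
        missing.append("noise")

    if "explainable_variance" in bundle:
        lines.append("\n-- Explainable variance --")
        for tag, s in bundle["explainable_variance"].items():
            lines.append(
                f"{tag}: additive {100 * s['additive_share']:.0f}%, "
                f"epistasis {100 * s['epistasis_share']:.0f}% "
                f"(noise {100 * s['noise_fraction']:.0f}%)"
            )
    else:
        missing.append("explainable_variance")

    if "census" in bundle:
        c = bundle["census"]
        lines.append("\n-- Epistasis census --")
        lines.append(
            f"nonzero J: {c['nonzero']}  sum|J|: {c['sum_abs_J']:.1f}  "
            f"antagonistic {c['antagonistic']}  synergistic {c['synergistic']}  "
            f"sign {c['sign']}  unclassified {c['unclassified']}"
        )
        if "block_table" in bundle:
            lines.append(bundle["block_table"].to_string())
    else:
        missing.append("census")

    if "random_phenotypes" in bundle:
        rp = bundle["random_phenotypes"]
        lines.append("\n-- Random sequences --")
        lines.append(
            f"neutral mode region: [{rp['mode_region'][0]:.2f}, {rp['mode_region'][1]:.2f}]  "
            f"wild type: {rp['wildtype_value']:.2f} "
            f"(percentile {rp['wildtype_percentile']:.1f})"
        )
    else:
        missing.append("random_phenotypes")

    if "walk_census" in bundle:
        wc = bundle["walk_census"]
        lines.append("\n-- Adaptive walks --")
        lines.append(
            f"distinct endpoints: {len(wc)}; top endpoint visited "
            f"{int(wc['count'].iloc[0])}x at Hamming distance "
            f"{int(wc['hamming_to_wildtype'].iloc[0])}"
        )
    else:
        missing.append("walks")

    if "pareto" in bundle:
        p = bundle["pareto"]
        lines.append("\n-- Two environments --")
        lines.append(
            f"{p['conditions'][0]} vs {p['conditions'][1]}: "
            f"{100 * p['fraction_dominating']:.2f}% of library sequences dominate the "
            f"wild type (random sequences: "
            f"{100 * (p['random_fraction_dominating'] or 0):.2f}%)"
        )

    if missing:
        lines.append(f"\n[missing sections: {', '.join(missing)}]")
    return "\n".join(lines)
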