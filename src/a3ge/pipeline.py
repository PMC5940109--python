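"""Config-driven orchestration: simulate -> quantify -> drift -> telomere -> rate.

``run_pipeline`` executes the stages in dependency order on synthetic
data (or user-supplied tables), writes every stage output as plain text,
and consolidates the numbers into one JSON report with provenance
(package version, seed, config hash).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .aging import A3gePoint, fit_a3ge_trajectory
from .drift import (
    DriftConfig,
    category_analysis,
    compare_groups,
    drift_by_tier,
    group_means,
    pca_overview,
    select_leg_heg,
    summarize_dispersion,
)
from .panel import PanelSpec, make_panel
from .quantify import compute_mr_ratio, correct_fractions
from .simulate import (
    DriftParams,
    SeqParams,
    TelomereSimParams,
    default_study_design,
    simulate_counts,
    simulate_expression,
    simulate_telomere_ct,
    write_calibration_tsv,
    write_counts_tsv,
    write_counts_vcf,
    write_ct_csv,
    write_expression_tsv,
    write_metadata_tsv,
    write_panel_tsv,
    write_sites_bed,
    write_sites_tsv,
)
from .telomere import (
    acceleration,
    calibrate_from_ct_table,
    hd_adjustment,
    infer_bio_age,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulation": {
        "n_genes": 175,
        "n_amplicons": 285,
        "mean_depth_per_amplicon": 20_000,
        "nb_dispersion": 0.1,
        "bias_sd_log2": 0.2,
        "telomere_ct_noise_sd": 0.02,
        "write_vcf": True,
    },
    "quantify": {"min_total_reads": 50},
    "drift": {
        "log_base": 2,
        "a3ge_variant": "one_minus_m_squared",
        "tier_n": 50,
        "reference_tissue_group": "wy",
        "min_category_features": 5,
    },
    "telomere": {
        "baseline_age_months": 2.0,
        "fit_on": "age_means",
        "query_ratio": 0.69,
        "query_chrono_age_months": 19.0,
    },
    "rate": {"level": 0.5},
}

REQUIRED_SECTIONS = ("simulation", "quantify", "drift", "telomere", "rate")


class ConfigError(ValueError):
    """Invalid run configuration."""


def validate_config(raw: dict | None) -> dict:
    """Merge a user config over the defaults.

    Unknown keys are warned about but kept; wrong-typed sections fail
    with a message naming the key.
    """
    config = copy.deepcopy(DEFAULT_CONFIG)
    if raw is None:
        return config
    if not isinstance(raw, dict):
        raise ConfigError("config must be a JSON object")
    errors = []
    for key, value in raw.items():
        if key == "seed":
            config["seed"] = int(value)
            continue
        if key not in DEFAULT_CONFIG:
            logger.warning("config: unknown top-level key %r (kept)", key)
            config[key] = value
            continue
        if not isinstance(value, dict):
            errors.append(f"section {key!r} must be an object")
            continue
        for sub, sub_value in value.items():
            if sub not in DEFAULT_CONFIG[key]:
                logger.warning("config: unknown key %s.%s (kept)", key, sub)
            config[key][sub] = sub_value
    if errors:
        raise ConfigError("; ".join(errors))
    return config


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(json.load(fh))


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(
    config: dict | None = None,
    outdir: str | Path = "a3ge_run",
    seed: int | None = None,
) -> dict:
    """Run the full synthetic demo and return the consolidated report.

    Stages: simulate the study design (amplicon panel, drifting latent
    expression, competitive counts, telomere Ct tables), quantify the
    counts into corrected M/R ratios, compute drift statistics for every
    tissue's young-vs-X contrasts, calibrate the telomere clock and
    age-adjust the disease group, and fit the A3GE-vs-age rate model.
    """
    config = validate_config(config)
    if seed is not None:
        config["seed"] = int(seed)
    seed = int(config["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "package": "a3ge",
            "version": __version__,
            "seed": seed,
            "config_hash": _config_hash(config),
        },
        "outputs": {},
    }

    def _write(name, writer, *args):
        path = outdir / name
        writer(*args, path)
        report["outputs"][name] = str(path)
        return path

    # --- stage: simulate -------------------------------------------------
    logger.info("[simulate] generating panel, expression, counts, Ct tables")
    sim_cfg = config["simulation"]
    spec = PanelSpec(
        n_genes=int(sim_cfg["n_genes"]),
        n_amplicons=int(sim_cfg["n_amplicons"]),
    )
    panel = make_panel(spec, seed=seed)
    groups = default_study_design()
    latent = simulate_expression(panel, groups, DriftParams(), seed=seed + 1)
    seq = SeqParams(
        mean_depth_per_amplicon=int(sim_cfg["mean_depth_per_amplicon"]),
        nb_dispersion=float(sim_cfg["nb_dispersion"]),
        bias_sd_log2=float(sim_cfg["bias_sd_log2"]),
        seed=seed + 2,
    )
    counts, calibration = simulate_counts(latent, seq)
    tel_sim = TelomereSimParams(ct_noise_sd=float(sim_cfg["telomere_ct_noise_sd"]))
    ct_table, ct_truth = simulate_telomere_ct(tel_sim, n_replicates=4,
                                              seed=seed + 3)

    _write("panel.tsv", write_panel_tsv, panel)
    _write("sites.tsv", write_sites_tsv, panel)
    _write("sites.bed", write_sites_bed, panel)
    _write("counts.tsv", write_counts_tsv, counts)
    _write("calibration.tsv", write_calibration_tsv, calibration)
    _write("telomere_ct.csv", write_ct_csv, ct_table)
    _write("truth_baseline.tsv",
           lambda s, p: s.to_csv(p, sep="\t", header=True),
           latent.truth["baseline_log2"])
    _write("truth_group_m.tsv",
           lambda s, p: s.to_csv(p, sep="\t", header=True),
           latent.truth["group_m"])
    if sim_cfg.get("write_vcf", True):
        _write("counts.vcf", lambda c, p: write_counts_vcf(panel, c, p), counts)

    # --- stage: quantify -------------------------------------------------
    logger.info("[quantify] correcting fractions and computing M/R ratios")
    corrected = correct_fractions(counts, calibration)
    values = compute_mr_ratio(
        corrected, min_total_reads=int(config["quantify"]["min_total_reads"])
    )
    meta = latent.meta
    n_missing = int(values.isna().sum().sum())
    logger.info(
        "[quantify] %d amplicons x %d samples; %d entries below coverage",
        values.shape[0], values.shape[1], n_missing,
    )
    _write("expression.tsv", write_expression_tsv, values)
    _write("metadata.tsv", write_metadata_tsv, meta)

    # --- stage: drift ----------------------------------------------------
    drift_cfg = config["drift"]
    dconfig = DriftConfig(
        log_base=float(drift_cfg["log_base"]),
        a3ge_variant=drift_cfg["a3ge_variant"],
        tier_n=int(drift_cfg["tier_n"]),
    )
    tissues = sorted(meta["tissue"].unique())
    contrasts = []
    for tissue in tissues:
        tissue_groups = meta.loc[meta["tissue"] == tissue, "group"].unique()
        ref = f"{tissue}_{drift_cfg['reference_tissue_group']}"
        if ref not in tissue_groups:
            logger.warning("[drift] tissue %s has no reference group %s",
                           tissue, ref)
            continue
        for grp in tissue_groups:
            if grp == ref:
                continue
            rec = compare_groups(values, meta, ref, grp, dconfig)
            contrasts.append(rec)
            logger.info(
                "[drift] %s vs %s: m=%.4f R2=%.4f wRMSD=%.4f A3GE=%.4f (n=%d)",
                ref, grp, rec.slope_m, rec.r_squared, rec.wrmsd, rec.a3ge,
                rec.n_features_used,
            )
    report["contrasts"] = [c.to_dict() for c in contrasts]
    pd.DataFrame(report["contrasts"]).to_csv(
        outdir / "contrasts.tsv", sep="\t", index=False
    )
    report["outputs"]["contrasts.tsv"] = str(outdir / "contrasts.tsv")

    # per-category drift for the strongest T-cell contrast
    cat_map = panel.amplicon_to_category()
    cat_records, skipped = {}, {}
    for cmp_grp in ("tcell_wo", "tcell_ho"):
        recs, skip = category_analysis(
            values, meta, "tcell_wy", cmp_grp, cat_map, dconfig,
            min_category_features=int(drift_cfg["min_category_features"]),
        )
        cat_records[cmp_grp] = [r.to_dict() for r in recs]
        skipped[cmp_grp] = skip
    report["categories"] = cat_records
    report["categories_skipped"] = skipped
    pd.DataFrame(
        [r for recs in cat_records.values() for r in recs]
    ).to_csv(outdir / "categories.tsv", sep="\t", index=False)
    report["outputs"]["categories.tsv"] = str(outdir / "categories.tsv")

    # dispersion convergence across the T-cell groups
    tcell_groups = [g for g in meta["group"].unique() if g.startswith("tcell")]
    disp = summarize_dispersion(values, meta, tcell_groups, "tcell_wy", dconfig)
    report["dispersion"] = disp.reset_index().to_dict(orient="records")
    disp.to_csv(outdir / "dispersion.tsv", sep="\t")
    report["outputs"]["dispersion.tsv"] = str(outdir / "dispersion.tsv")

    # LEG/HEG tiers on the T-cell panel
    wy_means, _ = group_means(values, meta, "tcell_wy")
    leg, heg = select_leg_heg(wy_means, tier_n=dconfig.tier_n)
    tiers = {}
    for cmp_grp in ("tcell_wo", "tcell_ho"):
        cmp_means, _ = group_means(values, meta, cmp_grp)
        leg_res, heg_res, between_p = drift_by_tier(
            wy_means, cmp_means, leg, heg
        )
        tiers[cmp_grp] = {
            "LEG": leg_res.to_dict(),
            "HEG": heg_res.to_dict(),
            "between_tier_p": between_p,
        }
    report["tiers"] = tiers
    tier_rows = [
        {"contrast": grp, **res[t]}
        for grp, res in tiers.items()
        for t in ("LEG", "HEG")
    ]
    pd.DataFrame(tier_rows).to_csv(outdir / "tiers.tsv", sep="\t", index=False)
    report["outputs"]["tiers.tsv"] = str(outdir / "tiers.tsv")

    # PCA overview on the mouse-count matrix
    mouse_matrix = counts.pivot(
        index="amplicon_id", columns="sample_id", values="mouse_reads"
    )
    coords, explained = pca_overview(mouse_matrix, top_k_variable=200)
    report["pca"] = {
        "explained_variance_ratio": [float(e) for e in explained],
    }
    coords.to_csv(outdir / "pca.tsv", sep="\t", index_label="sample_id")
    report["outputs"]["pca.tsv"] = str(outdir / "pca.tsv")

    # --- stage: telomere ---------------------------------------------------
    tel_cfg = config["telomere"]
    calib, ts_table = calibrate_from_ct_table(
        ct_table,
        baseline_age_months=float(tel_cfg["baseline_age_months"]),
        fit_on=tel_cfg["fit_on"],
    )
    logger.info(
        "[telomere] decline %.3f %%/month (R2=%.4f)",
        calib.decline_rate_pct_per_month, calib.r_squared,
    )
    chrono = float(tel_cfg["query_chrono_age_months"])
    wo_rel = calib.predict(chrono)
    ho_rel_full, ho_rel = hd_adjustment(wo_rel, float(tel_cfg["query_ratio"]))
    bio_age, bio_age_rounded = infer_bio_age(calib, ho_rel_full)
    report["telomere"] = {
        "calibration": calib.to_dict(),
        "wo_relative_ts": wo_rel,
        "query_ratio": float(tel_cfg["query_ratio"]),
        "ho_relative_ts": ho_rel_full,
        "ho_relative_ts_rounded": ho_rel,
        "ho_biological_age_months": bio_age,
        "ho_biological_age_rounded": bio_age_rounded,
        "ho_acceleration": acceleration(bio_age, chrono),
    }
    ts_table.to_csv(outdir / "telomere.tsv", sep="\t", index=False)
    report["outputs"]["telomere.tsv"] = str(outdir / "telomere.tsv")

    # --- stage: rate -------------------------------------------------------
    by_label = {c.comparison_label: c for c in contrasts}
    age_of = meta.drop_duplicates("group").set_index("group")["age_months"]
    points = [A3gePoint("tcell_wy", float(age_of["tcell_wy"]), 0.0)]
    for grp in ("tcell_wm", "tcell_wo"):
        points.append(A3gePoint(grp, float(age_of[grp]), by_label[grp].a3ge))
    points.append(A3gePoint("tcell_ho", bio_age, by_label["tcell_ho"].a3ge))
    model = fit_a3ge_trajectory(points)
    level = float(config["rate"]["level"])
    report["rate"] = {
        **model.to_dict(),
        "points": [
            {"label": p.label, "age_months": p.age_months, "a3ge": p.a3ge}
            for p in points
        ],
        "age_at_level": {str(level): model.age_at_level(level)},
    }
    logger.info(
        "[rate] A3GE rate %.4f/month; reaches %.0f%% at %.1f months",
        model.rate_per_month_, level * 100, model.age_at_level(level),
    )

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2)
    report["outputs"]["report.json"] = str(report_path)

    for name, path in report["outputs"].items():
        p = Path(path)
        if not p.exists() or p.stat().st_size == 0:
            raise RuntimeError(f"declared output {name} missing or empty")
    return report
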