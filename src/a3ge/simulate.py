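"""Synthetic data generator for the drift analysis.

Emulates the structure of the study's data so the whole pipeline can be
exercised and validated against known ground truth:

* a latent expression model in which old-age transcriptomes are a
  mean-reverting compression of the young baseline — each gene's log2
  level is pulled toward a grand-mean attractor with slope ``m`` in
  (0, 1], which simultaneously produces the lowered young-vs-old
  regression slope, the variance shrinkage (Var_old = m^2 * Var_young +
  sigma_drift^2), and the bimodal lowly-up / highly-down drift;
* competitive amplicon counts: rat (spike-in) read depth is negative
  binomial, mouse reads Poisson around depth x M/R x a fixed
  per-amplicon amplification bias, so the fractional-quantity correction
  can be validated by round trip;
* telomere qPCR Ct tables whose T/S ratio declines linearly with age;
* an RNA-seq-like FPKM matrix spanning the dynamic range of real
  T-cell transcriptomes (~4e-3 to ~7e3 FPKM).

Every latent quantity is emitted in truth tables, and all randomness is
driven by explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import Panel, PanelSpec, make_panel


class SimulationError(ValueError):
    """Invalid simulation parameters or group design."""


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class DriftParams:
    """Parameters of the mean-reversion drift model (log2 M/R units).

    ``attractor_log2`` is the level genes converge toward (defaults to
    the young grand mean, matching the near-constant group medians);
    ``baseline_mean_log2`` = 1.0 puts the median young M/R at 2.
    """

    attractor_log2: float = 1.0
    sigma_drift: float = 0.1
    sigma_rep: float = 0.05
    baseline_mean_log2: float = 1.0
    baseline_sd_log2: float = 2.0

    def validate(self) -> None:
        if self.sigma_drift < 0 or self.sigma_rep < 0:
            raise SimulationError("sigma terms must be >= 0")
        if self.baseline_sd_log2 <= 0:
            raise SimulationError("baseline_sd_log2 must be > 0")


@dataclass(frozen=True)
class GroupSpec:
    """One sample group: tissue x genotype x age, with its drift strength.

    ``compression_m`` in [0, 1] is the mean-reversion slope for this
    group (1 = no drift, 0 = complete collapse onto the attractor).
    ``sigma_drift`` overrides the global per-gene drift noise when
    given; reference (young) groups use 0 so they *are* the baseline.
    """

    label: str
    tissue: str
    genotype: str
    age_months: float
    n_replicates: int = 4
    compression_m: float = 1.0
    sigma_drift: float | None = None

    def validate(self) -> None:
        if not (0.0 <= self.compression_m <= 1.0):
            raise SimulationError(
                f"group {self.label}: compression_m must be in [0, 1]"
            )
        if self.n_replicates < 1:
            raise SimulationError(f"group {self.label}: need >= 1 replicate")
        if self.sigma_drift is not None and self.sigma_drift < 0:
            raise SimulationError(f"group {self.label}: sigma_drift < 0")


@dataclass(frozen=True)
class SeqParams:
    """Sequencing model: NB rat depth, Poisson mouse counts, fixed bias."""

    mean_depth_per_amplicon: int = 20_000
    nb_dispersion: float = 0.1
    bias_sd_log2: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.mean_depth_per_amplicon < 1:
            raise SimulationError("mean_depth_per_amplicon must be >= 1")
        if self.nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be > 0")
        if self.bias_sd_log2 < 0:
            raise SimulationError("bias_sd_log2 must be >= 0")


@dataclass(frozen=True)
class TelomereSimParams:
    """Linear telomere attrition: relative T/S = 1 - rate * (age - baseline)."""

    baseline_age_months: float = 2.0
    decline_per_month: float = 0.0183
    ct_ref_mean: float = 22.0
    ct_noise_sd: float = 0.0
    ages: tuple[float, ...] = (2.0, 20.0, 25.0, 28.0)
    ts_scale: float = 0.5  # arbitrary raw T/S scale K, recorded in truth

    def validate(self) -> None:
        if not (0.0 <= self.decline_per_month < 1.0):
            raise SimulationError("decline_per_month must be in [0, 1)")
        if any(a < self.baseline_age_months for a in self.ages):
            raise SimulationError("ages must be >= baseline_age_months")
        if self.ct_noise_sd < 0:
            raise SimulationError("ct_noise_sd must be >= 0")
        floor = 1.0 - self.decline_per_month * (
            max(self.ages) - self.baseline_age_months
        )
        if floor <= 1e-6:
            raise SimulationError(
                "decline rate drives relative T/S to <= 0 at the oldest age"
            )


# ---------------------------------------------------------------------------
# latent expression


@dataclass(frozen=True)
class LatentExpression:
    """Latent M/R levels per sample plus the generating truth.

    ``values``: DataFrame amplicon x sample of latent M/R (level scale).
    ``meta``: per-sample metadata (tissue, genotype, age, group, replicate).
    ``truth``: dict with ``baseline_log2`` (per gene), ``group_m``,
    ``group_level_log2`` (gene x group latent levels before replicate
    noise) — everything a recovery test needs.
    """

    values: pd.DataFrame = field(repr=False)
    meta: pd.DataFrame = field(repr=False)
    truth: dict[str, pd.DataFrame | pd.Series] = field(repr=False)


def simulate_expression(
    panel: Panel,
    groups: list[GroupSpec],
    params: DriftParams | None = None,
    seed: int = 0,
) -> LatentExpression:
    """Draw latent M/R levels under the mean-reversion drift model.

    Per gene g: young baseline b_g ~ N(baseline_mean, baseline_sd^2).
    Per group with compression m: latent log2 level =
    attractor + m * (b_g - attractor) + N(0, sigma_drift^2); replicates
    add N(0, sigma_rep^2).  Amplicons of the same gene share the gene's
    latent level.
    """
    params = params or DriftParams()
    params.validate()
    if not groups:
        raise SimulationError("at least one group required")
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise SimulationError("group labels must be unique")
    for g in groups:
        g.validate()

    rng = np.random.default_rng(seed)
    genes = panel.gene_ids
    n_genes = len(genes)
    baseline = rng.normal(
        params.baseline_mean_log2, params.baseline_sd_log2, size=n_genes
    )
    baseline_s = pd.Series(baseline, index=genes, name="baseline_log2")

    group_levels = {}
    sample_cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for g in groups:
        sigma_d = params.sigma_drift if g.sigma_drift is None else g.sigma_drift
        level = params.attractor_log2 + g.compression_m * (
            baseline - params.attractor_log2
        )
        if sigma_d > 0:
            level = level + rng.normal(0.0, sigma_d, size=n_genes)
        group_levels[g.label] = level
        for r in range(1, g.n_replicates + 1):
            sid = f"{g.label}_r{r}"
            rep = level
            if params.sigma_rep > 0:
                rep = rep + rng.normal(0.0, params.sigma_rep, size=n_genes)
            sample_cols[sid] = rep
            meta_rows.append(
                {
                    "sample_id": sid,
                    "tissue": g.tissue,
                    "genotype": g.genotype,
                    "age_months": g.age_months,
                    "group": g.label,
                    "replicate": r,
                }
            )

    gene_log2 = pd.DataFrame(sample_cols, index=genes)
    amp_to_gene = panel.amplicon_to_gene()
    values = np.exp2(gene_log2.loc[amp_to_gene.values])
    values.index = amp_to_gene.index

    truth = {
        "baseline_log2": baseline_s,
        "group_m": pd.Series(
            {g.label: g.compression_m for g in groups}, name="compression_m"
        ),
        "group_level_log2": pd.DataFrame(group_levels, index=genes),
        "latent_mr": values.copy(),
    }
    return LatentExpression(
        values=values, meta=pd.DataFrame(meta_rows), truth=truth
    )


# ---------------------------------------------------------------------------
# count simulation


def simulate_counts(
    latent: LatentExpression,
    seq: SeqParams | None = None,
    expected: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw mouse/rat read counts for every (sample, amplicon).

    Rat depth R_a ~ NB(mean_depth, dispersion); a per-amplicon bias
    beta_a = 2^N(0, bias_sd^2), fixed across samples, models unequal
    mouse/rat amplification; mouse reads ~ Poisson(R_a * M/R * beta_a).

    With ``expected=True`` no sampling occurs: rat = mean_depth and
    mouse = rat * M/R * beta exactly (float counts) — a noiseless hook
    for inversion tests.

    Returns the long count table (sample_id, amplicon_id, mouse_reads,
    rat_reads) and the calibration table (amplicon_id, bias_factor).
    """
    seq = seq or SeqParams()
    seq.validate()
    if (latent.values <= 0).any().any():
        raise SimulationError("latent M/R must be > 0 everywhere")

    rng = np.random.default_rng(seq.seed)
    amplicons = latent.values.index
    n_amp = len(amplicons)
    bias = (
        np.exp2(rng.normal(0.0, seq.bias_sd_log2, size=n_amp))
        if seq.bias_sd_log2 > 0
        else np.ones(n_amp)
    )
    calibration = pd.DataFrame(
        {"amplicon_id": amplicons, "bias_factor": bias}
    )

    depth = float(seq.mean_depth_per_amplicon)
    rows = []
    for sid in latent.values.columns:
        ratio = latent.values[sid].to_numpy()
        if expected:
            rat = np.full(n_amp, depth)
            mouse = rat * ratio * bias
        else:
            # NB with mean d and Var = d + alpha d^2
            n_param = 1.0 / seq.nb_dispersion
            p_param = n_param / (n_param + depth)
            rat = rng.negative_binomial(n_param, p_param, size=n_amp).astype(
                float
            )
            mouse = rng.poisson(rat * ratio * bias).astype(float)
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "amplicon_id": amplicons,
                    "mouse_reads": mouse,
                    "rat_reads": rat,
                }
            )
        )
    counts = pd.concat(rows, ignore_index=True)
    if not expected:
        counts["mouse_reads"] = counts["mouse_reads"].astype(int)
        counts["rat_reads"] = counts["rat_reads"].astype(int)
    return counts, calibration


# ---------------------------------------------------------------------------
# telomere qPCR simulation


def simulate_telomere_ct(
    params: TelomereSimParams | None = None,
    n_replicates: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float | pd.Series]]:
    """Generate a long-format Ct table for the telomere/reference assay.

    Relative T/S at age a is 1 - decline * (a - baseline), and the raw
    T/S read out by 2^-(Ct_tel - Ct_ref) equals relative T/S times the
    arbitrary scale K (``ts_scale``), recorded in the truth dict.
    """
    params = params or TelomereSimParams()
    params.validate()
    if n_replicates < 1:
        raise SimulationError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)

    rows = []
    rel_truth = {}
    for age in params.ages:
        rel = 1.0 - params.decline_per_month * (age - params.baseline_age_months)
        rel = max(rel, 1e-6)
        rel_truth[age] = rel
        sid = f"wt_{age:g}mo"
        for r in range(n_replicates):
            ct_ref = params.ct_ref_mean
            ct_tel = ct_ref - np.log2(rel * params.ts_scale)
            if params.ct_noise_sd > 0:
                ct_ref = ct_ref + rng.normal(0.0, params.ct_noise_sd)
                ct_tel = ct_tel + rng.normal(0.0, params.ct_noise_sd)
            rows.append(
                {
                    "sample_id": sid,
                    "age_months": age,
                    "ct_telomere": ct_tel,
                    "ct_ref": ct_ref,
                }
            )
    truth = {
        "ts_scale": params.ts_scale,
        "decline_per_month": params.decline_per_month,
        "relative_ts": pd.Series(rel_truth, name="relative_ts"),
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# RNA-seq-like FPKM simulation


@dataclass(frozen=True)
class FpkmParams:
    """Baseline log2-FPKM distribution wide enough to cover the printed
    LEG (0.0041–0.035) and HEG (144.1–7444.7) ranges at n >= 1000."""

    baseline_mean_log2: float = 2.5
    baseline_sd_log2: float = 5.0
    compression_m: float = 0.7071
    sigma_drift: float = 0.3


def simulate_fpkm(
    n_genes: int = 10_000,
    params: FpkmParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Young/old FPKM matrix under the same mean-reversion drift model.

    Returns a DataFrame (gene x {young, old}) and the per-gene baseline
    truth.  All FPKM are strictly positive (log-normal draws).
    """
    params = params or FpkmParams()
    if n_genes < 2:
        raise SimulationError("n_genes must be >= 2")
    rng = np.random.default_rng(seed)
    genes = pd.Index(
        [f"tx{str(i + 1).zfill(len(str(n_genes)))}" for i in range(n_genes)]
    )
    baseline = rng.normal(
        params.baseline_mean_log2, params.baseline_sd_log2, size=n_genes
    )
    old = params.baseline_mean_log2 + params.compression_m * (
        baseline - params.baseline_mean_log2
    )
    if params.sigma_drift > 0:
        old = old + rng.normal(0.0, params.sigma_drift, size=n_genes)
    fpkm = pd.DataFrame(
        {"young": np.exp2(baseline), "old": np.exp2(old)}, index=genes
    )
    return fpkm, pd.Series(baseline, index=genes, name="baseline_log2")


# ---------------------------------------------------------------------------
# default study design


def default_study_design() -> list[GroupSpec]:
    """The study's sample groups with drift strengths matching its findings.

    Compression values encode: muscle essentially driftless, brain mild
    (old-HD slope 0.9879 as printed), T cells strong — old wild-type at
    1/sqrt(2) (variance halves) and old HD at 0.5 (variance quarters) —
    plus a 7-month wild-type T-cell group with no discernible drift and
    an old-macrophage negative control at m = 0.988.
    """
    young, old, mid = 2.0, 19.0, 7.0
    g = GroupSpec
    return [
        g("muscle_wy", "muscle", "wt", young, 3, 1.0, 0.0),
        g("muscle_hy", "muscle", "hd", young, 3, 0.999),
        g("muscle_wo", "muscle", "wt", old, 3, 0.997),
        g("muscle_ho", "muscle", "hd", old, 3, 0.995),
        g("brain_wy", "brain", "wt", young, 3, 1.0, 0.0),
        g("brain_hy", "brain", "hd", young, 3, 0.995),
        g("brain_wo", "brain", "wt", old, 3, 0.99),
        g("brain_ho", "brain", "hd", old, 3, 0.9879),
        g("tcell_wy", "tcell", "wt", young, 4, 1.0, 0.0),
        g("tcell_hy", "tcell", "hd", young, 4, 0.98),
        g("tcell_wm", "tcell", "wt", mid, 4, 1.0, 0.0),
        g("tcell_wo", "tcell", "wt", old, 4, 0.7071),
        g("tcell_ho", "tcell", "hd", old, 4, 0.5),
        g("macrophage_wy", "macrophage", "wt", young, 3, 1.0, 0.0),
        g("macrophage_wo", "macrophage", "wt", old, 3, 0.988),
    ]


# ---------------------------------------------------------------------------
# writers (plain-text outputs)


def write_panel_tsv(panel: Panel, path) -> None:
    panel.amplicons.to_csv(path, sep="\t", index=False)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def write_calibration_tsv(calibration: pd.DataFrame, path) -> None:
    calibration.to_csv(path, sep="\t", index=False)


def write_ct_csv(ct_table: pd.DataFrame, path) -> None:
    ct_table.to_csv(path, index=False)


def write_expression_tsv(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="feature_id")


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def write_sites_tsv(panel: Panel, path) -> None:
    panel.site_list().to_csv(path, sep="\t", index=False)


def write_sites_bed(panel: Panel, path) -> None:
    """BED companion: 0-based half-open intervals of the ISV sites."""
    sites = panel.site_list()
    bed = sites[["contig", "start", "end", "amplicon_id"]]
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_counts_vcf(panel: Panel, counts: pd.DataFrame, path) -> None:
    """Minimal VCF: one record per ISV site, per-sample AD = (mouse, rat).

    REF is the mouse allele, ALT the rat allele, matching the assay's
    read-assignment convention.
    """
    import pysam

    samples = list(pd.unique(counts["sample_id"]))
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                    'Description="Allelic depths (mouse, rat)">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for contig in panel.amplicons["contig"]:
        header.contigs.add(contig, length=1000)
    for s in samples:
        header.add_sample(s)

    wide_m = counts.pivot(
        index="amplicon_id", columns="sample_id", values="mouse_reads"
    )
    wide_r = counts.pivot(
        index="amplicon_id", columns="sample_id", values="rat_reads"
    )
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in panel.amplicons.itertuples():
            rec = vcf.new_record(
                contig=row.contig,
                start=row.pos - 1,
                alleles=(row.mouse_allele, row.rat_allele),
            )
            for s in samples:
                m = int(wide_m.at[row.amplicon_id, s])
                r = int(wide_r.at[row.amplicon_id, s])
                rec.samples[s]["AD"] = (m, r)
                rec.samples[s]["GT"] = (0, 1)
            vcf.write(rec)


def simulate_panel_dataset(
    spec: PanelSpec | None = None,
    groups: list[GroupSpec] | None = None,
    drift: DriftParams | None = None,
    seq: SeqParams | None = None,
    seed: int = 0,
) -> dict:
    """One-call convenience: panel + latent expression + counts + truth."""
    spec = spec or PanelSpec()
    groups = groups or default_study_design()
    drift = drift or DriftParams()
    panel = make_panel(spec, seed=seed)
    latent = simulate_expression(panel, groups, drift, seed=seed + 1)
    seq = replace(seq or SeqParams(), seed=seed + 2)
    counts, calibration = simulate_counts(latent, seq)
    return {
        "panel": panel,
        "latent": latent,
        "counts": counts,
        "calibration": calibration,
    }
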