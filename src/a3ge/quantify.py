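"""Competitive-amplicon quantification: allele counts -> corrected M/R ratios.

Each amplicon co-amplifies the mouse target cDNA and a rat genomic
spike-in; reads are assigned to a species at the amplicon's
inter-species variant (ISV) site.  The expression level of an amplicon
is the M/R ratio — mouse reads over rat reads — after correcting each
amplicon's mouse fraction for its fixed mouse-vs-rat amplification bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ("sample_id", "amplicon_id", "mouse_reads", "rat_reads")
SITE_COLUMNS = ("amplicon_id", "contig", "pos", "mouse_allele", "rat_allele")


class CountTableError(ValueError):
    """Malformed allele-count table."""


class SiteMismatchError(ValueError):
    """VCF alleles disagree with the ISV site list."""


# ---------------------------------------------------------------------------
# readers


def read_sites_tsv(path) -> pd.DataFrame:
    """Read the ISV site list.

    Requires ``amplicon_id, contig, pos, mouse_allele, rat_allele``;
    ``pos`` is 1-based (VCF convention).  Optional ``start``/``end``
    columns give the 0-based half-open BED interval of the same site and,
    when present, are checked for consistency (start = pos - 1).
    """
    sites = pd.read_csv(path, sep="\t", dtype={"contig": str})
    missing = set(SITE_COLUMNS) - set(sites.columns)
    if missing:
        raise CountTableError(f"site list missing columns: {sorted(missing)}")
    if sites.duplicated(["contig", "pos"]).any():
        raise CountTableError("duplicate (contig, pos) in site list")
    if (sites["mouse_allele"] == sites["rat_allele"]).any():
        raise CountTableError("mouse and rat alleles must differ at each site")
    if {"start", "end"} <= set(sites.columns):
        bad = sites[(sites["start"] != sites["pos"] - 1)
                    | (sites["end"] != sites["pos"])]
        if len(bad):
            raise CountTableError(
                "BED start/end inconsistent with 1-based pos for sites: "
                f"{bad['amplicon_id'].tolist()[:5]}"
            )
    return sites


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    missing = set(COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise CountTableError(f"count table missing columns: {sorted(missing)}")
    counts = counts[list(COUNT_COLUMNS)].copy()
    if counts.duplicated(["sample_id", "amplicon_id"]).any():
        dup = counts[counts.duplicated(["sample_id", "amplicon_id"])]
        raise CountTableError(
            f"duplicate (sample, amplicon) rows, e.g. "
            f"{dup.iloc[0]['sample_id']}/{dup.iloc[0]['amplicon_id']}"
        )
    for col in ("mouse_reads", "rat_reads"):
        if counts[col].isna().any():
            raise CountTableError(f"missing values in {col}")
        if (counts[col] < 0).any():
            raise CountTableError(f"negative counts in {col}")
    return counts


def read_allele_counts_tsv(path) -> pd.DataFrame:
    """Read and validate a long count table
    (sample_id, amplicon_id, mouse_reads, rat_reads)."""
    return _validate_counts(pd.read_csv(path, sep="\t"))


def read_allele_counts_vcf(vcf_path, sites: pd.DataFrame) -> pd.DataFrame:
    """Extract mouse/rat allelic depths at the listed ISV sites from a VCF.

    For each site, mouse_reads is the AD of the mouse allele and
    rat_reads the AD of the rat allele.  Sites absent from the VCF yield
    (0, 0) with a logged warning; a VCF record whose alleles disagree
    with the site list raises :class:`SiteMismatchError`.
    """
    import pysam

    records: dict[tuple[str, int], object] = {}
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            records[(rec.contig, rec.pos)] = {
                "alleles": rec.alleles,
                "ad": {s: rec.samples[s].get("AD") for s in samples},
            }

    rows = []
    for site in sites.itertuples():
        key = (str(site.contig), int(site.pos))
        rec = records.get(key)
        if rec is None:
            logger.warning(
                "site %s (%s:%d) absent from VCF; emitting zero counts",
                site.amplicon_id, key[0], key[1],
            )
            for s in samples:
                rows.append((s, site.amplicon_id, 0, 0))
            continue
        alleles = rec["alleles"]
        try:
            i_mouse = alleles.index(site.mouse_allele)
            i_rat = alleles.index(site.rat_allele)
        except ValueError:
            raise SiteMismatchError(
                f"site {site.amplicon_id} ({key[0]}:{key[1]}): VCF alleles "
                f"{alleles} do not contain mouse={site.mouse_allele} / "
                f"rat={site.rat_allele}"
            ) from None
        for s in samples:
            ad = rec["ad"][s]
            if ad is None:
                rows.append((s, site.amplicon_id, 0, 0))
            else:
                rows.append(
                    (s, site.amplicon_id, int(ad[i_mouse]), int(ad[i_rat]))
                )
    return _validate_counts(
        pd.DataFrame(rows, columns=list(COUNT_COLUMNS))
    )


def read_calibration_tsv(path) -> pd.Series:
    """Calibration table: amplicon_id -> amplification-bias factor c_a > 0."""
    calib = pd.read_csv(path, sep="\t")
    col = "bias_factor" if "bias_factor" in calib.columns else "correction_factor"
    if "amplicon_id" not in calib.columns or col not in calib.columns:
        raise CountTableError(
            "calibration table needs columns amplicon_id and "
            "bias_factor (or correction_factor)"
        )
    s = calib.set_index("amplicon_id")[col].astype(float)
    if (s <= 0).any():
        raise CountTableError("calibration factors must be > 0")
    return s


# ---------------------------------------------------------------------------
# fractional-quantity correction


def correct_fractions(
    counts: pd.DataFrame, calibration: pd.Series | pd.DataFrame
) -> pd.DataFrame:
    """Undo per-amplicon amplification bias on the mouse-fraction scale.

    With f = M/(M+R) and bias factor c_a (relative amplification of the
    mouse allele over the rat allele), the corrected fraction is
    f' = (f/c_a) / (f/c_a + (1-f)); corrected reads are f'*(M+R) and
    (1-f')*(M+R), so per-row total read mass is preserved.  Amplicons
    absent from the calibration default to c_a = 1; rows with M+R = 0
    pass through unchanged.
    """
    counts = _validate_counts(counts)
    if isinstance(calibration, pd.DataFrame):
        calibration = read_calibration_frame(calibration)
    if (calibration <= 0).any():
        raise CountTableError("calibration factors must be > 0")

    c = (
        counts["amplicon_id"].map(calibration).fillna(1.0).to_numpy(float)
    )
    m = counts["mouse_reads"].to_numpy(float)
    r = counts["rat_reads"].to_numpy(float)
    total = m + r
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, m / np.where(total > 0, total, 1.0), 0.0)
        fc = f / c
        f_corr = fc / (fc + (1.0 - f))
    out = counts.copy()
    out["mouse_reads"] = np.where(total > 0, f_corr * total, m)
    out["rat_reads"] = np.where(total > 0, (1.0 - f_corr) * total, r)
    return out


def read_calibration_frame(calib: pd.DataFrame) -> pd.Series:
    col = "bias_factor" if "bias_factor" in calib.columns else "correction_factor"
    return calib.set_index("amplicon_id")[col].astype(float)


class FractionCorrector(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping :func:`correct_fractions`.

    ``fit`` takes the calibration table (DataFrame with amplicon_id and
    bias_factor, or a Series); ``transform`` corrects a long count table.
    """

    def fit(self, calibration, y=None):
        if isinstance(calibration, pd.DataFrame):
            calibration = read_calibration_frame(calibration)
        calibration = pd.Series(calibration, dtype=float)
        if (calibration <= 0).any():
            raise CountTableError("calibration factors must be > 0")
        self.calibration_ = calibration
        return self

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "calibration_"):
            raise RuntimeError("FractionCorrector is not fitted")
        return correct_fractions(counts, self.calibration_)


# ---------------------------------------------------------------------------
# M/R ratios and gene aggregation


def compute_mr_ratio(
    counts: pd.DataFrame, min_total_reads: int = 50
) -> pd.DataFrame:
    """M/R ratio per (amplicon, sample), low-coverage entries set missing.

    Entries with mouse+rat < ``min_total_reads`` or rat = 0 become NaN
    (missing, not zero) so they are excluded from log-scale statistics
    rather than dragging them to -inf.  Returns a wide DataFrame
    (amplicon x sample).
    """
    if min_total_reads < 1:
        raise CountTableError("min_total_reads must be >= 1")
    counts = _validate_counts(counts)
    m = counts["mouse_reads"].to_numpy(float)
    r = counts["rat_reads"].to_numpy(float)
    ok = (m + r >= min_total_reads) & (r > 0)
    level = np.where(ok, m / np.where(r > 0, r, 1.0), np.nan)
    long = counts[["sample_id", "amplicon_id"]].assign(level=level)
    wide = long.pivot(index="amplicon_id", columns="sample_id", values="level")
    wide.columns.name = None
    wide.index.name = "feature_id"
    n_missing = int(np.isnan(level).sum())
    if n_missing:
        logger.info(
            "compute_mr_ratio: %d/%d entries below coverage threshold "
            "(min_total_reads=%d)", n_missing, len(level), min_total_reads,
        )
    return wide


def aggregate_to_genes(
    values: pd.DataFrame,
    amplicon_to_gene: pd.Series,
    method: str = "mean",
) -> pd.DataFrame:
    """Summarize amplicon-level values per gene (mean or median),
    ignoring missing amplicons; genes with all amplicons missing stay NaN."""
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    unmapped = values.index.difference(amplicon_to_gene.index)
    if len(unmapped):
        raise CountTableError(
            f"amplicons without a gene mapping: {list(unmapped[:5])}"
        )
    genes = values.index.map(amplicon_to_gene)
    out = values.groupby(genes).agg(method)
    out.index.name = "feature_id"
    return out
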