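"""Epi-driver amplicon panel description.

The assay measures each gene through one or more exonic amplicons
co-amplified from mouse cDNA and spiked-in rat genomic DNA.  Every
amplicon carries at least one inter-species variant (ISV) — a nucleotide
that differs between the mouse and rat sequence — which is what assigns
sequencing reads to a species.  The default panel mirrors the study
design: 285 amplicons covering 175 genes grouped into eight functional
categories of chromatin/epigenome machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_CATEGORIES: tuple[str, ...] = (
    "dna_methylation",
    "demethylation",
    "acetylation",
    "deacetylation",
    "lysine_methylation",
    "arginine_methylation",
    "ubiquitination",
    "prg",
)

_BASES = np.array(list("ACGT"))


class PanelError(ValueError):
    """Invalid panel specification."""


@dataclass(frozen=True)
class PanelSpec:
    """Shape of an amplicon panel: how many genes, amplicons, categories."""

    n_genes: int = 175
    n_amplicons: int = 285
    categories: tuple[str, ...] = DEFAULT_CATEGORIES

    def validate(self) -> None:
        if self.n_genes < 1:
            raise PanelError("n_genes must be >= 1")
        if self.n_amplicons < self.n_genes:
            raise PanelError(
                f"n_amplicons ({self.n_amplicons}) must be >= n_genes "
                f"({self.n_genes}): every gene needs at least one amplicon"
            )
        if len(self.categories) < 1:
            raise PanelError("at least one category required")


@dataclass(frozen=True)
class Panel:
    """A realized panel.

    ``amplicons`` has one row per amplicon with columns
    ``amplicon_id, gene_id, category, contig, pos, start, end,
    mouse_allele, rat_allele``.  ``pos`` is the 1-based ISV coordinate
    (VCF convention); ``start``/``end`` give the same site as a 0-based
    half-open interval (BED convention).
    """

    amplicons: pd.DataFrame = field(repr=False)

    @property
    def amplicon_ids(self) -> pd.Index:
        return pd.Index(self.amplicons["amplicon_id"])

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.amplicons["gene_id"].unique())

    def amplicon_to_gene(self) -> pd.Series:
        return self.amplicons.set_index("amplicon_id")["gene_id"]

    def amplicon_to_category(self) -> pd.Series:
        return self.amplicons.set_index("amplicon_id")["category"]

    def gene_to_category(self) -> pd.Series:
        return (
            self.amplicons.drop_duplicates("gene_id")
            .set_index("gene_id")["category"]
        )

    def site_list(self) -> pd.DataFrame:
        """ISV site table (one site per amplicon) for the VCF reader."""
        return self.amplicons[
            ["amplicon_id", "contig", "pos", "start", "end",
             "mouse_allele", "rat_allele"]
        ].copy()


def make_panel(spec: PanelSpec | None = None, seed: int = 0) -> Panel:
    """Build a deterministic synthetic panel from a :class:`PanelSpec`.

    Amplicons are distributed over genes with 1–3 amplicons per gene;
    genes are assigned round-robin to categories; each amplicon gets one
    synthetic ISV site with distinct mouse/rat alleles.
    """
    spec = spec or PanelSpec()
    spec.validate()
    rng = np.random.default_rng(seed)

    n_extra = spec.n_amplicons - spec.n_genes
    counts = np.ones(spec.n_genes, dtype=int)
    # hand out the surplus amplicons one at a time, capped at 3 per gene
    while n_extra > 0:
        open_genes = np.flatnonzero(counts < 3)
        if open_genes.size == 0:
            raise PanelError(
                "cannot place more than 3 amplicons per gene; "
                "reduce n_amplicons or raise n_genes"
            )
        take = min(n_extra, open_genes.size)
        chosen = rng.choice(open_genes, size=take, replace=False)
        counts[chosen] += 1
        n_extra -= take

    width = len(str(spec.n_genes))
    genes = [f"gene{str(i + 1).zfill(width)}" for i in range(spec.n_genes)]
    categories = [
        spec.categories[i % len(spec.categories)] for i in range(spec.n_genes)
    ]

    rows = []
    for g, cat, k in zip(genes, categories, counts):
        for j in range(k):
            amplicon_id = f"{g}_amp{j + 1}"
            pos = int(rng.integers(50, 250))  # 1-based ISV position
            mouse, rat = rng.choice(_BASES, size=2, replace=False)
            rows.append(
                {
                    "amplicon_id": amplicon_id,
                    "gene_id": g,
                    "category": cat,
                    "contig": amplicon_id,
                    "pos": pos,
                    "start": pos - 1,
                    "end": pos,
                    "mouse_allele": str(mouse),
                    "rat_allele": str(rat),
                }
            )
    return Panel(amplicons=pd.DataFrame(rows))
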