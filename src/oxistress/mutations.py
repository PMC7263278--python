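"""Per-sample somatic point-mutation rates from a MAF-style variant table.

The response variable of the whole analysis is the per-sample count of
somatic single-nucleotide variants (SNVs) divided by the nominal number of
human protein-coding genes, 20,000. Only records with ``Variant_Type ==
SNP`` are counted; insertions, deletions and multi-nucleotide types are
ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import FormatError

logger = logging.getLogger("oxistress")

#: Nominal number of protein-coding genes used as the rate denominator.
GENOME_GENE_COUNT = 20_000

#: Variant types recognised as-is; anything else becomes "other".
KNOWN_VARIANT_TYPES = ("SNP", "INS", "DEL")

#: Column aliases: canonical name -> accepted MAF header names.
_MAF_COLUMNS = {
    "sample_id": ("Tumor_Sample_Barcode", "sample_id", "sample"),
    "gene": ("Hugo_Symbol", "gene"),
    "variant_type": ("Variant_Type", "variant_type"),
    "variant_classification": ("Variant_Classification", "variant_classification"),
}


def read_maf(path: str | Path) -> pd.DataFrame:
    """Parse a MAF-style TSV into a variant table.

    Returns a DataFrame with columns ``sample_id, gene, variant_type,
    variant_classification``; standard TCGA MAF column names are honoured
    and extra columns ignored. Unrecognised ``Variant_Type`` values are
    mapped to ``"other"`` with a logged warning.

    Raises
    ------
    FormatError
        If a required column is absent, naming the missing column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    renamed = {}
    for canonical, aliases in _MAF_COLUMNS.items():
        for alias in aliases:
            if alias in df.columns:
                renamed[alias] = canonical
                break
        else:
            raise FormatError(f"missing column {aliases[0]}")
    table = df.rename(columns=renamed)[list(_MAF_COLUMNS)]
    unknown = ~table["variant_type"].isin(KNOWN_VARIANT_TYPES)
    if unknown.any():
        values = sorted(table.loc[unknown, "variant_type"].unique())
        logger.warning("mapping %d records with unknown Variant_Type %s to 'other'",
                       int(unknown.sum()), values)
        table.loc[unknown, "variant_type"] = "other"
    if (table["sample_id"].fillna("") == "").any():
        raise FormatError("empty sample_id in variant table")
    return table.reset_index(drop=True)


def mutation_rates(
    variants: pd.DataFrame,
    samples: Sequence[str],
    denominator: int = GENOME_GENE_COUNT,
    exclude_classifications: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Count SNV records per sample and divide by ``denominator``.

    Parameters
    ----------
    variants
        Variant table as returned by :func:`read_maf`.
    samples
        Sample IDs to report; samples absent from the table get rate 0.
    denominator
        Rate denominator; the default (20,000 genes) should not normally be
        changed and exists for sensitivity analysis only.
    exclude_classifications
        Optional ``Variant_Classification`` values to exclude in addition
        to the SNP-only filter (off by default).

    Returns a DataFrame indexed by sample with columns ``snv_count`` and
    ``rate`` where rate = snv_count / denominator exactly.
    """
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    index = pd.Index([str(s) for s in samples], name="sample")
    if index.duplicated().any():
        raise ValueError("duplicate sample IDs requested")
    mask = variants["variant_type"] == "SNP"
    if exclude_classifications is not None:
        mask &= ~variants["variant_classification"].isin(set(exclude_classifications))
    counts = (
        variants.loc[mask, "sample_id"].value_counts().reindex(index, fill_value=0)
    )
    out = pd.DataFrame(
        {"snv_count": counts.astype(int), "rate": counts / denominator}, index=index
    )
    return out


@dataclass
class RateHistogram:
    """Binned distribution of per-sample SNV counts."""

    bins: pd.DataFrame  # columns: bin_left, bin_right, count
    mean_count: float
    n_samples: int


def rate_distribution(rates: pd.DataFrame, n_bins: int) -> RateHistogram:
    """Histogram the per-sample SNV counts into ``n_bins`` equal-width bins.

    Also reports the mean mutation count per genome. Bin counts sum to the
    number of samples (the rightmost bin is closed on both sides).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(rates) == 0:
        raise ValueError("empty rate vector")
    counts = rates["snv_count"].to_numpy(dtype=float)
    hist, edges = np.histogram(counts, bins=n_bins)
    bins = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist.astype(int)}
    )
    return RateHistogram(bins=bins, mean_count=float(counts.mean()),
                         n_samples=len(rates))
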