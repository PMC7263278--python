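"""Readers, writers and configuration shared by all pipeline stages.

All tabular files are tab-separated UTF-8 text with '.' as the decimal
separator and no quoting. Gene symbols are case-preserved and matched
case-sensitively throughout.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("oxistress")

#: Pattern for Enzyme Commission numbers: 1 to 4 dot-separated fields,
#: trailing fields may be '-' placeholders (e.g. "3.4.21.5", "2.7.-").
EC_PATTERN = re.compile(r"^\d+(\.(\d+|-)){0,3}$")


class FormatError(ValueError):
    """A file does not conform to the expected column layout."""


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV.

    First column holds gene symbols, the header row holds sample IDs.
    Duplicate gene symbols are collapsed by their mean (with a warning);
    values must be non-negative reals.
    """
    with open(path) as fh:  # pandas mangles duplicate headers, check raw
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = pd.Index(header)
    if seen.duplicated().any():
        dupes = sorted(set(seen[seen.duplicated()]))
        raise FormatError(f"duplicate sample IDs: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        logger.warning("collapsing %d duplicated gene symbols by mean: %s",
                       len(dupes), dupes[:10])
        df = df.groupby(level=0, sort=False).mean()
    values_ok = df.apply(pd.to_numeric, errors="coerce")
    if values_ok.isna().any().any():
        raise FormatError("expression matrix contains non-numeric values")
    if (values_ok < 0).any().any():
        raise FormatError("expression matrix contains negative values")
    return values_ok


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# per-sample mutation rates


def read_rates(path: str | Path) -> pd.DataFrame:
    """Read a rates table (sample, snv_count, rate), indexed by sample."""
    df = pd.read_csv(path, sep="\t", index_col="sample")
    for col in ("snv_count", "rate"):
        if col not in df.columns:
            raise FormatError(f"missing column {col}")
    df.index = df.index.astype(str)
    return df


def write_rates(rates: pd.DataFrame, path: str | Path) -> None:
    rates.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# enzyme (EC) annotation


def read_ec_map(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column gene TAB ec_number mapping.

    A gene may appear on several lines (one per EC number). Malformed EC
    strings raise; the returned mapping preserves input order of ECs.
    """
    mapping: dict[str, list[str]] = {}
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("EC mapping must have two columns: gene, ec_number")
    for gene, ec in zip(df.iloc[:, 0], df.iloc[:, 1]):
        ec = str(ec).strip()
        if not EC_PATTERN.match(ec):
            raise FormatError(f"malformed EC number {ec!r} for gene {gene!r}")
        mapping.setdefault(str(gene), [])
        if ec not in mapping[str(gene)]:
            mapping[str(gene)].append(ec)
    return mapping


def write_ec_map(mapping: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tec_number\n")
        for gene, ecs in mapping.items():
            for ec in ecs:
                fh.write(f"{gene}\t{ec}\n")


# ---------------------------------------------------------------------------
# sample metadata


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata: sample, group in {tumor, control}, stage (1-4 or NA)."""
    df = pd.read_csv(path, sep="\t", index_col="sample", dtype={"stage": "string"})
    if "group" not in df.columns:
        raise FormatError("missing column group")
    bad = set(df["group"]) - {"tumor", "control"}
    if bad:
        raise FormatError(f"unknown group labels: {sorted(bad)}")
    df.index = df.index.astype(str)
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample", na_rep="NA")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: one gene set per line (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, ""] + list(genes)) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run.

    Regression parameters mirror :class:`oxistress.regression.TrainConfig`;
    ``panels`` maps panel name to a list of gene symbols (defaults are the
    three anti-oxidation validation panels).
    """

    expression: str | None = None
    maf: str | None = None
    ec_map: str | None = None
    metadata: str | None = None
    gmt: str | None = None
    outdir: str = "oxistress_run"

    lasso_alpha: float | None = None
    ec_classes: tuple[str, ...] = ("2", "3")
    p_threshold: float = 0.05
    split_fraction: float = 2 / 3
    n_restarts: int = 20
    subset_lambda: float | None = None
    coexpression_threshold: float = 0.8

    panels: dict[str, list[str]] | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must be in (0, 1)")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config fields: {sorted(unknown)}")
        if "ec_classes" in raw and raw["ec_classes"] is not None:
            raw["ec_classes"] = tuple(str(c) for c in raw["ec_classes"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["ec_classes"] = list(self.ec_classes)
        return d


def save_json(obj: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
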