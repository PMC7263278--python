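"""Synthetic cohort generator with a planted expression-mutation relation.

Emulates the statistical structure the downstream analysis assumes: a
genes x samples expression matrix (log-normal on the natural scale), a
sparse linear dependence of the per-sample somatic SNV rate on the
log-transformed expression of a small set of enzyme-encoding "causal"
genes, EC-number labels over genes, named anti-oxidation validation panels
correlated with the latent stress, and tumor/control metadata with stage
labels whose mean latent stress increases with stage.

The planted model lives on the transformed scale used by the regression,
t = log2(x + 1):

    latent_i = sum_{g in support} B[g] * t[g, i]

and the variant table holds round(20000 * (latent_i + eps_i)) SNP records
per sample (eps ~ Normal(0, noise_sd), counts clipped at 0), plus a
configurable fraction of indel records that rate computation must ignore.
Stage structure is implanted through the causal genes' expression (an
additive shift on the transformed scale split across the support), so a
predictor that only sees expression can recover it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import io as oio
from .mutations import GENOME_GENE_COUNT

# Named validation panels: genes with established anti-oxidation roles whose
# expression should correlate with the true stress level.
FATTY_ACID_GENES = ["FASN", "ACAT1", "ACAT2", "MCAT"]
MUCIN_GENES = [
    "MUC1", "MUC2", "MUC8", "MUC12", "MUC13", "MUC15", "MUC16", "MUC17",
    "MUC19", "MUC20", "MUC21", "MUC22", "MUC3A", "MUC3B", "MUC4", "MUC5AC",
    "MUC5B", "MUC6", "MUC7", "MUCL1",
]
GLUTATHIONE_GENES = ["GCLC", "GCLM", "GSS"]

DEFAULT_PANELS: dict[str, list[str]] = {
    "fatty_acid": FATTY_ACID_GENES,
    "mucin": MUCIN_GENES,
    "glutathione": GLUTATHIONE_GENES,
}

#: EC sub-subclasses used for genes outside the planted support.
DECOY_SUBCLASSES = [
    "1.1.1", "1.14.14", "2.1.1", "2.3.1", "2.4.1", "2.5.1", "2.7.7",
    "3.1.1", "3.1.3", "3.2.1", "3.6.3", "4.2.1", "5.3.1", "6.3.2",
]


@dataclass
class SyntheticConfig:
    """Parameters of the generated cohort.

    Defaults describe a mid-sized tumor cohort: 400 tumor samples, 200
    enzyme-encoding genes of which 6 drive the mutation rate, coefficient
    magnitudes giving ~100-500 SNVs per genome, and residual noise about a
    tenth of the signal's spread.
    """

    n_samples: int = 400          # tumor samples
    n_genes: int = 200            # enzyme-encoding genes
    n_causal: int = 6             # size of the planted support
    ec_subclasses: tuple[str, ...] = ("2.7.1", "3.4.21")
    noise_sd: float = 4e-4        # residual sd of the mutation rate
    coef_range: tuple[float, float] = (5e-4, 2e-3)
    n_controls: int = 40
    n_stages: int = 0             # 0 = no stage structure
    stage_effect: float = 0.0     # mean latent-stress increment per stage
    validation_rho: float = 0.8   # target corr of panel genes with latent
    indel_fraction: float = 0.2   # indel records per SNP record
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0 or self.n_causal <= 0:
            raise ValueError("dimensions must be positive")
        if self.n_causal > self.n_genes:
            raise ValueError("n_causal must not exceed n_genes")
        if self.noise_sd < 0 or self.stage_effect < 0 or self.n_controls < 0:
            raise ValueError("noise_sd, stage_effect, n_controls must be >= 0")
        if not (0 <= self.n_stages <= 4):
            raise ValueError("n_stages must be in [0, 4]")
        if not (0 <= self.validation_rho <= 1):
            raise ValueError("validation_rho must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort: the recovery target for tests."""

    support: set[str]
    B_true: dict[str, float]
    latent_stress: pd.Series        # per sample, on the rate scale
    stage_means: dict[str, float]   # mean latent per group (control, stage_k)
    snv_counts: pd.Series           # planted rounded SNV count per sample

    def to_dict(self) -> dict:
        return {
            "support": sorted(self.support),
            "B_true": self.B_true,
            "latent_stress": self.latent_stress.to_dict(),
            "stage_means": self.stage_means,
            "snv_counts": {k: int(v) for k, v in self.snv_counts.items()},
        }


class SyntheticDataset(NamedTuple):
    expression: pd.DataFrame        # genes x samples, natural scale
    variants: pd.DataFrame          # MAF-style records
    ec_map: dict[str, list[str]]
    metadata: pd.DataFrame          # sample -> group, stage
    truth: SyntheticTruth


def _transformed_base_expression(rng: np.random.Generator, n_genes: int,
                                 n_samples: int) -> np.ndarray:
    """Gene-wise Normal on the log2(x+1) scale, clipped at 0 so that the
    natural-scale expression 2**t - 1 is non-negative (log-normal-like)."""
    mu = rng.uniform(2.0, 6.0, size=n_genes)
    sd = rng.uniform(0.8, 1.6, size=n_genes)
    t = rng.normal(mu[:, None], sd[:, None], size=(n_genes, n_samples))
    return np.clip(t, 0.0, None)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one cohort; byte-identical for identical configs."""
    n_tumor, n_ctrl = config.n_samples, config.n_controls
    n_total = n_tumor + n_ctrl
    ss = np.random.SeedSequence(config.seed)
    # named substreams so each feature of the data is individually stable
    (s_expr, s_support, s_coef, s_noise, s_panel, s_records) = ss.spawn(6)
    rng_expr = np.random.default_rng(s_expr)
    rng_support = np.random.default_rng(s_support)
    rng_coef = np.random.default_rng(s_coef)
    rng_noise = np.random.default_rng(s_noise)
    rng_panel = np.random.default_rng(s_panel)
    rng_records = np.random.default_rng(s_records)

    genes = [f"ENZ{i + 1:04d}" for i in range(config.n_genes)]
    samples = [f"TUM{i + 1:04d}" for i in range(n_tumor)] + \
              [f"CTL{i + 1:04d}" for i in range(n_ctrl)]

    # planted support and coefficients (positive: rates are non-negative)
    support_idx = np.sort(rng_support.choice(config.n_genes, size=config.n_causal,
                                             replace=False))
    support = [genes[i] for i in support_idx]
    magnitudes = rng_coef.uniform(*config.coef_range, size=config.n_causal)
    B_true = {g: float(b) for g, b in zip(support, magnitudes)}

    # EC annotation: causal genes cycle through the configured subclasses,
    # the rest draw from a decoy pool (plus occasional second EC number)
    ec_map: dict[str, list[str]] = {}
    for k, g in enumerate(support):
        sub = config.ec_subclasses[k % len(config.ec_subclasses)]
        ec_map[g] = [f"{sub}.{k + 1}"]
    decoys = [s for s in DECOY_SUBCLASSES if s not in config.ec_subclasses]
    for i, g in enumerate(genes):
        if g in ec_map:
            continue
        sub = decoys[int(rng_support.integers(len(decoys)))]
        ec_map[g] = [f"{sub}.{i + 1}"]
        if rng_support.random() < 0.1:  # some genes carry two EC numbers
            sub2 = decoys[int(rng_support.integers(len(decoys)))]
            ec_map[g].append(f"{sub2}.{i + 1}")

    # expression on the transformed scale, then stage structure
    t = _transformed_base_expression(rng_expr, config.n_genes, n_total)

    stage = np.full(n_total, -1)  # -1 = no stage (controls / unstaged tumors)
    if config.n_stages > 0:
        stage[:n_tumor] = (np.arange(n_tumor) % config.n_stages) + 1
    group = np.array(["tumor"] * n_tumor + ["control"] * n_ctrl)

    sum_b = float(sum(B_true.values()))
    shift = np.where(stage > 0, config.stage_effect * stage, 0.0)
    # split the per-sample shift across the support so that the latent
    # stress gains exactly stage_effect * stage through expression alone
    t[support_idx, :] += shift[None, :] / sum_b

    latent = pd.Series(np.einsum("i,ij->j", magnitudes, t[support_idx, :]),
                       index=samples, name="latent_stress")

    eps = rng_noise.normal(0.0, config.noise_sd, size=n_total) \
        if config.noise_sd > 0 else np.zeros(n_total)
    counts = np.clip(np.round(GENOME_GENE_COUNT * (latent.to_numpy() + eps)),
                     0, None).astype(int)
    snv_counts = pd.Series(counts, index=samples, name="snv_count")

    # validation panels: transformed expression linear in the standardised
    # latent stress at correlation validation_rho
    z = latent.to_numpy() - latent.mean()
    z_sd = z.std()
    z = z / z_sd if z_sd > 0 else np.zeros_like(z)
    rho = config.validation_rho
    panel_rows = {}
    for name in FATTY_ACID_GENES + MUCIN_GENES + GLUTATHIONE_GENES:
        w = rng_panel.standard_normal(n_total)
        tp = 6.0 + 1.0 * (rho * z + np.sqrt(max(0.0, 1 - rho ** 2)) * w)
        panel_rows[name] = np.clip(tp, 0.0, None)

    expr_t = pd.DataFrame(t, index=genes, columns=samples)
    for name, row in panel_rows.items():
        expr_t.loc[name] = row
    expression = (np.exp2(expr_t) - 1.0).clip(lower=0.0)
    expression.index.name = "gene"

    # MAF-style records: counts[i] SNPs + round(indel_fraction*count) indels
    rec_samples: list[str] = []
    rec_genes: list[str] = []
    rec_types: list[str] = []
    rec_class: list[str] = []
    gene_arr = np.asarray(genes)
    for i, sample in enumerate(samples):
        c = int(counts[i])
        n_indel = int(round(config.indel_fraction * c))
        hit = gene_arr[rng_records.integers(0, config.n_genes, size=c + n_indel)]
        rec_samples.extend([sample] * (c + n_indel))
        rec_genes.extend(hit.tolist())
        rec_types.extend(["SNP"] * c)
        rec_class.extend(["Missense_Mutation"] * c)
        for j in range(n_indel):
            if j % 2 == 0:
                rec_types.append("INS")
                rec_class.append("Frame_Shift_Ins")
            else:
                rec_types.append("DEL")
                rec_class.append("Frame_Shift_Del")
    variants = pd.DataFrame({
        "sample_id": rec_samples,
        "gene": rec_genes,
        "variant_type": rec_types,
        "variant_classification": rec_class,
    })

    stage_str = pd.array([str(s) if s > 0 else pd.NA for s in stage],
                         dtype="string")
    metadata = pd.DataFrame({"group": group, "stage": stage_str},
                            index=pd.Index(samples, name="sample"))

    stage_means: dict[str, float] = {}
    if n_ctrl > 0:
        stage_means["control"] = float(latent[group == "control"].mean())
    for k in range(1, config.n_stages + 1):
        mask = stage == k
        if mask.any():
            stage_means[f"stage_{k}"] = float(latent[mask].mean())

    truth = SyntheticTruth(support=set(support), B_true=B_true,
                           latent_stress=latent, stage_means=stage_means,
                           snv_counts=snv_counts)
    return SyntheticDataset(expression, variants, ec_map, metadata, truth)


def write_dataset(data: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all generated files (TSVs + truth JSON) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "maf": outdir / "variants.maf.tsv",
        "ec_map": outdir / "ec_map.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.json",
    }
    oio.write_expression(data.expression, paths["expression"])
    maf = data.variants.rename(columns={
        "sample_id": "Tumor_Sample_Barcode",
        "gene": "Hugo_Symbol",
        "variant_type": "Variant_Type",
        "variant_classification": "Variant_Classification",
    })
    maf.to_csv(paths["maf"], sep="\t", index=False)
    oio.write_ec_map(data.ec_map, paths["ec_map"])
    oio.write_metadata(data.metadata, paths["metadata"])
    oio.save_json(data.truth.to_dict(), paths["truth"])
    return paths
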