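"""Synthetic imaging-genetics cohorts.

Generates tabular stand-ins for a voxel-based-morphometry feature matrix and
an LD-structured SNP dosage matrix, with four ordered diagnostic groups
(HC < EMCI < LMCI < AD), so the fusion / forest / association stages can be
exercised end-to-end on data with known ground truth.

The simulated structure:

* voxels: participant x voxel Gaussian features; a chosen set of
  "informative" voxels receives an ordered additive mean shift of
  ``stage * voxel_effect`` standard deviations (stage 0..3 along the
  HC -> AD axis), so group separability is controlled by a single knob.
* dosages: per gene, minor-allele dosages in {0, 1, 2} obtained by
  thresholding a latent AR(1) Gaussian at Hardy-Weinberg quantiles, giving
  tunable within-gene LD without haplotype panels; MAFs are drawn uniformly
  from ``maf_range`` (QC floor 5%).
* causal SNPs additively perturb the informative voxels by
  ``snp_effect`` per (centred) minor allele, coupling genotype to the
  imaging trait for the association stage.
* covariates: age / sex / education with group-specific moments typical of
  an elderly memory-clinic cohort; non-confounding by default.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GROUP_ORDER",
    "CohortConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "snp_pvalue_fixture",
    "write_cohort",
]

#: Disease-stage ordering used for label conventions and effect ordering.
GROUP_ORDER = ("HC", "EMCI", "LMCI", "AD")

# Group-level covariate moments for an elderly memory-clinic cohort:
# (age mean, age sd), (education mean, sd), male fraction.
_AGE_MOMENTS = {"HC": (74.8, 5.4), "EMCI": (71.3, 7.2), "LMCI": (73.6, 7.6), "AD": (75.2, 7.9)}
_EDU_MOMENTS = {"HC": (16.3, 2.7), "EMCI": (16.1, 2.6), "LMCI": (15.8, 2.9), "AD": (15.2, 3.0)}
_MALE_FRAC = {"HC": 166 / 310, "EMCI": 153 / 271, "LMCI": 195 / 390, "AD": 166 / 296}

# Deterministic default SNP counts per gene: mixes full rows with short,
# zero-padded rows downstream.
_DEFAULT_SNP_PATTERN = (24, 18, 12, 6, 3, 21, 9, 15)


def _default_group_sizes() -> dict[str, int]:
    return {"HC": 310, "EMCI": 271, "LMCI": 390, "AD": 296}


@dataclass
class CohortConfig:
    """Parameters of the simulated cohort.

    Defaults reproduce the four-group design the method targets: ADNI-like
    group sizes, 24 candidate genes with at most 24 SNPs each, MAF >= 5%,
    moderate within-gene LD, and a planted imaging signal of 40 informative
    voxels shifted by 2 SD per disease stage.
    """

    group_sizes: Mapping[str, int] = field(default_factory=_default_group_sizes)
    n_voxels: int = 2000
    n_regions: int = 90
    n_genes: int = 24
    snps_per_gene: Sequence[int] | None = None
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.5
    voxel_effect: float = 2.0
    n_informative_voxels: int = 40
    snp_effect: float = 0.0
    n_causal_snps: int = 8
    confounding: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_sizes:
            raise ValueError("group_sizes must contain at least one group")
        for name, size in self.group_sizes.items():
            if size <= 0:
                raise ValueError(f"group {name!r} has non-positive size {size}")
        if self.n_voxels <= 0 or self.n_regions <= 0 or self.n_genes <= 0:
            raise ValueError("n_voxels, n_regions and n_genes must be positive")
        lo, hi = self.maf_range
        if not (0.05 <= lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} must lie within [0.05, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if self.n_informative_voxels > self.n_voxels:
            raise ValueError("n_informative_voxels exceeds n_voxels")
        if self.n_informative_voxels < 0 or self.n_causal_snps < 0:
            raise ValueError("counts must be non-negative")
        if self.snps_per_gene is None:
            self.snps_per_gene = tuple(
                _DEFAULT_SNP_PATTERN[i % len(_DEFAULT_SNP_PATTERN)] for i in range(self.n_genes)
            )
        self.snps_per_gene = tuple(int(s) for s in self.snps_per_gene)
        if len(self.snps_per_gene) != self.n_genes:
            raise ValueError("snps_per_gene must have one entry per gene")
        for count in self.snps_per_gene:
            if not (1 <= count <= 24):
                raise ValueError(f"snps_per_gene entries must lie in [1, 24], got {count}")

    @property
    def n_participants(self) -> int:
        return int(sum(self.group_sizes.values()))

    @property
    def n_snps(self) -> int:
        return int(sum(self.snps_per_gene))

    def group_order(self) -> list[str]:
        """Groups in disease-stage order; unknown labels keep insertion order."""
        known = [g for g in GROUP_ORDER if g in self.group_sizes]
        extra = [g for g in self.group_sizes if g not in GROUP_ORDER]
        return known + extra


@dataclass
class SyntheticCohort:
    """A simulated cohort with ground truth.

    ``truth`` records the planted signal: indices of informative voxels and
    of causal SNP columns.
    """

    voxels: np.ndarray
    groups: np.ndarray
    dosages: np.ndarray
    covariates: pd.DataFrame
    truth: dict
    ids: np.ndarray
    voxel_ids: list[str]
    snp_ids: list[str]
    gene_map: pd.DataFrame
    config: CohortConfig

    def __post_init__(self) -> None:
        n = self.voxels.shape[0]
        if not (len(self.groups) == self.dosages.shape[0] == len(self.covariates) == n):
            raise ValueError("row counts of voxels, groups, dosages, covariates differ")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosage values must be in {0, 1, 2}")

    def group_rows(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.groups == group)


def _ar1_latent(rng: np.random.Generator, n: int, s: int, rho: float) -> np.ndarray:
    """Latent N(0,1) matrix with AR(1) column correlation rho^|i-j|."""
    z = np.empty((n, s))
    z[:, 0] = rng.standard_normal(n)
    scale = np.sqrt(1.0 - rho**2)
    for j in range(1, s):
        z[:, j] = rho * z[:, j - 1] + scale * rng.standard_normal(n)
    return z


def _threshold_dosage(z: np.ndarray, mafs: np.ndarray) -> np.ndarray:
    """Map a latent Gaussian to {0,1,2} at Hardy-Weinberg genotype quantiles."""
    p0 = (1.0 - mafs) ** 2
    p1 = 2.0 * mafs * (1.0 - mafs)
    t0 = stats.norm.ppf(p0)
    t1 = stats.norm.ppf(p0 + p1)
    return (z >= t0).astype(np.int8) + (z >= t1).astype(np.int8)


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Simulate a cohort according to ``config``; same seed, same cohort."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    order = config.group_order()
    stage = {g: (GROUP_ORDER.index(g) if g in GROUP_ORDER else len(GROUP_ORDER) + order.index(g))
             for g in order}

    groups = np.concatenate([np.repeat(g, config.group_sizes[g]) for g in order])
    n = len(groups)
    ids = np.array([f"S{i + 1:05d}" for i in range(n)])

    # Voxels: Gaussian noise plus an ordered stage shift on informative voxels.
    voxels = rng.standard_normal((n, config.n_voxels))
    informative = np.sort(rng.choice(config.n_voxels, size=config.n_informative_voxels, replace=False))
    stage_vec = np.array([stage[g] for g in groups], dtype=float)
    if config.n_informative_voxels:
        voxels[:, informative] += config.voxel_effect * stage_vec[:, None]

    # Dosages: per-gene AR(1) latent Gaussian thresholded at HW quantiles.
    mafs = rng.uniform(*config.maf_range, size=config.n_snps)
    dosage_blocks = []
    snp_ids: list[str] = []
    gene_rows = []
    col = 0
    for gi, s in enumerate(config.snps_per_gene):
        gene = f"GENE{gi + 1:02d}"
        z = _ar1_latent(rng, n, s, config.ld_rho)
        dosage_blocks.append(_threshold_dosage(z, mafs[col:col + s]))
        for sj in range(s):
            snp_id = f"rs{gi + 1:02d}{sj + 1:03d}"
            snp_ids.append(snp_id)
            gene_rows.append((snp_id, gene))
        col += s
    dosages = np.concatenate(dosage_blocks, axis=1)

    # Genotype -> imaging coupling on the informative voxels.
    n_causal = min(config.n_causal_snps, config.n_snps)
    causal = np.sort(rng.choice(config.n_snps, size=n_causal, replace=False))
    if n_causal and config.snp_effect != 0.0 and config.n_informative_voxels:
        centred = dosages[:, causal] - 2.0 * mafs[causal]
        voxels[:, informative] += config.snp_effect * centred.sum(axis=1)[:, None]

    age = np.empty(n)
    edu = np.empty(n)
    sex = np.empty(n, dtype=int)
    for g in order:
        rows = np.flatnonzero(groups == g)
        mu, sd = _AGE_MOMENTS.get(g, (73.0, 7.0))
        age[rows] = rng.normal(mu, sd, size=len(rows))
        mu, sd = _EDU_MOMENTS.get(g, (16.0, 3.0))
        edu[rows] = rng.normal(mu, sd, size=len(rows))
        sex[rows] = (rng.random(len(rows)) < _MALE_FRAC.get(g, 0.5)).astype(int)
    if config.confounding:
        # Optional age->voxel leakage, off by default.
        voxels += config.confounding * ((age - age.mean()) / age.std())[:, None]

    covariates = pd.DataFrame(
        {"group": groups, "age": age, "sex": sex, "education": edu}, index=pd.Index(ids, name="participant_id")
    )
    gene_map = pd.DataFrame(gene_rows, columns=["snp_id", "gene_id"])
    truth = {
        "informative_voxels": informative,
        "causal_snps": causal,
        "mafs": mafs,
    }
    voxel_ids = [f"v{(i // max(1, config.n_voxels // config.n_regions)) % config.n_regions + 1:02d}_{i:05d}"
                 for i in range(config.n_voxels)]
    return SyntheticCohort(
        voxels=voxels,
        groups=groups,
        dosages=dosages,
        covariates=covariates,
        truth=truth,
        ids=ids,
        voxel_ids=voxel_ids,
        snp_ids=snp_ids,
        gene_map=gene_map,
        config=config,
    )


def snp_pvalue_fixture(
    config: CohortConfig,
    group_pair: str,
    causal_fraction: float = 0.1,
    enrichment: float = 0.2,
) -> dict[str, list[float]]:
    """Per-gene SNP p-value lists for a group (or group pair) without a GWAS.

    Null SNPs draw p ~ Uniform(0, 1); a ``causal_fraction`` of SNPs draw
    p ~ Beta(enrichment, 1), stochastically enriched for small values.
    Deterministic given ``config.seed`` and the ``group_pair`` token (any
    group label or pair name; it salts the stream so different groups get
    different matrices).
    """
    salt = zlib.crc32(str(group_pair).encode("utf8"))
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, salt)))
    out: dict[str, list[float]] = {}
    for gi, s in enumerate(config.snps_per_gene):
        p = rng.uniform(0.0, 1.0, size=s)
        if causal_fraction > 0:
            causal = rng.random(s) < causal_fraction
            if causal.any():
                p[causal] = rng.beta(enrichment, 1.0, size=int(causal.sum()))
        out[f"GENE{gi + 1:02d}"] = [float(v) for v in p]
    return out


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path, plink_raw: bool = False) -> dict[str, Path]:
    """Write voxels / dosages / covariates as TSV (participant IDs first column).

    With ``plink_raw`` also writes the dosages in PLINK .raw dialect
    (FID IID PAT MAT SEX PHENOTYPE then one column per SNP).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    idx = pd.Index(cohort.ids, name="participant_id")
    vox = pd.DataFrame(cohort.voxels, index=idx, columns=cohort.voxel_ids)
    paths["voxels"] = out / "voxels.tsv"
    vox.to_csv(paths["voxels"], sep="\t", float_format="%.6g")

    dos = pd.DataFrame(cohort.dosages, index=idx, columns=cohort.snp_ids)
    paths["dosages"] = out / "dosages.tsv"
    dos.to_csv(paths["dosages"], sep="\t")

    paths["covariates"] = out / "covariates.tsv"
    cohort.covariates.to_csv(paths["covariates"], sep="\t", float_format="%.6g")

    paths["gene_map"] = out / "gene_map.tsv"
    cohort.gene_map.to_csv(paths["gene_map"], sep="\t", index=False)

    if plink_raw:
        raw = pd.DataFrame(
            {
                "FID": cohort.ids,
                "IID": cohort.ids,
                "PAT": 0,
                "MAT": 0,
                # PLINK sex coding: 1 = male, 2 = female.
                "SEX": np.where(cohort.covariates["sex"].to_numpy() == 1, 1, 2),
                "PHENOTYPE": -9,
            }
        )
        snp_cols = pd.DataFrame(
            cohort.dosages, columns=[f"{snp}_A" for snp in cohort.snp_ids]
        )
        raw = pd.concat([raw, snp_cols], axis=1)
        paths["dosages_raw"] = out / "dosages.raw"
        raw.to_csv(paths["dosages_raw"], sep=" ", index=False)
    return paths
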