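"""End-to-end pipeline: simulate -> fuse -> train -> select -> assoc.

Every stage's random stream is derived deterministically from the single
global seed, all artifacts are plain TSV/JSON, and a JSON manifest records
the configuration, the derived stage seeds, the SHA-256 of every written
file and the headline metric of each stage — so a rerun with the same
configuration reproduces the manifest bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from .datagen import CohortConfig, simulate_cohort, snp_pvalue_fixture, write_cohort
from .forest import EvolutionConfig, GeneticWeightedForest, forest_to_dict
from .fusion import build_gene_p_matrix, build_pair_dataset, compute_alpha, fuse
from .selection import feature_frequency, sweep, top_candidates

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "fuse", "train", "select", "assoc")

_STAGE_SALT = {name: i + 1 for i, name in enumerate(ALL_STAGES)}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence((int(global_seed), _STAGE_SALT[stage]))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    The cohort defaults are the generator's (four ADNI-sized groups, 2000
    voxels); the ensemble defaults here are the synthetic-scale operating
    point (50 trees, 5 generations) rather than the full-size 320/50, so a
    complete run finishes in minutes on one CPU.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    pair: str = "AD-HC"
    n_trees: int = 50
    generations: int = 5
    group_size: int = 5
    use_weights: bool = True
    use_evolution: bool = True
    candidate_limit: int = 1000
    sweep_end: int = 1000
    sweep_step: int = 10
    pca_k: int | None = 2
    pca_scan: bool = False
    seed: int = 0
    out_dir: str = "gwrf_run"
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # Keep pipeline order regardless of the order given.
        self.stages = tuple(s for s in ALL_STAGES if s in self.stages)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        cohort = payload.pop("cohort", {})
        if isinstance(cohort, dict):
            if "group_sizes" in cohort:
                cohort["group_sizes"] = {k: int(v) for k, v in cohort["group_sizes"].items()}
            cohort = CohortConfig(**cohort)
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        return cls(cohort=cohort, **payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _require(state: dict, key: str, stage: str, needed_by: str):
    if key not in state:
        raise RuntimeError(f"stage {needed_by!r} requires the {stage!r} stage to run first")
    return state[key]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}

    for stage in config.stages:
        seed = stage_seed(config.seed, stage)
        record: dict = {"seed": seed, "outputs": {}, "summary": {}}

        if stage == "simulate":
            cohort_cfg = dataclasses.replace(config.cohort, seed=seed)
            cohort = simulate_cohort(cohort_cfg)
            paths = write_cohort(cohort, out / "simulate")
            state["cohort"] = cohort
            record["summary"] = {
                "n_participants": int(cohort.voxels.shape[0]),
                "n_voxels": int(cohort.voxels.shape[1]),
                "n_snps": int(cohort.dosages.shape[1]),
            }
            record["outputs"] = {k: str(p) for k, p in paths.items()}

        elif stage == "fuse":
            cohort = _require(state, "cohort", "simulate", "fuse")
            name_a, name_b = config.pair.split("-")
            fuse_dir = out / "fuse"
            fuse_dir.mkdir(parents=True, exist_ok=True)
            alphas = {}
            scaled = {}
            for grp in (name_a, name_b):
                plists = snp_pvalue_fixture(cohort.config, grp)
                mp = build_gene_p_matrix(plists, group=grp)
                scalar = compute_alpha(mp)
                alphas[grp] = scalar.alpha
                rows = cohort.group_rows(grp)
                if rows.size == 0:
                    raise RuntimeError(f"stage 'fuse': group {grp!r} absent from the cohort")
                scaled[grp] = (fuse(cohort.voxels[rows], scalar), cohort.ids[rows])
            dataset = build_pair_dataset(
                scaled[name_a][0], scaled[name_b][0], config.pair,
                ids_a=scaled[name_a][1], ids_b=scaled[name_b][1],
                alpha_a=alphas[name_a], alpha_b=alphas[name_b],
            )
            state["dataset"] = dataset
            fused_path = fuse_dir / "fused.tsv"
            dataset.to_frame().to_csv(fused_path, sep="\t", float_format="%.6g")
            _write_json(fuse_dir / "alphas.json", {g: float(a) for g, a in alphas.items()})
            record["outputs"] = {"fused": str(fused_path), "alphas": str(fuse_dir / "alphas.json")}
            record["summary"] = {"n_rows": dataset.n, "alphas": {g: float(a) for g, a in alphas.items()}}

        elif stage == "train":
            dataset = _require(state, "dataset", "fuse", "train")
            evo = EvolutionConfig(
                n_trees=config.n_trees, group_size=config.group_size,
                generations=config.generations, use_weights=config.use_weights,
                use_evolution=config.use_evolution, seed=seed,
            )
            results = GeneticWeightedForest(dataset, evo).fit()
            state["results"] = results
            train_dir = out / "train"
            train_dir.mkdir(parents=True, exist_ok=True)
            model_path = train_dir / "model.json"
            _write_json(model_path, forest_to_dict(results.forest))
            metrics = results.evaluate()
            _write_json(train_dir / "metrics.json", metrics)
            record["outputs"] = {"model": str(model_path), "metrics": str(train_dir / "metrics.json")}
            record["summary"] = metrics

        elif stage == "select":
            results = _require(state, "results", "train", "select")
            dataset = state["dataset"]
            freq = feature_frequency(results.forest)
            candidates = top_candidates(freq, limit=config.candidate_limit)
            evo = dataclasses.replace(results.config, seed=seed)
            sweep_res = sweep(candidates, dataset, evo,
                              end=config.sweep_end, step=config.sweep_step)
            state["candidates"] = candidates
            state["important"] = candidates[: sweep_res.best_count]
            sel_dir = out / "select"
            sel_dir.mkdir(parents=True, exist_ok=True)
            rank_df = pd.DataFrame({
                "feature_id": candidates,
                "frequency": freq.counts[candidates],
                "rank": np.arange(1, len(candidates) + 1),
            })
            rank_path = sel_dir / "candidates.tsv"
            rank_df.to_csv(rank_path, sep="\t", index=False)
            curve_path = sel_dir / "sweep.json"
            _write_json(curve_path, {
                "grid": sweep_res.grid.tolist(),
                "accuracies": sweep_res.accuracies.tolist(),
                "best_count": sweep_res.best_count,
            })
            record["outputs"] = {"candidates": str(rank_path), "sweep": str(curve_path)}
            record["summary"] = {
                "best_count": sweep_res.best_count,
                "best_accuracy": float(sweep_res.accuracies.max()),
            }

        elif stage == "assoc":
            cohort = _require(state, "cohort", "simulate", "assoc")
            dataset = _require(state, "dataset", "fuse", "assoc")
            important = _require(state, "important", "select", "assoc")
            # Pair participants in cohort row order.
            id_to_row = {pid: i for i, pid in enumerate(cohort.ids)}
            rows = np.array([id_to_row[pid] for pid in dataset.ids])
            order = np.argsort(rows)
            rows = rows[order]
            # Continuous phenotype: mean of the selected fused features.
            phenotype = dataset.features[order][:, important].mean(axis=1)
            dosages = cohort.dosages[rows]
            base_cov = cohort.covariates.iloc[rows][["age", "sex", "education"]].to_numpy(float)
            genes = cohort.gene_map["gene_id"].to_numpy()
            if config.pca_scan:
                first_gene_cols = np.flatnonzero(genes == genes[0])
                k = assoc_mod.select_pca_count(dosages, phenotype, base_cov, first_gene_cols)
            else:
                k = int(config.pca_k or 0)
            cov = base_cov
            cov_names = ["age", "sex", "education"]
            if k >= 1:
                cov = np.column_stack([base_cov, assoc_mod.pca_covariates(dosages, k)])
                cov_names += [f"PC{i + 1}" for i in range(k)]
            gwas = assoc_mod.run_gwas(dosages, phenotype, cov, covariate_names=cov_names)
            gene_ids = list(dict.fromkeys(genes))
            gene_rows = []
            for gene in gene_ids:
                cols = np.flatnonzero(genes == gene)
                gr = assoc_mod.gates_gene_p(
                    gwas.snp_p[cols], dosages[:, cols], gene_id=gene, n_genes=len(gene_ids)
                )
                gene_rows.append((gene, gr.gene_p, gr.m_e, gr.corrected_p))
            assoc_dir = out / "assoc"
            assoc_dir.mkdir(parents=True, exist_ok=True)
            snp_df = pd.DataFrame({
                "snp_id": cohort.snp_ids,
                "gene_id": genes,
                "beta": gwas.betas,
                "p": gwas.snp_p,
            })
            snp_path = assoc_dir / "snp_assoc.tsv"
            snp_df.to_csv(snp_path, sep="\t", index=False, float_format="%.6g")
            gene_df = pd.DataFrame(gene_rows, columns=["gene_id", "gene_p", "m_e", "corrected_p"])
            gene_path = assoc_dir / "gene_assoc.tsv"
            gene_df.to_csv(gene_path, sep="\t", index=False, float_format="%.6g")
            record["outputs"] = {"snp_assoc": str(snp_path), "gene_assoc": str(gene_path)}
            record["summary"] = {
                "pca_k": k,
                "min_gene_p": float(gene_df["gene_p"].min()),
                "n_significant_genes": int((gene_df["corrected_p"] < 0.05).sum()),
            }

        record["outputs"] = {
            name: {"path": path, "sha256": _sha256(Path(path))}
            for name, path in record["outputs"].items()
        }
        manifest["stages"][stage] = record

    _write_json(out / "manifest.json", manifest)
    return manifest
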