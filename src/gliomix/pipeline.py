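"""End-to-end orchestration of the multi-omics classification analysis.

Stages: simulate (or load) -> preprocess -> design -> tune -> fit ->
evaluate -> consensus -> differential expression -> survival/correlation.
Every stage writes its artifact under the run directory and registers it in
``manifest.json`` together with the parameters and derived seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classification, consensus_selection, diffexp, model_selection
from . import preprocess as prep
from . import survival_correlation as surv
from .containers import MultiOmicsDataset, read_blacklist, read_dataset
from .sgcca_core import fit_sgcca, transform
from .synthetic_data import BlockSpec, SimConfig, SurvivalSpec, generate_study

_STAGES = ["simulate", "preprocess", "design", "tune", "fit", "evaluate",
           "consensus", "dge", "survival"]


@dataclass
class RunConfig:
    """All stage parameters, defaulting to the study's printed settings."""

    data_dir: str | None = None          # load a written dataset; None = simulate
    blacklist: str | None = None
    count_block: str | None = None       # block treated as raw counts for DE
    simulate: dict = field(default_factory=dict)   # SimConfig overrides
    train_frac: float = 0.7
    unique_cutoff: float = 0.10
    freq_ratio_cutoff: float = 19.0
    folds: int = 5
    repeats: int = 5
    n_partitions: int = 30
    consensus_thresholds: tuple[float, float, float, float] = (15, 0.05, 10, 0.2)
    keepX_grid: tuple[int, ...] = (5, 10, 20, 40)
    keepX: list[dict] | None = None      # fixed keepX skips tuning
    n_components: int | None = None      # default K - 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["consensus_thresholds"] = list(self.consensus_thresholds)
        d["keepX_grid"] = list(self.keepX_grid)
        Path(path).write_text(yaml.safe_dump(d))


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence([master, stage index])."""
    return int(
        np.random.SeedSequence([int(master), _STAGES.index(stage)]).generate_state(1)[0]
        % (2**31)
    )


def _sim_config(cfg: RunConfig) -> SimConfig:
    over = dict(cfg.simulate)
    if "block_specs" in over:
        over["block_specs"] = tuple(BlockSpec(**b) for b in over["block_specs"])
    if "survival" in over:
        over["survival"] = SurvivalSpec(**over["survival"])
    if "n_per_class" in over:
        over["n_per_class"] = tuple(over["n_per_class"])
    over.setdefault("seed", stage_seed(cfg.seed, "simulate"))
    return SimConfig(**over)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage, writing artifacts and a manifest; returns a summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": dataclasses.asdict(config), "stages": {}, "artifacts": {}}
    summary: dict = {}

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = {"seed": stage_seed(config.seed, stage)}
        for p in paths:
            manifest["artifacts"][p.name] = _file_hash(p)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    stage = "simulate"
    try:
        if config.data_dir is None:
            dataset = generate_study(_sim_config(config))
            dataset.write(outdir / "data")
            record(stage, outdir / "data" / "samples.tsv")

        stage = "preprocess"
        if config.data_dir is not None:
            dataset = read_dataset(config.data_dir)
            dataset.write(outdir / "data")
            record(stage, outdir / "data" / "samples.tsv")
        blacklist = read_blacklist(config.blacklist) if config.blacklist else set()
        blocks = {}
        for b, X in dataset.blocks.items():
            X = prep.apply_blacklist(X, blacklist)
            kept = prep.near_zero_variance_filter(
                X, config.unique_cutoff, config.freq_ratio_cutoff
            )
            blocks[b] = X[kept]
        dataset = MultiOmicsDataset(
            blocks=blocks, labels=dataset.labels, survival=dataset.survival,
            truth=dataset.truth,
        )
        split = prep.stratified_split(
            dataset.labels, config.train_frac, seed=stage_seed(config.seed, stage)
        )
        json.dump(
            {"train": list(split.train_ids), "test": list(split.test_ids)},
            open(outdir / "split.json", "w"),
        )
        record(stage, outdir / "split.json")

        model_blocks = {
            b: X for b, X in dataset.blocks.items() if b != config.count_block
        } or dict(dataset.blocks)
        train_ids, test_ids = list(split.train_ids), list(split.test_ids)
        train_std, scalings = {}, {}
        for b, X in model_blocks.items():
            train_std[b], scalings[b] = prep.center_scale(X.loc[train_ids])

        stage = "design"
        C = model_selection.design_from_blocks(train_std)
        C.to_csv(outdir / "design.tsv", sep="\t")
        record(stage, outdir / "design.tsv")

        stage = "tune"
        K = len(dataset.classes)
        H = model_selection.choose_ncomp(K, config.n_components)
        if config.keepX is not None:
            keepX = [{b: int(k[b]) for b in model_blocks} for k in config.keepX]
            tuning = None
        else:
            grid = [g for g in config.keepX_grid
                    if g <= min(X.shape[1] for X in model_blocks.values())]
            tuning = model_selection.tune_keepX(
                {b: X.loc[train_ids] for b, X in model_blocks.items()},
                dataset.labels.loc[train_ids], H, grid,
                folds=config.folds, repeats=config.repeats,
                seed=stage_seed(config.seed, stage), design=C,
            )
            keepX = tuning.keepX
        json.dump(
            {"keepX": keepX, "H": H,
             "surface": None if tuning is None else
             [{",".join(map(str, k)): v for k, v in s.items()}
              for s in tuning.error_surface]},
            open(outdir / "tuning.json", "w"),
        )
        record(stage, outdir / "tuning.json")

        stage = "fit"
        model = fit_sgcca(train_std, dataset.labels.loc[train_ids], C, keepX, H,
                          scaling=scalings)
        model.to_json(outdir / "model.json")
        record(stage, outdir / "model.json")

        stage = "evaluate"
        test_std = {
            b: prep.apply_scaling(model_blocks[b].loc[test_ids], scalings[b])
            for b in model_blocks
        }
        scores = transform(model, test_std)
        preds = {
            b: classification.predict_block(model.centroids[b], scores[b], model.classes)
            for b in model_blocks
        }
        final = classification.weighted_vote(preds, model.block_weights)
        report = classification.performance_metrics(
            dataset.labels.loc[test_ids], final, classes=model.classes
        )
        aucs = {b: classification.per_class_auc(preds[b], dataset.labels.loc[test_ids])
                for b in model_blocks}
        json.dump(
            {"metrics": report.to_dict(), "auc": aucs,
             "block_weights": model.block_weights},
            open(outdir / "metrics.json", "w"),
        )
        pd.DataFrame(
            {"sample_id": test_ids,
             "true": dataset.labels.loc[test_ids].to_numpy(),
             **{f"vote_{b}": preds[b].predicted for b in model_blocks},
             "final": final}
        ).to_csv(outdir / "predictions.tsv", sep="\t", index=False)
        record(stage, outdir / "metrics.json", outdir / "predictions.tsv")
        summary["test_accuracy"] = report.accuracy

        stage = "consensus"
        records, reports = consensus_selection.repeated_fit(
            model_blocks, dataset.labels, keepX, H, design=C,
            n_partitions=config.n_partitions, train_frac=config.train_frac,
            base_seed=stage_seed(config.seed, stage),
        )
        f1, m1, f2, m2 = config.consensus_thresholds
        selected = consensus_selection.select_consensus(records, f1, m1, f2, m2)
        summary["mean_partition_accuracy"] = float(
            np.mean([r.accuracy for r in reports])
        )

        stage = "dge"
        de_results: dict[tuple[str, str], pd.DataFrame] = {}
        if config.count_block and config.count_block in dataset.blocks:
            counts = dataset.blocks[config.count_block].T  # genes x samples
            classes = dataset.classes
            for i, a in enumerate(classes):
                for b in classes[i + 1 :]:
                    res = diffexp.de_contrast(counts, dataset.labels, (b, a))
                    de_results[(a, b)] = res
                    res.to_csv(outdir / f"de_{a}_vs_{b}.tsv", sep="\t")
                    diffexp.write_rnk(res, outdir / f"de_{a}_vs_{b}.rnk")
            summary["n_deg"] = {
                f"{a}_vs_{b}": int((res["FDR"] < 0.05).sum())
                for (a, b), res in de_results.items()
            }

        # outcome-class assignment per modality
        for sf in selected:
            X = dataset.blocks[sf.block]
            means = {
                c: float(X.loc[dataset.labels == c, sf.feature].mean())
                for c in dataset.classes
            }
            try:
                if sf.block == config.count_block and de_results:
                    sf.outcome, sf.low_confidence = (
                        consensus_selection.assign_outcome_expression(
                            sf.feature, de_results, dataset.classes
                        )
                    )
                elif X[sf.feature].between(0, 1).all():
                    sf.outcome, sf.low_confidence = (
                        consensus_selection.assign_outcome_methylation(means)
                    )
                elif len(dataset.classes) == 2:
                    sf.outcome, sf.low_confidence = (
                        consensus_selection.assign_outcome_mirna(means)
                    )
                else:
                    best = max(means.values())
                    sf.outcome = [c for c in dataset.classes if means[c] == best][0]
            except KeyError:
                sf.outcome, sf.low_confidence = None, True
        ctable = consensus_selection.consensus_table(selected)
        ctable.to_csv(outdir / "consensus.tsv", sep="\t", index=False)
        record("consensus", outdir / "consensus.tsv")
        summary["n_selected"] = {
            b: len(s) for b, s in
            consensus_selection.consensus_feature_sets(selected).items()
        }

        stage = "survival"
        if dataset.survival is not None and selected:
            rows = []
            feats = sorted({(sf.block, sf.feature) for sf in selected})
            for b, f in feats[:50]:
                try:
                    res = surv.survival_by_feature(
                        dataset.blocks[b][f].to_numpy(),
                        dataset.survival["time"].to_numpy(),
                        dataset.survival["event"].to_numpy(),
                    )
                except ValueError as e:
                    warnings.warn(f"survival analysis skipped for {f}: {e}")
                    continue
                rows.append({"block": b, "feature": f, "cutoff": res["cutoff"],
                             "method": res["method"], "statistic": res["statistic"],
                             "p": res["p"]})
            pd.DataFrame(rows).to_csv(outdir / "survival.tsv", sep="\t", index=False)
            corr_X = pd.concat(
                [dataset.blocks[b][[f]] for b, f in feats], axis=1
            )
            corr = surv.pearson_matrix(corr_X)
            corr.r.to_csv(outdir / "correlation_r.tsv", sep="\t")
            corr.p.to_csv(outdir / "correlation_p.tsv", sep="\t")
            record(stage, outdir / "survival.tsv", outdir / "correlation_r.tsv")
            if rows:
                summary["min_logrank_p"] = float(np.nanmin([r["p"] for r in rows]))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        raise PipelineError(stage, exc) from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
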