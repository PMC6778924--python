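"""End-to-end orchestration: impute → normalize → select → vote/prune → classify.

The default protocol runs feature selection once on the whole preprocessed
table and then cross-validates the classifier on the selected features; a
``nested`` option moves selection inside every training fold, which removes
selection bias at a large computational cost.  One global seed
deterministically derives every per-stage seed, so two runs with the same
configuration produce byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .bpnn import BPNNConfig, BackpropClassifier
from .data import ClinicalDataset, validate_schema
from .ensemble import EnsembleResult, derive_seeds, run_ensemble
from .evaluation import compute_metrics, stratified_kfold_cv
from .fitness import FitnessConfig
from .preprocess import hot_deck_impute, min_max_normalize

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    positive_label: str | None = None
    impute: bool = True
    normalize_range: tuple[float, float] = (0.0, 1.0)
    de_params: dict = field(default_factory=dict)
    loa_params: dict = field(default_factory=dict)
    gso_params: dict = field(default_factory=dict)
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    threshold: float = 0.95
    bpnn: BPNNConfig = field(default_factory=BPNNConfig)
    cv_k: int = 10
    seed: int = 0
    nested: bool = False


def _mask_table(result: EnsembleResult) -> list[dict]:
    rows = []
    names = result.feature_names or [f"f{i}" for i in range(len(result.majority))]
    for j, name in enumerate(names):
        rows.append({
            "feature": name,
            "de": int(result.votes["de"][j]),
            "loa": int(result.votes["loa"][j]),
            "gso": int(result.votes["gso"][j]),
            "majority": int(result.majority[j]),
            "final": int(result.final[j]),
        })
    return rows


def run_pipeline(dataset: ClinicalDataset, config: PipelineConfig | None = None,
                 outdir=None) -> dict:
    """Execute the full diagnosis pipeline and return a machine-readable report."""
    config = config or PipelineConfig()
    seeds = derive_seeds(config.seed, 4)  # fitness, ensemble, cv, bpnn
    report: dict = {"config": _config_dict(config), "seeds": {
        "fitness": seeds[0], "ensemble": seeds[1], "cv": seeds[2], "bpnn": seeds[3]}}
    report["schema"] = validate_schema(dataset)

    if config.impute and dataset.n_missing() > 0:
        dataset, imp_report = hot_deck_impute(dataset)
        report["imputation"] = {
            "n_imputed": len(imp_report),
            "cross_class_fallbacks": len(imp_report.cross_class_fallbacks),
        }
    else:
        report["imputation"] = {"n_imputed": 0, "cross_class_fallbacks": 0}
    dataset, _ = min_max_normalize(dataset, *config.normalize_range)

    fitness_config = FitnessConfig(
        n_boost_rounds=config.fitness.n_boost_rounds,
        svm_kernel=config.fitness.svm_kernel, svm_C=config.fitness.svm_C,
        eval_protocol=config.fitness.eval_protocol, k=config.fitness.k,
        holdout_fraction=config.fitness.holdout_fraction, seed=seeds[0],
    )
    ensemble = run_ensemble(
        dataset, de_params=config.de_params, loa_params=config.loa_params,
        gso_params=config.gso_params, fitness_config=fitness_config,
        threshold=config.threshold, seed=seeds[1],
    )
    report["selection"] = {
        "masks": _mask_table(ensemble),
        "selector_fitness": {k: float(v) for k, v in ensemble.fitnesses.items()},
        "pruned_pairs": [
            {"kept": ensemble.feature_names[k], "removed": ensemble.feature_names[d],
             "r": r} for k, d, r in ensemble.pruned_pairs
        ],
        "n_selected": int(ensemble.final.sum()),
    }

    bpnn_config = BPNNConfig(
        init_weight_low=config.bpnn.init_weight_low,
        init_weight_high=config.bpnn.init_weight_high,
        initial_lr=config.bpnn.initial_lr, momentum=config.bpnn.momentum,
        lr_increase=config.bpnn.lr_increase, lr_decrease=config.bpnn.lr_decrease,
        error_increase_tolerance=config.bpnn.error_increase_tolerance,
        max_epochs=config.bpnn.max_epochs,
        convergence_tol=config.bpnn.convergence_tol, seed=seeds[3],
    )

    def trainer(X_tr, y_tr):
        return BackpropClassifier.from_config(bpnn_config).fit(X_tr, y_tr)

    pooled, per_fold = stratified_kfold_cv(
        dataset, ensemble.final, k=config.cv_k, trainer=trainer, seed=seeds[2],
        normalize_within_fold=config.nested,
    )
    metrics = compute_metrics(pooled)
    report["evaluation"] = {
        "confusion": {"tp": pooled.tp, "tn": pooled.tn,
                      "fp": pooled.fp, "fn": pooled.fn},
        "metrics_pct": metrics.percentages(),
        "per_fold_pct": [m.percentages() for m in per_fold],
        "k": config.cv_k,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        lines = ["feature,de,loa,gso,majority,final"]
        for row in report["selection"]["masks"]:
            lines.append(f"{row['feature']},{row['de']},{row['loa']},"
                         f"{row['gso']},{row['majority']},{row['final']}")
        (outdir / "masks.csv").write_text("\n".join(lines) + "\n")
    return report


def _config_dict(config: PipelineConfig) -> dict:
    out = asdict(config)
    out["normalize_range"] = list(config.normalize_range)
    return out
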