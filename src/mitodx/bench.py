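"""Enumeration and execution of selector -> modeler diagnostic benchmarks.

The default manifest pairs every feature-selecting algorithm (Lasso, nine
elastic-net mixings, three stepwise directions, glmBoost, RF — 15 selector
variants) with each of seven downstream modelers (Ridge, SVM, LDA,
NaiveBayes, XGBoost, GBM, plsRglm), and adds the seven modelers plus Lasso
as standalone single-stage models: 105 + 8 = 113 configurations. Each
configuration is trained on the merged training cohort, its selected
features ("subFeature") are the only inputs to the modeler, and its score
is the mean AUC over the validation cohorts (the C-index of a binary
diagnostic model).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .learners import FittedLearner, LearnerSpec, extract_features, fit_learner
from .metrics import roc_auc

__all__ = [
    "BenchError",
    "ModelConfig",
    "BenchmarkResult",
    "default_manifest",
    "enumerate_configs",
    "run_combo",
    "run_benchmark",
    "predict_class",
]


class BenchError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """A selector -> modeler pair, or a standalone model when selector is None."""

    modeler: LearnerSpec
    selector: LearnerSpec | None = None

    def __post_init__(self) -> None:
        if self.selector is not None and not self.selector.can_select:
            raise BenchError(f"{self.selector.label} cannot act as a feature selector")

    @property
    def label(self) -> str:
        if self.selector is None:
            return self.modeler.label
        return f"{self.selector.label}+{self.modeler.label}"


@dataclass
class BenchmarkResult:
    label: str
    cohort_auc: dict[str, float]  # validation cohorts only
    train_auc: float | None
    mean_auc: float | None  # the C-index: mean over validation cohorts
    n_selected: int
    features: list[str] = field(default_factory=list)
    status: str = "ok"
    fitted: FittedLearner | None = field(default=None, repr=False)


def default_manifest() -> dict:
    """The shipped 113-configuration manifest (105 pairs + 8 standalones)."""
    return {
        "selectors": (
            ["Lasso"]
            + [{"algorithm": "Enet", "alpha": round(a / 10, 1)} for a in range(1, 10)]
            + [{"algorithm": "StepGLM", "direction": d} for d in ("both", "backward", "forward")]
            + ["glmBoost", "RF"]
        ),
        "modelers": ["Ridge", "SVM", "LDA", "NaiveBayes", "XGBoost", "GBM", "plsRglm"],
        "standalones": ["Ridge", "SVM", "LDA", "NaiveBayes", "XGBoost", "GBM", "plsRglm", "Lasso"],
    }


def _spec_from(entry) -> LearnerSpec:
    if isinstance(entry, str):
        return LearnerSpec(algorithm=entry)
    if isinstance(entry, dict):
        return LearnerSpec(**entry)
    if isinstance(entry, LearnerSpec):
        return entry
    raise BenchError(f"cannot interpret manifest entry {entry!r}")


def enumerate_configs(manifest: dict | None = None) -> list[ModelConfig]:
    """Expand a manifest into the full list of configurations.

    The default manifest yields exactly 113 configurations with unique
    labels, including "glmBoost+LDA".
    """
    manifest = manifest or default_manifest()
    selectors = [_spec_from(e) for e in manifest.get("selectors", [])]
    modelers = [_spec_from(e) for e in manifest.get("modelers", [])]
    standalones = [_spec_from(e) for e in manifest.get("standalones", [])]
    configs = [ModelConfig(modeler=m, selector=s) for s in selectors for m in modelers]
    configs += [ModelConfig(modeler=m) for m in standalones]
    labels = [c.label for c in configs]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise BenchError(f"duplicate configuration labels: {sorted(dupes)}")
    return configs


def _derived_seed(master: int, tag: str) -> int:
    return (zlib.crc32(tag.encode()) ^ (master & 0xFFFFFFFF)) % (2**31)


def _check_features(train: pd.DataFrame, validations: dict[str, tuple[pd.DataFrame, np.ndarray]]):
    for name, (Xv, _) in validations.items():
        if list(Xv.columns) != list(train.columns):
            raise BenchError(f"validation cohort {name!r} feature space differs from training")


def run_combo(
    config: ModelConfig,
    X_train: pd.DataFrame,
    y_train,
    validations: dict[str, tuple[pd.DataFrame, np.ndarray]],
    seed: int = 0,
    min_features: int = 2,
    selector_cache: dict | None = None,
) -> BenchmarkResult:
    """Fit one configuration and score it on every validation cohort.

    The selector (when present) is fitted on the training cohort; the
    modeler sees only the selected feature columns. A selection smaller
    than ``min_features`` marks the configuration skipped.
    """
    _check_features(X_train, validations)
    y_train = np.asarray(y_train).astype(int)
    features = list(X_train.columns)
    if config.selector is not None:
        sel_seed = _derived_seed(seed, config.selector.label)
        key = (config.selector.label, sel_seed)
        if selector_cache is not None and key in selector_cache:
            sel = selector_cache[key]
        else:
            sel = fit_learner(config.selector, X_train, y_train, seed=sel_seed)
            if selector_cache is not None:
                selector_cache[key] = sel
        features = extract_features(sel)
        if len(features) < min_features:
            return BenchmarkResult(
                label=config.label, cohort_auc={}, train_auc=None, mean_auc=None,
                n_selected=len(features), features=features, status="skipped",
            )
    mod_seed = _derived_seed(seed, config.label)
    fitted = fit_learner(config.modeler, X_train[features], y_train, seed=mod_seed)
    train_auc = roc_auc(fitted.predict_proba(X_train), y_train)
    cohort_auc = {}
    for name, (Xv, yv) in validations.items():
        cohort_auc[name] = roc_auc(fitted.predict_proba(Xv), np.asarray(yv).astype(int))
    mean_auc = float(np.mean(list(cohort_auc.values()))) if cohort_auc else None
    return BenchmarkResult(
        label=config.label, cohort_auc=cohort_auc, train_auc=float(train_auc),
        mean_auc=mean_auc, n_selected=len(features), features=features, fitted=fitted,
    )


def run_benchmark(
    configs: list[ModelConfig],
    X_train: pd.DataFrame,
    y_train,
    validations: dict[str, tuple[pd.DataFrame, np.ndarray]],
    seed: int = 0,
    min_features: int = 2,
    scale_data: bool = False,
) -> tuple[pd.DataFrame, list[BenchmarkResult]]:
    """Run every configuration and rank by mean validation AUC.

    Ranking is by mean validation AUC descending, ties broken by fewer
    selected features then label; the training-cohort AUC is reported in
    its own column and never enters the ranking mean. ``scale_data``
    centers and scales features on training statistics first (off by
    default).
    """
    if not configs:
        raise BenchError("no configurations to run")
    if scale_data:
        mean = X_train.mean(axis=0)
        sd = X_train.std(axis=0, ddof=0).replace(0.0, 1.0)
        X_train = (X_train - mean) / sd
        validations = {
            name: ((Xv - mean) / sd, yv) for name, (Xv, yv) in validations.items()
        }
    cache: dict = {}
    results = [
        run_combo(c, X_train, y_train, validations, seed=seed,
                  min_features=min_features, selector_cache=cache)
        for c in configs
    ]
    ok = [r for r in results if r.status == "ok"]
    skipped = [r for r in results if r.status != "ok"]
    ok.sort(key=lambda r: (-r.mean_auc, r.n_selected, r.label))
    ranked = ok + skipped
    rows = []
    for r in ranked:
        row = {"label": r.label, "status": r.status, "n_selected": r.n_selected,
               "train_auc": r.train_auc, "mean_auc": r.mean_auc}
        row.update({f"auc_{k}": v for k, v in r.cohort_auc.items()})
        rows.append(row)
    return pd.DataFrame(rows), ranked


def predict_class(probabilities, threshold: float = 0.5) -> np.ndarray:
    """Binarize probabilities: >= threshold -> "Treat", else "Control"."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise BenchError("probabilities must lie in [0, 1]")
    return np.where(p >= threshold, "Treat", "Control")
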