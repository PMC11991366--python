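"""High-level Model/Results interface for breath-based screening.

``BreathScreeningModel`` wraps the full analysis — preprocessing, the
33-descriptor featurization, leakage-free feature selection, and Monte-Carlo
cross-validated RBF-SVC classification — behind a statsmodels-style pair:
the model is built from data (a cohort of breath samples or a ready feature
matrix), ``fit()`` returns a ``BreathScreeningResults`` carrying the fitted
selection state, the cross-validation report and the final classifier, and
``summary()`` prints the screening metrics as mean +/- SD tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import FeatureMatrix, build_feature_matrix
from .model import (
    ConfusionCounts,
    CVReport,
    METRIC_NAMES,
    MetricSet,
    ModelConfig,
    SelectionParams,
    TuningResult,
    evaluate_holdout,
    fit_classifier,
    monte_carlo_cv,
    tune_hyperparameters,
)
from .selection import SelectionState
from .signals import BreathSample, process_sample


def preprocess_cohort(
    samples: Sequence[BreathSample], **signal_params
) -> tuple[list[BreathSample], list[BreathSample]]:
    """QC + segment + smooth every sample; returns (passed, rejected)."""
    passed, rejected = [], []
    for s in samples:
        out = process_sample(s, **signal_params)
        (passed if out.qc_state == "pass" else rejected).append(out)
    return passed, rejected


class BreathScreeningModel:
    """Binary screening model over an e-nose feature matrix.

    Parameters
    ----------
    features : FeatureMatrix
        Training samples (924 descriptors each) with 0/1 labels.
    config : ModelConfig, optional
        SVC hyperparameters; defaults to C=1, gamma="scale".
    selection : SelectionParams, optional
        Variance-filter and top-fraction settings refit inside every
        cross-validation split and once on the full training set.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        config: Optional[ModelConfig] = None,
        selection: Optional[SelectionParams] = None,
    ) -> None:
        labels = features.y
        if set(np.unique(labels)) - {0, 1}:
            raise ValueError("training labels must be 0/1")
        self.features = features
        self.config = config or ModelConfig()
        self.selection = selection or SelectionParams()

    @classmethod
    def from_cohort(
        cls,
        samples: Sequence[BreathSample],
        config: Optional[ModelConfig] = None,
        selection: Optional[SelectionParams] = None,
        **signal_params,
    ) -> "BreathScreeningModel":
        """Preprocess and featurize raw samples, then build the model.

        QC-rejected samples are dropped (their ids are kept on the model as
        ``rejected_ids``).
        """
        passed, rejected = preprocess_cohort(samples, **signal_params)
        if not passed:
            raise ValueError("no sample passed QC")
        model = cls(build_feature_matrix(passed), config=config,
                    selection=selection)
        model.rejected_ids = [s.sample_id for s in rejected]
        return model

    def fit(
        self,
        n_iter: int = 100,
        holdout: float = 0.2,
        seed: int = 0,
        tune: bool = False,
        n_trials: int = 50,
        tune_cv_iters: int = 25,
    ) -> "BreathScreeningResults":
        """Cross-validate (optionally after tuning) and fit the final pipeline.

        With ``tune=True`` a seeded stochastic search over the bounded default
        space picks hyperparameters by reduced-iteration MC-CV mean accuracy;
        the winner is re-scored with the full ``n_iter`` iterations.  The
        final selection state and classifier are then fitted on all training
        rows.
        """
        config = self.config
        tuning: Optional[TuningResult] = None
        if tune:
            tuning = tune_hyperparameters(
                self.features.frame, self.features.y,
                n_trials=n_trials, seed=seed, cv_iters=tune_cv_iters,
                holdout=holdout, selection=self.selection,
                baseline_config=config,
            )
            config = tuning.best_config

        cv_report = monte_carlo_cv(
            self.features.frame, self.features.y, config,
            n_iter=n_iter, holdout=holdout, seed=seed,
            selection=self.selection,
        )
        state = SelectionState.fit(
            self.features.frame, self.features.y,
            variance_eps=self.selection.variance_eps,
            top_fraction=self.selection.top_fraction,
        )
        X = state.transform(self.features.frame).to_numpy(dtype=float)
        classifier = fit_classifier(X, self.features.y, config)
        return BreathScreeningResults(
            model=self,
            config=config,
            selection_state=state,
            cv_report=cv_report,
            classifier=classifier,
            tuning=tuning,
            train_ids=set(self.features.frame.index),
        )


@dataclass
class BreathScreeningResults:
    """Fitted pipeline: selection state, CV report and final classifier."""

    model: BreathScreeningModel
    config: ModelConfig
    selection_state: SelectionState
    cv_report: CVReport
    classifier: object
    train_ids: set
    tuning: Optional[TuningResult] = None
    test_counts: Optional[ConfusionCounts] = None
    test_metrics: Optional[MetricSet] = None
    _extra: dict = field(default_factory=dict)

    def evaluate(self, test: FeatureMatrix) -> tuple[ConfusionCounts, MetricSet]:
        """Score untouched test samples; raises on train/test id overlap."""
        counts, metrics = evaluate_holdout(
            self.selection_state, self.classifier, test.frame, test.y,
            train_ids=self.train_ids,
        )
        self.test_counts, self.test_metrics = counts, metrics
        return counts, metrics

    def predict(self, features: FeatureMatrix) -> np.ndarray:
        X = self.selection_state.transform(features.frame).to_numpy(dtype=float)
        return self.classifier.predict(X)

    def report_dict(self) -> dict:
        """Per-metric {train: {mean, sd}, validation: {mean, sd}, test: value}."""
        out = {}
        for m in METRIC_NAMES:
            entry = {
                "train": dict(self.cv_report.train_aggregate[m]),
                "validation": dict(self.cv_report.aggregate[m]),
            }
            if self.test_metrics is not None:
                entry["test"] = getattr(self.test_metrics, m)
            out[m] = entry
        return out

    def summary(self) -> str:
        """Human-readable screening summary (mean +/- SD per metric)."""
        lines = [
            "Breath screening — RBF-SVC with Monte-Carlo cross-validation",
            f"  samples: {len(self.model.features)}   "
            f"features: {self.model.features.frame.shape[1]} -> "
            f"{len(self.selection_state.selected)} selected",
            f"  CV: {self.cv_report.n_iterations} iterations, "
            f"{self.cv_report.holdout_fraction:.0%} stratified holdout, "
            f"seed {self.cv_report.seed}",
            f"  SVC: C={self.config.C:g}, gamma={self.config.gamma}, "
            f"tol={self.config.tol:g}",
            "",
            f"  {'Metric':<12}{'Train':>16}{'Validation':>18}"
            + ("" if self.test_metrics is None else f"{'Test':>10}"),
        ]
        for m in METRIC_NAMES:
            tr = self.cv_report.train_aggregate[m]
            va = self.cv_report.aggregate[m]
            row = (
                f"  {m.capitalize():<12}"
                f"{tr['mean']:>9.2f} ± {tr['sd']:<4.2f}"
                f"{va['mean']:>11.2f} ± {va['sd']:<4.2f}"
            )
            if self.test_metrics is not None:
                row += f"{getattr(self.test_metrics, m):>8.2f}"
            lines.append(row)
        return "\n".join(lines)

    def plot_pca(self, selected: bool = True, ax=None):
        """Fig.-style PCA scatter of the training samples.

        ``selected=True`` projects the selected, standardized features;
        ``False`` projects all (unstandardized) features.
        """
        import matplotlib.pyplot as plt

        from .selection import project_pca

        frame = (
            self.selection_state.transform(self.model.features.frame)
            if selected
            else self.model.features.frame
        )
        res = project_pca(frame, k=2)
        if ax is None:
            _, ax = plt.subplots()
        y = self.model.features.y
        for label, color, name in ((0, "tab:red", "healthy"),
                                   (1, "tab:blue", "sick")):
            mask = y == label
            ax.scatter(res.scores.iloc[mask, 0], res.scores.iloc[mask, 1],
                       c=color, label=name, alpha=0.7)
        ax.set_xlabel(f"PC1 ({res.explained_variance_ratio[0]:.0%})")
        ax.set_ylabel(f"PC2 ({res.explained_variance_ratio[1]:.0%})")
        ax.legend()
        ax.set_title("selected + standardized" if selected else "all features")
        return ax
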