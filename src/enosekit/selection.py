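"""Filter feature selection and scaling for the breath-screening pipeline.

The feature matrix (924 descriptors) is reduced in three leakage-free steps,
all fitted on training rows only:

1. columns with (numerically) zero variance are dropped;
2. the top 3% of the remaining features by one-way ANOVA F-value — the
   between/within mean-square ratio across the two classes — are retained
   (ceiling rounding, so 870 survivors yield ceil(26.1) = 27 features);
3. the selected columns are standardized to zero mean and unit variance with
   training-set statistics.

A sign-fixed PCA projection is provided for visual inspection of class
separation before and after selection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

DEFAULT_VARIANCE_EPS = 1e-12
DEFAULT_TOP_FRACTION = 0.03


class SelectionError(ValueError):
    """Invalid input to a selection operation."""


def drop_zero_variance(
    frame: pd.DataFrame, eps: float = DEFAULT_VARIANCE_EPS
) -> tuple[pd.DataFrame, list[str]]:
    """Remove columns whose variance across samples is below ``eps``.

    Returns the reduced frame and the removed column names (original order).
    """
    if frame.shape[1] == 0 or frame.shape[0] == 0:
        raise SelectionError("empty feature matrix")
    variances = frame.var(axis=0, ddof=0)
    removed = [c for c in frame.columns if variances[c] < eps]
    if len(removed) == frame.shape[1]:
        raise SelectionError("all columns are constant; degenerate dataset")
    return frame.drop(columns=removed), removed


def anova_f_scores(frame: pd.DataFrame, labels: np.ndarray) -> pd.Series:
    """Per-feature one-way ANOVA F-value across the two label groups.

    F = MS_between / MS_within.  A feature with zero within-group variance
    but distinct group means scores +inf (ranked above every finite score);
    zero variance within and between scores 0.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise SelectionError("both classes must be present")
    for c in classes:
        if np.sum(y == c) < 2:
            raise SelectionError(f"class {c} has fewer than 2 samples")

    X = frame.to_numpy(dtype=float)
    n, k = X.shape[0], classes.size
    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        ss_between += Xc.shape[0] * (mc - grand) ** 2
        ss_within += ((Xc - mc) ** 2).sum(axis=0)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)

    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
    f = np.where(ms_within == 0.0, np.where(ms_between > 0.0, np.inf, 0.0), f)
    return pd.Series(f, index=frame.columns, name="anova_f")


def select_top_fraction(
    f_scores: pd.Series, fraction: float = DEFAULT_TOP_FRACTION
) -> list[str]:
    """Keep the ceil(fraction * n) highest-scoring features.

    Ties (including ties among +inf sentinels) are broken by canonical column
    order; at least one feature is always retained.
    """
    if not 0.0 < fraction <= 1.0:
        raise SelectionError("fraction must lie in (0, 1]")
    if f_scores.empty:
        raise SelectionError("empty score map")
    n_keep = max(int(math.ceil(fraction * len(f_scores))), 1)
    order = np.lexsort((np.arange(len(f_scores)), -f_scores.to_numpy()))
    keep_positions = sorted(order[:n_keep])
    return [f_scores.index[i] for i in keep_positions]


def fit_standardizer(frame: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Per-column (mean, population SD) from training rows only."""
    means = frame.mean(axis=0)
    sds = frame.std(axis=0, ddof=0)
    bad = [c for c in frame.columns if sds[c] == 0.0]
    if bad:
        raise SelectionError(
            f"zero-SD columns cannot be standardized: {bad[:5]}"
        )
    return {c: (float(means[c]), float(sds[c])) for c in frame.columns}


def apply_standardizer(
    standardizer: dict[str, tuple[float, float]], frame: pd.DataFrame
) -> pd.DataFrame:
    """Transform columns with the stored training statistics.

    Columns not in the standardizer are dropped; a missing standardizer
    column raises a named error.
    """
    missing = [c for c in standardizer if c not in frame.columns]
    if missing:
        raise SelectionError(f"matrix is missing standardized column(s): {missing[:5]}")
    cols = list(standardizer)
    out = frame[cols].copy()
    for c in cols:
        mean, sd = standardizer[c]
        out[c] = (out[c] - mean) / sd
    return out


@dataclass
class SelectionState:
    """The fitted selection + scaling pipeline, fitted on training rows only.

    Attributes mirror the fit steps: the variance-filter survivors, their
    ANOVA F-scores, the selected top-fraction names, and the per-column
    standardization (mean, SD) pairs.
    """

    kept_after_variance: list[str]
    f_scores: dict[str, float]
    selected: list[str]
    standardizer: dict[str, tuple[float, float]]
    removed_zero_variance: list[str] = field(default_factory=list)

    @classmethod
    def fit(
        cls,
        frame: pd.DataFrame,
        labels: np.ndarray,
        variance_eps: float = DEFAULT_VARIANCE_EPS,
        top_fraction: float = DEFAULT_TOP_FRACTION,
    ) -> "SelectionState":
        kept_frame, removed = drop_zero_variance(frame, eps=variance_eps)
        scores = anova_f_scores(kept_frame, labels)
        selected = select_top_fraction(scores, fraction=top_fraction)
        standardizer = fit_standardizer(kept_frame[selected])
        return cls(
            kept_after_variance=list(kept_frame.columns),
            f_scores={c: float(scores[c]) for c in kept_frame.columns},
            selected=selected,
            standardizer=standardizer,
            removed_zero_variance=removed,
        )

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        """Standardized selected-feature view of any matrix (train or test)."""
        return apply_standardizer(self.standardizer, frame)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kept_after_variance": self.kept_after_variance,
                "f_scores": self.f_scores,
                "selected": self.selected,
                "standardizer": {c: list(v) for c, v in self.standardizer.items()},
                "removed_zero_variance": self.removed_zero_variance,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SelectionState":
        d = json.loads(text)
        return cls(
            kept_after_variance=d["kept_after_variance"],
            f_scores={c: float(v) for c, v in d["f_scores"].items()},
            selected=d["selected"],
            standardizer={c: (float(v[0]), float(v[1]))
                          for c, v in d["standardizer"].items()},
            removed_zero_variance=d.get("removed_zero_variance", []),
        )


@dataclass
class PCAResult:
    """Sign-fixed principal-component scores with loadings and variance ratios."""

    scores: pd.DataFrame
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray


def project_pca(frame: pd.DataFrame, k: int = 2) -> PCAResult:
    """Centered PCA scores of the first ``k`` components.

    Component signs are fixed by making the largest-magnitude entry of each
    loading vector positive, so projections are reproducible across runs.
    """
    n, p = frame.shape
    if k > min(n - 1, p):
        raise SelectionError(f"k={k} exceeds min(n_rows - 1, n_cols) = {min(n - 1, p)}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(frame.to_numpy(dtype=float))
    loadings = pca.components_.copy()
    for i in range(k):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    score_df = pd.DataFrame(
        scores, index=frame.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PCAResult(scores=score_df, loadings=loadings,
                     explained_variance_ratio=pca.explained_variance_ratio_)
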