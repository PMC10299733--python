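"""Control-free percentile normalization and cross-dataset marker comparison.

Independently processed expression datasets (different platforms,
normalization protocols, no shared controls) cannot be compared on raw
values.  Percentile normalization maps each measurement to its rank-based
percentile within its own dataset's pooled value distribution — by default
across ALL cells of the dataset, optionally within each feature row — using
the midrank convention (rank - 0.5) / N, which keeps values strictly inside
(0, 1) and makes ties well-defined.  Because percentiles depend only on the
within-dataset ordering, any strictly increasing per-dataset transform of
the raw values (a platform/normalization change) leaves every downstream
comparison identical; this rank invariance is what justifies cross-platform
use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CohortBundle, ExpressionMatrix, EmptyMatrixError
from .consensus import anova_two_group

POOL_MODES = ("global", "per_feature")


class PercentileNormalizer(TransformerMixin, BaseEstimator):
    """Map each cell to its midrank percentile within the transformed matrix.

    Parameters
    ----------
    pool : "global" (default) or "per_feature"
        Whether ranks are computed over the dataset's pooled cells or within
        each feature row.

    The transform is self-referential (ranks are taken within the matrix
    being transformed, not against a training set), so ``fit`` only
    validates parameters.
    """

    def __init__(self, pool: str = "global"):
        self.pool = pool

    def fit(self, X=None, y=None):
        if self.pool not in POOL_MODES:
            raise ValueError(f"pool must be one of {POOL_MODES}, got {self.pool!r}")
        self.n_features_in_ = None if X is None else np.asarray(X).shape[-1]
        return self

    def transform(self, X):
        self.fit(X)
        arr = np.asarray(X, dtype=float)
        if arr.size == 0:
            raise EmptyMatrixError("cannot percentile-normalize an empty matrix")
        if self.pool == "global":
            ranks = stats.rankdata(arr, method="average").reshape(arr.shape)
            out = (ranks - 0.5) / arr.size
        else:
            ranks = stats.rankdata(arr, method="average", axis=-1)
            out = (ranks - 0.5) / arr.shape[-1]
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


@dataclass
class PercentileMatrix:
    """Features x samples matrix of within-dataset percentiles in (0, 1)."""

    data: pd.DataFrame
    dataset_id: str = ""
    pool: str = "global"

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class CrossDatasetComparison:
    """Group contrast of one feature on the percentile scale."""

    feature_id: str
    statistic: float
    p: float
    direction: str  # group with the higher median percentile, or "none"
    group_medians: dict
    group_iqrs: dict
    test: str = "anova"
    missing: bool = False
    per_dataset: dict = field(default_factory=dict)


def percentile_normalize(
    m: ExpressionMatrix, pool: str = "global", dataset_id: str = ""
) -> PercentileMatrix:
    """Percentile-normalize one dataset's curated expression matrix."""
    out = PercentileNormalizer(pool=pool).fit_transform(m.data)
    return PercentileMatrix(out, dataset_id=dataset_id, pool=pool)


def _contrast(values: np.ndarray, labels: pd.Series, feature_id: str, test: str):
    groups = list(pd.unique(labels))
    parts = [values[(labels == g).to_numpy()] for g in groups]
    if test == "anova":
        res = anova_two_group(values, labels, feature_id)
        statistic, p = res.F, res.p
    elif test == "ranksum":
        statistic, p = stats.mannwhitneyu(parts[0], parts[1], alternative="two-sided")
        statistic, p = float(statistic), float(p)
    else:
        raise ValueError(f"test must be anova|ranksum, got {test!r}")
    medians = {g: float(np.median(part)) for g, part in zip(groups, parts)}
    iqrs = {
        g: float(np.percentile(part, 75) - np.percentile(part, 25))
        for g, part in zip(groups, parts)
    }
    if medians[groups[0]] > medians[groups[1]]:
        direction = str(groups[0])
    elif medians[groups[0]] < medians[groups[1]]:
        direction = str(groups[1])
    else:
        direction = "none"
    return statistic, p, direction, medians, iqrs


def compare_groups(
    p: PercentileMatrix, labels, features, test: str = "anova"
) -> list[CrossDatasetComparison]:
    """Two-group contrast of selected features on the percentile scale.

    Features absent from the matrix are reported with ``missing=True``
    rather than raising.
    """
    labels = pd.Series(list(labels))
    if len(labels) != len(p.sample_ids):
        raise ValueError("labels must align with the percentile matrix samples")
    if len(pd.unique(labels)) != 2 or labels.value_counts().min() < 1:
        raise ValueError("two non-empty groups required")
    out = []
    for fid in features:
        if fid not in p.data.index:
            out.append(
                CrossDatasetComparison(
                    fid, float("nan"), float("nan"), "none", {}, {},
                    test=test, missing=True,
                )
            )
            continue
        statistic, pval, direction, med, iqr = _contrast(
            p.data.loc[fid].to_numpy(), labels, fid, test
        )
        out.append(
            CrossDatasetComparison(
                fid, statistic, pval, direction, med, iqr, test=test
            )
        )
    return out


def cross_dataset_report(
    datasets: list[tuple[CohortBundle, str]],
    features,
    pool: str = "global",
    test: str = "anova",
) -> list[CrossDatasetComparison]:
    """Contrast marker percentiles between cohorts across >= 2 datasets.

    Each dataset is percentile-normalized SEPARATELY (never pooled), then the
    two-cohort contrast is computed on the concatenated percentile values,
    with per-dataset group medians retained for reporting.  Datasets may be
    single-cohort (as when a PGL-only and a PANNET-only series are compared).
    """
    if len(datasets) < 2:
        raise ValueError("cross-dataset validation needs >= 2 datasets")
    norm = []
    for bundle, dataset_id in datasets:
        pm = percentile_normalize(bundle.expression, pool=pool, dataset_id=dataset_id)
        norm.append((pm, bundle.cohorts, dataset_id))

    out = []
    for fid in features:
        have = [(pm, cohorts, did) for pm, cohorts, did in norm if fid in pm.data.index]
        if not have:
            out.append(
                CrossDatasetComparison(
                    fid, float("nan"), float("nan"), "none", {}, {},
                    test=test, missing=True,
                )
            )
            continue
        values = np.concatenate([pm.data.loc[fid].to_numpy() for pm, _, _ in have])
        labels = pd.Series(np.concatenate([c.to_numpy() for _, c, _ in have]))
        statistic, pval, direction, med, iqr = _contrast(
            values, labels, fid, test
        )
        per_dataset = {}
        for pm, cohorts, did in have:
            row = pm.data.loc[fid]
            per_dataset[did] = {
                str(g): float(np.median(row[(cohorts == g).to_numpy()]))
                for g in pd.unique(cohorts)
            }
        out.append(
            CrossDatasetComparison(
                fid, statistic, pval, direction, med, iqr,
                test=test, per_dataset=per_dataset,
            )
        )
    return out


def comparisons_to_tsv(comparisons: list[CrossDatasetComparison], path) -> None:
    rows = []
    for c in comparisons:
        row = {
            "feature_id": c.feature_id,
            "test": c.test,
            "statistic": c.statistic,
            "p": c.p,
            "direction": c.direction,
            "missing": c.missing,
        }
        for g, v in c.group_medians.items():
            row[f"median_{g}"] = v
        for g, v in c.group_iqrs.items():
            row[f"iqr_{g}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, encoding="utf-8")
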