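"""Stratified consensus marker selection with ANOVA confirmation.

The cohort is divided into five demographically defined strata — the full
primary-tumor set, males, females, race "white", and ethnicity
"not hispanic or latino" — to guard the ranking against composition bias
from the unbalanced group sizes.  The characteristic-direction ranking runs
in each usable stratum; features placed in the top k of every list (strict
intersection by default, a ``min_lists`` threshold optionally relaxes it)
form the consensus marker set.  Each selected marker is confirmed by a
one-way ANOVA of its expression between the two cohorts on the full
primary stratum, reported with per-cohort mean +/- std.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import CohortBundle, filter_primary, PRIMARY_TUMOR_CODE
from .ranking import CharacteristicDirection

ALL_PRIMARY = "all_primary"

#: The five strata: id -> pure predicate over one clinical row.
STRATUM_PREDICATES = {
    ALL_PRIMARY: lambda row: True,
    "male": lambda row: row["gender"] == "male",
    "female": lambda row: row["gender"] == "female",
    "white": lambda row: row["race"] == "white",
    "not_hispanic_or_latino": lambda row: row["ethnicity"] == "not hispanic or latino",
}


@dataclass(frozen=True)
class StratumSpec:
    stratum_id: str

    def mask(self, clinical: pd.DataFrame) -> np.ndarray:
        pred = STRATUM_PREDICATES[self.stratum_id]
        return clinical.apply(pred, axis=1).to_numpy(dtype=bool)


@dataclass
class AnovaResult:
    """One-way ANOVA of a single feature between two groups."""

    feature_id: str
    F: float
    p: float
    df_between: int
    df_within: int
    group_means: dict
    group_sds: dict
    note: str = ""


@dataclass
class ConsensusReport:
    """The selected marker set with per-stratum ranks and ANOVA confirmation."""

    selected: list[str]
    per_stratum_rank: pd.DataFrame  # features x strata, NaN when below top-k
    anova: dict  # feature_id -> AnovaResult
    p_adjusted: dict  # feature_id -> Benjamini-Hochberg adjusted p
    group_summary: pd.DataFrame  # per-feature per-cohort mean/sd (all-primary)
    k: int
    strata_used: list[str]
    strata_skipped: dict
    params: dict = field(default_factory=dict)


def build_strata(b: CohortBundle) -> list[tuple[StratumSpec, CohortBundle]]:
    """Split a primary-filtered bundle into the five demographic strata.

    Strata where either cohort has fewer than two samples cannot support the
    downstream ranking/ANOVA and are excluded with a warning.
    """
    out = []
    for stratum_id in STRATUM_PREDICATES:
        spec = StratumSpec(stratum_id)
        mask = spec.mask(b.clinical)
        sub_ids = [s for s, keep in zip(b.sample_ids, mask) if keep]
        if sub_ids:
            sub = b.subset_samples(sub_ids)
            counts = sub.cohorts.value_counts()
        else:
            sub, counts = None, pd.Series(dtype=int)
        if len(counts) < 2 or counts.min() < 2:
            warnings.warn(
                f"stratum {stratum_id!r} unusable: cohort counts "
                f"{counts.to_dict()}",
                stacklevel=2,
            )
            continue
        out.append((spec, sub))
    return out


def anova_two_group(values, labels, feature_id: str = "") -> AnovaResult:
    """One-way ANOVA between two groups of per-sample values.

    Means and standard deviations (ddof=1) are reported per group.  With zero
    variance in both groups and equal means the F statistic is undefined and
    reported as NaN with a note.
    """
    values = np.asarray(values, dtype=float)
    labels = pd.Series(labels)
    groups = list(pd.unique(labels))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    parts = [values[(labels == g).to_numpy()] for g in groups]
    if any(len(part) < 2 for part in parts):
        raise ValueError("each group needs >= 2 samples for ANOVA")
    means = {g: float(part.mean()) for g, part in zip(groups, parts)}
    sds = {g: float(part.std(ddof=1)) for g, part in zip(groups, parts)}
    df_between = 1
    df_within = len(values) - 2
    if all(sd == 0.0 for sd in sds.values()):
        if means[groups[0]] == means[groups[1]]:
            return AnovaResult(
                feature_id, float("nan"), float("nan"), df_between, df_within,
                means, sds, note="undefined: zero variance in both groups, equal means",
            )
        return AnovaResult(
            feature_id, float("inf"), 0.0, df_between, df_within, means, sds,
            note="zero within-group variance, unequal means",
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, p = stats.f_oneway(*parts)
    return AnovaResult(feature_id, float(F), float(p), df_between, df_within, means, sds)


def group_summary(b: CohortBundle, features=None) -> pd.DataFrame:
    """Per-feature per-cohort mean and std (ddof=1) of expression values."""
    m = b.expression if features is None else b.expression.subset_features(features)
    rows = {}
    cohorts = b.cohorts
    for g in pd.unique(cohorts):
        sub = m.data.loc[:, (cohorts == g).to_numpy()]
        rows[f"mean_{g}"] = sub.mean(axis=1)
        rows[f"sd_{g}"] = sub.std(axis=1, ddof=1)
    return pd.DataFrame(rows)


class ConsensusMarkerSelector(BaseEstimator):
    """Select markers ranked in the top k of every stratum's direction ranking.

    Parameters
    ----------
    k : int, default=8
        Ranking depth per stratum.
    ridge : float, default=1.0
        Penalty strength of the per-stratum logistic fit.
    min_lists : int or None, default=None
        Number of usable strata a feature must hit the top k of; None means
        all of them (strict intersection).
    class_weight : passed to :class:`CharacteristicDirection`.

    Attributes
    ----------
    selected_ : list of feature ids, ordered by mean rank then id.
    rankings_ : dict stratum_id -> full ranking DataFrame.
    per_stratum_rank_ : DataFrame of the selected features' ranks per stratum.
    strata_used_ : stratum ids that supported a fit.
    """

    def __init__(self, k: int = 8, ridge: float = 1.0, min_lists: int | None = None,
                 class_weight: str | None = None):
        self.k = k
        self.ridge = ridge
        self.min_lists = min_lists
        self.class_weight = class_weight

    def fit(self, X, y, strata: dict | None = None):
        """Fit per-stratum rankings and intersect their top-k lists.

        ``X``: samples x features DataFrame (or array); ``y``: two-group
        cohort labels; ``strata``: mapping stratum_id -> boolean sample mask
        (default: one stratum covering every sample).
        """
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if strata is None:
            strata = {"all": np.ones(len(y), dtype=bool)}
        if not 1 <= self.k <= X.shape[1]:
            raise ValueError(f"k must be in [1, {X.shape[1]}]")
        self.rankings_ = {}
        self.models_ = {}
        skipped = {}
        for stratum_id, mask in strata.items():
            mask = np.asarray(mask, dtype=bool)
            ys = y[mask]
            counts = pd.Series(ys).value_counts()
            if len(counts) < 2 or counts.min() < 2:
                skipped[stratum_id] = counts.to_dict()
                continue
            model = CharacteristicDirection(
                ridge=self.ridge, class_weight=self.class_weight
            ).fit(X.loc[mask], ys)
            self.models_[stratum_id] = model
            self.rankings_[stratum_id] = model.ranking()
        if not self.rankings_:
            raise ValueError(f"no usable strata (all skipped: {skipped})")
        self.strata_used_ = list(self.rankings_)
        self.strata_skipped_ = skipped

        need = len(self.strata_used_) if self.min_lists is None else self.min_lists
        hits: dict[str, int] = {}
        for tbl in self.rankings_.values():
            for fid in tbl.head(self.k)["feature_id"]:
                hits[fid] = hits.get(fid, 0) + 1
        selected = [fid for fid, c in hits.items() if c >= need]

        rank_of = {
            sid: dict(zip(tbl["feature_id"], tbl["rank"]))
            for sid, tbl in self.rankings_.items()
        }
        per_rank = pd.DataFrame(
            {sid: {fid: rank_of[sid].get(fid) for fid in selected}
             for sid in self.strata_used_}
        )
        if not per_rank.empty:
            order = per_rank.mean(axis=1).sort_values(kind="mergesort")
            # stable mean-rank order, ties resolved lexicographically
            per_rank = per_rank.loc[
                sorted(order.index, key=lambda f: (order[f], f))
            ]
        self.selected_ = list(per_rank.index)
        self.per_stratum_rank_ = per_rank
        return self

    def get_support_ids(self) -> list[str]:
        return list(self.selected_)


def run_consensus(
    b: CohortBundle,
    k: int = 8,
    ridge: float = 1.0,
    seed: int = 0,
    min_lists: int | None = None,
) -> ConsensusReport:
    """Full consensus pipeline on a cohort bundle.

    Applies the primary-tumor filter, builds the five demographic strata,
    ranks features by characteristic direction in each usable stratum,
    intersects the top-k lists, and confirms every selected marker by
    one-way ANOVA (plus Benjamini-Hochberg adjusted p) on the full primary
    stratum.  The fit itself is deterministic; ``seed`` is recorded in the
    provenance block.
    """
    if (b.clinical["sample_type_code"] != PRIMARY_TUMOR_CODE).any():
        b = filter_primary(b)
    strata_bundles = build_strata(b)
    if not strata_bundles:
        raise ValueError("no usable strata: every stratum lacks a cohort")
    strata_masks = {
        spec.stratum_id: np.isin(b.sample_ids, sub.sample_ids)
        for spec, sub in strata_bundles
    }
    X = pd.DataFrame(
        b.expression.values.T,
        index=pd.Index(b.sample_ids),
        columns=b.expression.feature_ids,
    )
    selector = ConsensusMarkerSelector(
        k=k, ridge=ridge, min_lists=min_lists
    ).fit(X, b.cohorts.to_numpy(), strata=strata_masks)

    anova: dict[str, AnovaResult] = {}
    labels = b.cohorts.to_numpy()
    for fid in selector.selected_:
        anova[fid] = anova_two_group(
            b.expression.data.loc[fid].to_numpy(), labels, feature_id=fid
        )
    raw_p = [anova[fid].p for fid in selector.selected_]
    finite = np.isfinite(raw_p)
    adj = np.full(len(raw_p), np.nan)
    if finite.any():
        adj[finite] = stats.false_discovery_control(np.asarray(raw_p)[finite])
    p_adjusted = dict(zip(selector.selected_, adj))

    summary = group_summary(b, selector.selected_) if selector.selected_ else (
        pd.DataFrame()
    )
    return ConsensusReport(
        selected=selector.selected_,
        per_stratum_rank=selector.per_stratum_rank_,
        anova=anova,
        p_adjusted=p_adjusted,
        group_summary=summary,
        k=k,
        strata_used=selector.strata_used_,
        strata_skipped=selector.strata_skipped_,
        params={"k": k, "ridge": ridge, "seed": seed, "min_lists": min_lists,
                "n_samples": len(b.sample_ids)},
    )


def report_to_tsv(report: ConsensusReport, path, provenance_path=None) -> None:
    """Serialize the marker table (per-cohort mean +/- std and p-values)."""
    rows = []
    for fid in report.selected:
        a = report.anova[fid]
        row = {"feature_id": fid}
        for g in a.group_means:
            row[f"{g}_mean"] = round(a.group_means[g], 3)
            row[f"{g}_sd"] = round(a.group_sds[g], 3)
        row["F"] = a.F
        row["p"] = a.p
        row["p_bh"] = report.p_adjusted[fid]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, encoding="utf-8")
    if provenance_path is not None:
        doc = {
            "k": report.k,
            "strata_used": report.strata_used,
            "strata_skipped": report.strata_skipped,
            "params": report.params,
            "per_stratum_rank": {
                fid: {s: (None if pd.isna(r) else int(r))
                      for s, r in report.per_stratum_rank.loc[fid].items()}
                for fid in report.selected
            },
        }
        with open(provenance_path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)
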