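"""Reading, curation and joining of expression matrices with clinical metadata.

The on-disk dialect is the Xena-browser export format: a tab-separated table
with the feature identifier in the first column, one sample per remaining
column, and a header row of sample barcodes.  Values are log2(RPM+1).
Clinical metadata is a TSV with named columns (``sample``, ``gender``,
``race``, ``ethnicity``, ``cohort``); the two-character sample-type code
("01" = primary solid tumor) is parsed from the barcode's final
dash-delimited token.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_KINDS = ("gene", "mirna")
PRIMARY_TUMOR_CODE = "01"

CLINICAL_COLUMNS = ("sample_type_code", "gender", "race", "ethnicity", "cohort")


class CohortIOError(ValueError):
    """Base class for cohort input/output failures."""


class EmptyMatrixError(CohortIOError):
    """The file or matrix contains no usable expression values."""


class DuplicateFeatureError(CohortIOError):
    """A feature identifier occurs more than once in one file."""


class DuplicateSampleError(CohortIOError):
    """A sample barcode occurs more than once in one file."""


class EmptyResultError(CohortIOError):
    """A curation/merge/filter step removed every feature or sample."""


@dataclass
class ExpressionMatrix:
    """Features x samples table of log2(RPM+1) expression values.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with one column per sample barcode.
    feature_kind
        Per-feature tag, each entry in ``{"gene", "mirna"}``, aligned with
        ``data.index``.
    """

    data: pd.DataFrame
    feature_kind: pd.Series

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DuplicateFeatureError(f"duplicate feature ids: {dupes[:5]}")
        if not self.data.columns.is_unique:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DuplicateSampleError(f"duplicate sample ids: {dupes[:5]}")
        self.feature_kind = pd.Series(self.feature_kind, dtype=object).reindex(
            self.data.index
        )
        bad = set(self.feature_kind.dropna().unique()) - set(FEATURE_KINDS)
        if bad:
            raise CohortIOError(f"unknown feature kinds: {sorted(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.data.loc[list(feature_ids)], self.feature_kind.loc[list(feature_ids)]
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)], self.feature_kind)

    def of_kind(self, kind: str) -> "ExpressionMatrix":
        """Return the sub-matrix of features tagged ``kind`` (gene | mirna)."""
        if kind not in FEATURE_KINDS:
            raise CohortIOError(f"unknown feature kind {kind!r}")
        keep = self.feature_kind[self.feature_kind == kind].index
        return self.subset_features(keep)


@dataclass
class CohortBundle:
    """An expression matrix joined with per-sample clinical covariates.

    ``clinical`` is indexed by sample barcode with columns
    ``sample_type_code``, ``gender``, ``race``, ``ethnicity``, ``cohort``;
    its index is identical to (and ordered as) the expression sample axis.
    """

    expression: ExpressionMatrix
    clinical: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.clinical.index) != self.expression.sample_ids:
            raise CohortIOError(
                "clinical table and expression matrix disagree on sample ids/order"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def cohorts(self) -> pd.Series:
        return self.clinical["cohort"]

    def subset_samples(self, sample_ids) -> "CohortBundle":
        sample_ids = list(sample_ids)
        return CohortBundle(
            self.expression.subset_samples(sample_ids),
            self.clinical.loc[sample_ids],
            dict(self.meta),
        )


def sample_type_code(barcode: str) -> str | None:
    """Last dash-delimited token of a barcode ("01" = primary solid tumor)."""
    if "-" not in barcode:
        return None
    return barcode.rsplit("-", 1)[1]


def read_expression_tsv(
    path, kind: str = "mirna", orientation: str = "features"
) -> ExpressionMatrix:
    """Read a Xena-dialect TSV expression matrix.

    Parameters
    ----------
    path
        Tab-separated file; first column feature ids, header row of sample
        barcodes.  Unparseable cells become missing (removed by `curate`).
    kind
        Feature kind tag applied to every row, ``"gene"`` or ``"mirna"``.
    orientation
        ``"features"`` (Xena default, features in rows) or ``"samples"``
        (transposed dialect, samples in rows).
    """
    if orientation not in ("features", "samples"):
        raise CohortIOError(f"orientation must be features|samples, got {orientation!r}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    if not header.strip():
        raise EmptyMatrixError(f"{path}: empty file or blank header")
    columns = header.split("\t")[1:]
    if len(columns) != len(set(columns)):
        seen: set[str] = set()
        dupes = sorted({c for c in columns if c in seen or seen.add(c)})
        raise DuplicateSampleError(f"{path}: duplicate columns {dupes[:5]}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise EmptyMatrixError(f"{path}: no data rows/columns")
    if not raw.index.is_unique:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise DuplicateFeatureError(f"{path}: duplicate feature ids {dupes[:5]}")
    data = raw.apply(pd.to_numeric, errors="coerce")
    data.index = data.index.astype(str)
    data.columns = data.columns.astype(str)
    if orientation == "samples":
        data = data.T
    kind_tags = pd.Series(kind, index=data.index, dtype=object)
    return ExpressionMatrix(data, kind_tags)


def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    """Write the Xena features-in-rows TSV dialect (UTF-8, header row)."""
    m.data.to_csv(path, sep="\t", encoding="utf-8")


def curate(m: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Drop every feature row containing a missing or non-finite value.

    Returns the curated matrix and the list of dropped feature ids.
    Raises :class:`EmptyResultError` if no feature survives.
    """
    finite = np.isfinite(m.data.to_numpy(dtype=float))
    keep_mask = finite.all(axis=1)
    dropped = [fid for fid, ok in zip(m.feature_ids, keep_mask) if not ok]
    if not keep_mask.any():
        raise EmptyResultError(
            f"curation removed all {m.shape[0]} features "
            "(every row carried a missing or non-finite value)"
        )
    kept = m.data.loc[keep_mask]
    return ExpressionMatrix(kept, m.feature_kind.loc[keep_mask]), dropped


def write_curation_report(dropped: list[str], path) -> None:
    pd.DataFrame({"dropped_feature": dropped}).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def read_clinical_tsv(path) -> pd.DataFrame:
    """Read a clinical metadata TSV (columns: sample, gender, race, ethnicity, cohort).

    The ``sample_type_code`` column is derived from the barcode suffix when
    not supplied explicitly.  Missing covariates remain as NaN.
    """
    tbl = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in tbl.columns:
        raise CohortIOError(f"{path}: clinical table needs a 'sample' column")
    if tbl["sample"].duplicated().any():
        dupes = tbl.loc[tbl["sample"].duplicated(), "sample"].tolist()
        raise DuplicateSampleError(f"{path}: duplicate clinical sample ids {dupes[:5]}")
    tbl = tbl.set_index("sample")
    if "sample_type_code" not in tbl.columns:
        tbl["sample_type_code"] = [sample_type_code(s) for s in tbl.index]
    for col in CLINICAL_COLUMNS:
        if col not in tbl.columns:
            tbl[col] = np.nan
    return tbl[list(CLINICAL_COLUMNS)]


def merge_clinical(m: ExpressionMatrix, clinical: pd.DataFrame) -> CohortBundle:
    """Join expression with clinical rows on the sample-id intersection.

    Samples present on only one side are dropped; their ids are recorded in
    ``bundle.meta["dropped_expression_samples"]`` /
    ``meta["dropped_clinical_samples"]``.  An empty intersection is an error.
    """
    expr_ids = m.sample_ids
    clin_ids = set(clinical.index)
    shared = [s for s in expr_ids if s in clin_ids]
    if not shared:
        raise EmptyResultError(
            f"no shared samples between expression ({len(expr_ids)}) "
            f"and clinical ({len(clin_ids)}) tables"
        )
    dropped_expr = [s for s in expr_ids if s not in clin_ids]
    dropped_clin = sorted(clin_ids - set(expr_ids))
    if dropped_expr or dropped_clin:
        warnings.warn(
            f"merge dropped {len(dropped_expr)} expression-only and "
            f"{len(dropped_clin)} clinical-only samples",
            stacklevel=2,
        )
    clin = clinical.loc[shared].copy()
    if "sample_type_code" not in clin.columns or clin["sample_type_code"].isna().all():
        clin["sample_type_code"] = [sample_type_code(s) for s in clin.index]
    return CohortBundle(
        m.subset_samples(shared),
        clin,
        meta={
            "dropped_expression_samples": dropped_expr,
            "dropped_clinical_samples": dropped_clin,
        },
    )


def filter_primary(b: CohortBundle) -> CohortBundle:
    """Keep only primary solid tumors (barcode sample-type suffix "01").

    The code is taken from the clinical ``sample_type_code`` column, falling
    back to parsing the barcode.  Fails if no barcode carries a parseable
    suffix, or if no primary sample remains.
    """
    codes = b.clinical["sample_type_code"].astype(object)
    missing = codes.isna()
    if missing.any():
        codes.loc[missing] = [sample_type_code(s) for s in codes.index[missing]]
    if codes.isna().all():
        raise CohortIOError(
            "no sample carries a parseable sample-type suffix "
            "(expected TCGA-style barcodes ending in -NN)"
        )
    keep = [s for s, c in codes.items() if c == PRIMARY_TUMOR_CODE]
    if not keep:
        counts = codes.value_counts(dropna=False).to_dict()
        raise EmptyResultError(
            f"primary-tumor filter removed all {len(codes)} samples; "
            f"observed sample-type codes: {counts}"
        )
    out = b.subset_samples(keep)
    out.meta["n_removed_nonprimary"] = len(codes) - len(keep)
    return out
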