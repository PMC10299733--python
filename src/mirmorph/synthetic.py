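"""Synthetic two-cohort miRNA expression bundles.

Emulates the statistical structure of the pooled TCGA PANNET (n=7) / PGL
(n=149) mature-strand miRNA table: 294 miRNA features on the log2(RPM+1)
scale, six planted marker profiles with cohort-specific Gaussian means, a
shared Gaussian background for all remaining (null) features, and clinical
covariates (gender, race, ethnicity, sample-type code) matching the
published cohort composition so that every demographic stratum of the
analysis pipeline is populated.

Expression values are drawn independently per feature and sample and clipped
at zero (log2(RPM+1) is non-negative; clipping is negligible at the default
means).  Covariate categories are assigned as exact per-cohort counts —
derived from the configured frequencies by largest remainder — and randomly
permuted across samples, so the cohort composition is reproduced exactly in
every replicate.  Inter-feature correlation is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .io import CohortBundle, ExpressionMatrix, CohortIOError

PANNET = "PANNET"
PGL = "PGL"


@dataclass(frozen=True)
class FeatureProfile:
    """Cohort-specific Gaussian profile of one planted marker, log2(RPM+1) scale.

    ``mean_a``/``sd_a`` parameterize cohort A (PANNET by default),
    ``mean_b``/``sd_b`` cohort B (PGL).
    """

    feature_id: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float

    def __post_init__(self) -> None:
        if self.sd_a <= 0 or self.sd_b <= 0:
            raise ValueError(f"{self.feature_id}: standard deviations must be > 0")


#: The six consensus markers with their published per-cohort mean +/- std
#: (log2(RPM+1)): PANNET first, PGL second.
MARKER_PROFILES: tuple[FeatureProfile, ...] = (
    FeatureProfile("hsa-miR-141-3p", 10.7, 0.76, 1.66, 0.87),
    FeatureProfile("hsa-miR-200c-3p", 13.4, 0.80, 4.33, 1.09),
    FeatureProfile("hsa-miR-10b-5p", 13.4, 1.0, 17.8, 0.50),
    FeatureProfile("hsa-miR-192-5p", 13.7, 0.6, 8.78, 0.87),
    FeatureProfile("hsa-miR-194-5p", 12.4, 0.72, 7.65, 0.86),
    FeatureProfile("hsa-miR-10b-3p", 2.65, 0.96, 6.17, 0.65),
)

NOT_HISPANIC = "not hispanic or latino"


@dataclass
class SyntheticConfig:
    """Parameters of the two-cohort generator.

    ``n_a``/``n_b`` are the PRIMARY-tumor sample counts of cohorts A and B;
    ``nonprimary`` optionally appends extra samples with non-"01" sample-type
    codes (removed downstream by the primary filter).  ``covariate_model``
    maps cohort -> covariate -> category frequencies (or counts; they are
    normalized).  Background features share one Gaussian in both cohorts.
    """

    n_a: int = 7
    n_b: int = 149
    n_features: int = 294
    planted: tuple[FeatureProfile, ...] = MARKER_PROFILES
    background_mean: float = 7.0
    background_sd: float = 1.5
    cohort_a: str = PANNET
    cohort_b: str = PGL
    clip_at_zero: bool = True
    covariate_model: dict = field(default_factory=dict)
    nonprimary: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < len(self.planted):
            raise ValueError(
                f"n_features={self.n_features} < {len(self.planted)} planted profiles"
            )
        ids = [p.feature_id for p in self.planted]
        if len(ids) != len(set(ids)):
            raise ValueError("planted feature ids must be unique")
        for cohort, covs in self.covariate_model.items():
            for cov, freqs in covs.items():
                if any(v < 0 for v in freqs.values()) or sum(freqs.values()) <= 0:
                    raise ValueError(f"invalid frequencies for {cohort}/{cov}")


def default_config(seed: int = 0) -> SyntheticConfig:
    """The study-condition configuration: 7 PANNET vs 149 PGL primaries,
    294 miRNAs, six planted marker profiles, covariates mirroring the
    published composition (PGL 64 male / 85 female; PANNET all white,
    6 of 7 not-hispanic-or-latino), plus three non-primary PGL samples
    exercising the "-01" filter.
    """
    covariate_model = {
        PANNET: {
            "gender": {"male": 3, "female": 4},
            "race": {"white": 7},
            "ethnicity": {NOT_HISPANIC: 6, "unclassified": 1},
        },
        PGL: {
            "gender": {"male": 64, "female": 85},
            "race": {"white": 135, "black or african american": 9, "asian": 5},
            "ethnicity": {NOT_HISPANIC: 140, "hispanic or latino": 9},
        },
    }
    return SyntheticConfig(
        covariate_model=covariate_model,
        nonprimary={PGL: {"06": 2, "11": 1}},
        seed=seed,
    )


def _counts_from_frequencies(freqs: dict, n: int) -> dict:
    """Exact category counts summing to n, by largest remainder."""
    total = float(sum(freqs.values()))
    cats = sorted(freqs)
    exact = {c: freqs[c] * n / total for c in cats}
    counts = {c: int(np.floor(exact[c])) for c in cats}
    short = n - sum(counts.values())
    by_rem = sorted(cats, key=lambda c: (-(exact[c] - counts[c]), c))
    for c in by_rem[:short]:
        counts[c] += 1
    return counts


def _assign_covariate(freqs: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    counts = _counts_from_frequencies(freqs, n)
    labels = np.repeat(list(counts), list(counts.values()))
    return rng.permutation(labels)


def generate(cfg: SyntheticConfig) -> CohortBundle:
    """Draw one synthetic cohort bundle, fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)

    codes_a = ["01"] * cfg.n_a
    codes_b = ["01"] * cfg.n_b
    for code, count in sorted(cfg.nonprimary.get(cfg.cohort_a, {}).items()):
        codes_a += [code] * count
    for code, count in sorted(cfg.nonprimary.get(cfg.cohort_b, {}).items()):
        codes_b += [code] * count
    n_a, n_b = len(codes_a), len(codes_b)

    barcodes = [f"SYN-A-{i:04d}-{c}" for i, c in enumerate(codes_a)] + [
        f"SYN-B-{i:04d}-{c}" for i, c in enumerate(codes_b)
    ]
    cohorts = [cfg.cohort_a] * n_a + [cfg.cohort_b] * n_b

    planted_ids = [p.feature_id for p in cfg.planted]
    n_bg = cfg.n_features - len(planted_ids)
    width = max(4, len(str(max(n_bg, 1))))
    feature_ids = planted_ids + [f"syn-miR-{i:0{width}d}" for i in range(n_bg)]

    values = np.empty((cfg.n_features, n_a + n_b))
    for row, p in enumerate(cfg.planted):
        values[row, :n_a] = rng.normal(p.mean_a, p.sd_a, n_a)
        values[row, n_a:] = rng.normal(p.mean_b, p.sd_b, n_b)
    if n_bg:
        values[len(planted_ids):] = rng.normal(
            cfg.background_mean, cfg.background_sd, (n_bg, n_a + n_b)
        )
    if cfg.clip_at_zero:
        # log2(RPM+1) is non-negative; truncation slightly biases moments of
        # profiles whose mean sits within ~2 sd of zero
        np.clip(values, 0.0, None, out=values)

    clinical = pd.DataFrame(
        {
            "sample_type_code": codes_a + codes_b,
            "cohort": cohorts,
        },
        index=pd.Index(barcodes, name="sample"),
    )
    # covariate counts are exact over the PRIMARY block of each cohort (the
    # published composition refers to the primary analysis set); the few
    # non-primary extras get their own largest-remainder assignment
    model_a = cfg.covariate_model.get(cfg.cohort_a, {})
    model_b = cfg.covariate_model.get(cfg.cohort_b, {})
    for cov in ("gender", "race", "ethnicity"):
        col = np.full(n_a + n_b, np.nan, dtype=object)
        for model, start, n_prim, n_tot in (
            (model_a, 0, cfg.n_a, n_a),
            (model_b, n_a, cfg.n_b, n_b),
        ):
            if cov not in model:
                continue
            col[start : start + n_prim] = _assign_covariate(model[cov], n_prim, rng)
            n_extra = n_tot - n_prim
            if n_extra:
                col[start + n_prim : start + n_tot] = _assign_covariate(
                    model[cov], n_extra, rng
                )
        clinical[cov] = col
    clinical = clinical[["sample_type_code", "gender", "race", "ethnicity", "cohort"]]

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=feature_ids, columns=barcodes),
        pd.Series("mirna", index=feature_ids, dtype=object),
    )
    return CohortBundle(expr, clinical, meta={"seed": cfg.seed, "synthetic": True})


def permute_labels(b: CohortBundle, seed: int) -> CohortBundle:
    """Randomly reassign cohort labels, preserving group sizes (null model)."""
    labels = b.clinical["cohort"].to_numpy()
    if len(pd.unique(labels)) < 2:
        raise CohortIOError("permute_labels needs at least two cohorts")
    rng = np.random.default_rng(seed)
    permuted = labels[rng.permutation(len(labels))]
    clinical = b.clinical.copy()
    clinical["cohort"] = permuted
    return CohortBundle(b.expression, clinical, {**b.meta, "permuted_seed": seed})


def config_to_yaml(cfg: SyntheticConfig, path) -> None:
    doc = asdict(cfg)
    doc["planted"] = [asdict(p) for p in cfg.planted]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path) -> SyntheticConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    doc["planted"] = tuple(FeatureProfile(**p) for p in doc.get("planted", ()))
    return SyntheticConfig(**doc)


def replicate_configs(base: SyntheticConfig, seeds) -> list[SyntheticConfig]:
    """Copies of ``base`` differing only in seed (replicate cohort draws)."""
    return [replace(base, seed=int(s)) for s in seeds]
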