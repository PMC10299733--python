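"""Morphing projections: aligned t-SNE views and convex-blend morph frames.

Each feature view (e.g. the gene block vs the miRNA block of the same
samples) gets its own 2D t-SNE embedding.  Independent t-SNE runs differ by
an arbitrary rotation/reflection/scale, so before blending, the second view
is rigidly aligned to the first by full orthogonal Procrustes (rotation or
reflection, isotropic scale, translation).  A morph frame at weight w is the
per-sample convex combination (1-w)*A + w*B_aligned; a frame sequence with
evenly spaced weights reproduces the animated gene-to-miRNA transition as a
set of static coordinate tables.

Blending operates on final aligned coordinates (not on projection axes);
this is the documented interpretation of the morphing-projection transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.manifold import TSNE

from .io import CohortBundle, ExpressionMatrix


@dataclass
class Embedding:
    """Per-sample 2D coordinates for one feature view."""

    sample_ids: list[str]
    coords: np.ndarray  # (n, 2)
    view_label: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape != (len(self.sample_ids), 2):
            raise ValueError(
                f"coords must be ({len(self.sample_ids)}, 2), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")


@dataclass
class MorphFrame:
    """A convex blend of two aligned embeddings at weight w (0 = A, 1 = B)."""

    sample_ids: list[str]
    coords: np.ndarray
    weight: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"weight must be in [0, 1], got {self.weight}")
        self.coords = np.asarray(self.coords, dtype=float)


def max_perplexity(n_samples: int) -> float:
    """Upper admissible perplexity for n samples: (n - 1) / 3."""
    return (n_samples - 1) / 3.0


def embed_tsne(
    data: CohortBundle | ExpressionMatrix,
    view: str | None = None,
    perplexity: float | None = None,
    seed: int = 0,
    n_iter: int = 1000,
    standardize: bool = True,
) -> Embedding:
    """2D t-SNE embedding of the samples of one feature view.

    Parameters
    ----------
    data
        Cohort bundle or bare expression matrix (features x samples).
    view
        Feature-kind filter ("gene" | "mirna"); None uses all features.
    perplexity
        t-SNE perplexity.  None picks min(30, (n-1)/3 * 0.999) — the default
        lowered automatically for small cohorts; an explicit value must
        satisfy perplexity < (n-1)/3 or the call fails naming the bound.
    seed
        Mandatory RNG seed; identical seeds give identical coordinates.
    """
    m = data.expression if isinstance(data, CohortBundle) else data
    if view is not None:
        m = m.of_kind(view)
    n = len(m.sample_ids)
    if n < 4:
        raise ValueError(f"t-SNE needs >= 4 samples, got {n}")
    bound = max_perplexity(n)
    if perplexity is None:
        perplexity = min(30.0, bound * 0.999)
    elif perplexity >= bound:
        raise ValueError(
            f"perplexity {perplexity} must be < (n - 1)/3 = {bound:.3f} for n={n}"
        )
    X = m.values.T  # samples x features
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=n_iter,
    )
    coords = tsne.fit_transform(X)
    coords = coords - coords.mean(axis=0)  # centered at the origin
    return Embedding(
        sample_ids=m.sample_ids,
        coords=coords,
        view_label=view or "all",
        params={"perplexity": perplexity, "seed": seed, "n_iter": n_iter},
    )


class ProcrustesAligner(TransformerMixin, BaseEstimator):
    """Rigidly align 2D point sets to a reference (full orthogonal Procrustes).

    ``fit`` stores the reference coordinates; ``transform`` returns the input
    rotated/reflected, isotropically scaled and translated to minimize the
    summed squared distance to the reference.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("reference must be a 2D coordinate array")
        self.reference_ = X
        self.reference_mean_ = X.mean(axis=0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape != self.reference_.shape:
            raise ValueError(
                f"shape mismatch: reference {self.reference_.shape}, got {X.shape}"
            )
        A = self.reference_ - self.reference_mean_
        B = X - X.mean(axis=0)
        R, s = orthogonal_procrustes(B, A)
        norm_b2 = float((B * B).sum())
        scale = s / norm_b2 if norm_b2 > 0 else 1.0
        return scale * (B @ R) + self.reference_mean_


def align(a: Embedding, b: Embedding) -> Embedding:
    """Return ``b`` Procrustes-aligned onto ``a`` (a is never modified)."""
    if a.sample_ids != b.sample_ids:
        raise ValueError("embeddings must share identical sample ids and order")
    coords = ProcrustesAligner().fit(a.coords).transform(b.coords)
    return Embedding(
        sample_ids=list(b.sample_ids),
        coords=coords,
        view_label=b.view_label,
        params={**b.params, "aligned_to": a.view_label},
    )


def morph(a: Embedding, b_aligned: Embedding, w: float) -> MorphFrame:
    """Per-sample convex combination (1-w)*a + w*b_aligned."""
    if a.sample_ids != b_aligned.sample_ids:
        raise ValueError("embeddings must share identical sample ids and order")
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"morph weight must be in [0, 1], got {w}")
    if w == 0.0:
        coords = a.coords.copy()
    elif w == 1.0:
        coords = b_aligned.coords.copy()
    else:
        coords = (1.0 - w) * a.coords + w * b_aligned.coords
    return MorphFrame(sample_ids=list(a.sample_ids), coords=coords, weight=w)


def frame_sequence(a: Embedding, b_aligned: Embedding, n_frames: int) -> list[MorphFrame]:
    """Morph frames at evenly spaced weights on [0, 1]; endpoints included."""
    if n_frames < 2:
        raise ValueError(f"n_frames must be >= 2, got {n_frames}")
    weights = np.linspace(0.0, 1.0, n_frames)
    return [morph(a, b_aligned, float(w)) for w in weights]


def frames_to_tsv(frames: list[MorphFrame], path) -> None:
    rows = []
    for frame in frames:
        for sid, (x, y) in zip(frame.sample_ids, frame.coords):
            rows.append({"sample_id": sid, "x": x, "y": y, "weight": frame.weight})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, encoding="utf-8")


def embedding_to_tsv(e: Embedding, path) -> None:
    pd.DataFrame(
        {"sample_id": e.sample_ids, "x": e.coords[:, 0], "y": e.coords[:, 1]}
    ).to_csv(path, sep="\t", index=False, encoding="utf-8")
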