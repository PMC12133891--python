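"""Nutrient-composition PCA and flux-space t-SNE embeddings of diets.

PCA is computed here by singular value decomposition with a deterministic
sign convention; t-SNE delegates to scikit-learn with a mandatory seed.
t-SNE coordinates are treated as visual outputs: the contract covers shape,
finiteness and same-seed reproducibility, not coordinate semantics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .biomarkers import BiomarkerPanel
from .solver import FluxSolution

log = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    pass


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # samples x k
    method: str  # "pca" | "tsne"
    feature_names: list[str]
    sample_names: list[str]
    variance_explained: list[float] = field(default_factory=list)  # pca only
    loadings: np.ndarray | None = None  # pca only, features x k
    seed: int | None = None  # tsne only

    def to_tsv(self, path: str | Path) -> None:
        cols = [f"dim{i + 1}" for i in range(self.coordinates.shape[1])]
        df = pd.DataFrame(self.coordinates, index=self.sample_names, columns=cols)
        df.rename_axis("sample").to_csv(path, sep="\t", float_format="%.10g")


def pca(matrix: np.ndarray, k: int, standardize: bool = True,
        feature_names: list[str] | None = None,
        sample_names: list[str] | None = None) -> EmbeddingResult:
    """Principal component analysis by SVD of the centered (scaled) matrix.

    Columns are mean-centered and, if ``standardize``, scaled to unit
    variance; constant columns are dropped with a warning.  Component signs
    are fixed so each loading vector's largest-magnitude entry is positive.
    Scores are the sample projections; ``variance_explained`` fractions are
    non-increasing.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("pca needs a 2-D matrix with at least 2 samples")
    n, p = X.shape
    feature_names = list(feature_names) if feature_names is not None else [
        f"f{j}" for j in range(p)]
    sample_names = list(sample_names) if sample_names is not None else [
        f"s{i}" for i in range(n)]
    if not (1 <= k <= min(n - 1, p)):
        raise ValueError(f"k={k} out of range for {n} samples x {p} features")

    Xc = X - X.mean(axis=0)
    keep = ~np.all(np.abs(Xc) < 1e-12, axis=0)
    if not keep.any():
        raise DegenerateInputError("all features are constant; PCA undefined")
    if not keep.all():
        dropped = [feature_names[j] for j in np.flatnonzero(~keep)]
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
        Xc = Xc[:, keep]
        feature_names = [f for f, kp in zip(feature_names, keep) if kp]
    if standardize:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / sd

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k_eff = min(k, len(s))
    V = Vt[:k_eff].T  # loadings, features x k
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k_eff):
        pivot = int(np.argmax(np.abs(V[:, j])))
        if V[pivot, j] < 0:
            V[:, j] = -V[:, j]
    scores = Xc @ V
    total_var = float(np.sum(s**2))
    var_exp = [float(si**2 / total_var) if total_var > 0 else 0.0
               for si in s[:k_eff]]
    if total_var <= 1e-24:
        warnings.warn("input rows are identical; all scores are zero",
                      stacklevel=2)
    return EmbeddingResult(coordinates=scores, method="pca",
                           feature_names=feature_names,
                           sample_names=sample_names,
                           variance_explained=var_exp, loadings=V)


def flux_matrix(solutions: dict, scope: str = "all_reactions",
                panel: BiomarkerPanel | None = None,
                drop_all_zero: bool = False
                ) -> tuple[np.ndarray, list[str], list[str]]:
    """Sample x reaction flux matrix from per-diet solutions.

    ``solutions`` maps a sample label (diet, or (diet, sex) tuple) to a
    FluxSolution; all solutions must cover the same reaction set.  Scope
    ``panel_reactions`` restricts columns to a resolved biomarker panel.
    """
    if not solutions:
        raise ValueError("no solutions given")
    labels = [k if isinstance(k, str) else "/".join(map(str, k))
              for k in solutions]
    sols: list[FluxSolution] = list(solutions.values())
    ref_cols = list(sols[0].fluxes)
    for lbl, s in zip(labels, sols):
        if list(s.fluxes) != ref_cols:
            raise ValueError(f"solution {lbl!r} covers a different reaction "
                             "set; mixed models in one flux matrix")
    if scope == "panel_reactions":
        if panel is None:
            raise ValueError("panel scope requires a resolved BiomarkerPanel")
        cols = panel.all_reactions()
    elif scope == "all_reactions":
        cols = ref_cols
    else:
        raise ValueError(f"unknown scope {scope!r}")
    M = np.array([[s.fluxes[c] for c in cols] for s in sols])
    if drop_all_zero:
        keep = ~np.all(np.abs(M) < 1e-12, axis=0)
        if not keep.all():
            log.info("flux_matrix: dropping %d all-zero columns",
                     int((~keep).sum()))
        M = M[:, keep]
        cols = [c for c, kp in zip(cols, keep) if kp]
    return M, cols, labels


def tsne_embed(matrix: np.ndarray, seed: int, perplexity: float = 30.0,
               sample_names: list[str] | None = None,
               feature_names: list[str] | None = None) -> EmbeddingResult:
    """2-D t-SNE with a mandatory seed; perplexity capped at (samples-1)/3.

    Deterministic for a fixed seed and backend (PCA initialization, exact
    gradient for the small sample counts used here).
    """
    from sklearn.manifold import TSNE

    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError(f"t-SNE needs at least 4 samples, got {n}")
    perplexity = min(perplexity, (n - 1) / 3.0)
    if perplexity <= 0:
        raise ValueError("perplexity must be positive")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=int(seed),
                init="pca", method="exact")
    coords = tsne.fit_transform(X)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return EmbeddingResult(
        coordinates=coords, method="tsne",
        feature_names=list(feature_names) if feature_names is not None else [],
        sample_names=list(sample_names) if sample_names is not None
        else [f"s{i}" for i in range(n)],
        seed=int(seed))
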