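"""One-hot diagnosis encoding and 2-D patient projection.

Patients are represented by binary vectors over their (non-AD) full-code
diagnoses and projected to two components.  The reducer is pluggable:
UMAP when the optional dependency is installed and requested, otherwise a
deterministic linear projection onto the top-2 principal directions, so
tests and pipelines never depend on a stochastic embedding.  Features
whose display name (or code) matches the exclusion pattern — by default
any name containing "alzheimer", case-insensitively — are excluded from
the encoding so the projection cannot trivially separate cases on the
case-defining codes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def one_hot(sets: dict[str, set[str]], names: dict[str, str] | None = None,
            exclusion: str = "alzheimer",
            patient_ids=None) -> pd.DataFrame:
    """Binary patient x feature matrix with excluded columns removed.

    Column order is lexicographic; *names* maps codes to display names for
    the exclusion match (the code itself is always checked too).
    """
    names = names or {}
    if patient_ids is None:
        patient_ids = sorted(sets)
    else:
        patient_ids = [str(p) for p in patient_ids]
    pat = exclusion.lower() if exclusion else None

    def excluded(code: str) -> bool:
        if not pat:
            return False
        return pat in code.lower() or pat in names.get(code, "").lower()

    features = sorted({f for p in patient_ids for f in sets.get(p, set())
                       if not excluded(f)})
    col_index = {f: j for j, f in enumerate(features)}
    mat = np.zeros((len(patient_ids), len(features)), dtype=np.int8)
    for i, p in enumerate(patient_ids):
        for f in sets.get(p, set()):
            j = col_index.get(f)
            if j is not None:
                mat[i, j] = 1
    return pd.DataFrame(mat, index=patient_ids, columns=features)


def _pca_2d(X: np.ndarray) -> np.ndarray:
    """Deterministic truncated projection onto the top-2 principal directions.

    Sign convention: each direction is flipped so its largest-magnitude
    loading is positive, making the output independent of SVD sign
    ambiguity (and of any seed).
    """
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(2, Vt.shape[0])
    comps = np.zeros((X.shape[0], 2))
    for j in range(k):
        v = Vt[j]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        comps[:, j] = Xc @ v
    return comps


def reduce_2d(matrix: pd.DataFrame, reducer: str = "pca",
              seed: int = 0, **reducer_kwargs) -> pd.DataFrame:
    """Project patients to 2-D.

    reducer="pca" is the deterministic fallback (seed-independent);
    reducer="umap" uses umap-learn when importable and falls back to PCA
    with a logged notice otherwise.
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 patients to embed")
    X = matrix.to_numpy(dtype=float)
    name = reducer
    if reducer == "umap":
        try:
            from umap import UMAP
            emb = UMAP(n_components=2, random_state=seed,
                       **reducer_kwargs).fit_transform(X)
        except ImportError:
            log.warning("umap-learn not available; falling back to the "
                        "deterministic PCA reducer")
            emb = _pca_2d(X)
            name = "pca_fallback"
    elif reducer == "pca":
        emb = _pca_2d(X)
    elif callable(reducer):
        emb = np.asarray(reducer(X, seed=seed, **reducer_kwargs))
        name = getattr(reducer, "__name__", "custom")
    else:
        raise ValueError(f"unknown reducer {reducer!r}")
    out = pd.DataFrame(emb[:, :2], index=matrix.index, columns=["comp1", "comp2"])
    out.attrs["reducer"] = name
    return out


def axis_association(embedding: pd.DataFrame, label, kind: str = "binary"
                     ) -> pd.DataFrame:
    """Association of each embedding component with a patient label.

    binary labels: two-sided Mann-Whitney U per component; continuous:
    Pearson r and p.  Returns rows (component, statistic, p, n).
    """
    lab = pd.Series(label)
    if isinstance(lab.index, pd.RangeIndex):
        if len(lab) != len(embedding):
            raise ValueError("positional label length must match the embedding")
        lab = pd.Series(lab.to_numpy(), index=embedding.index)
    else:
        lab = lab.reindex(embedding.index)
    if lab.isna().any():
        raise ValueError("label must be defined for every embedded patient")
    rows = []
    for comp in ("comp1", "comp2"):
        x = embedding[comp].to_numpy(dtype=float)
        if kind == "binary":
            values = lab.unique()
            if len(values) < 2:
                raise ValueError("degenerate label: only one level present")
            if len(values) > 2:
                raise ValueError("binary association requires exactly two label levels")
            g1 = x[(lab == values[0]).to_numpy()]
            g2 = x[(lab == values[1]).to_numpy()]
            res = stats.mannwhitneyu(g1, g2, alternative="two-sided")
            rows.append({"component": comp, "statistic": float(res.statistic),
                         "p": float(res.pvalue), "n": len(x)})
        elif kind == "continuous":
            y = lab.to_numpy(dtype=float)
            if np.all(y == y[0]):
                raise ValueError("degenerate label: constant values")
            r, p = stats.pearsonr(x, y)
            rows.append({"component": comp, "statistic": float(r),
                         "p": float(p), "n": len(x)})
        else:
            raise ValueError("kind must be 'binary' or 'continuous'")
    return pd.DataFrame(rows)
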