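"""Population-structure diagnostics from the GRM.

SVD of the (symmetric PSD) genomic relationship matrix gives sample scores
on the leading axes; breeds should appear as well-separated clusters and
case/control groups should not, so the cluster report scores both labelings
on the first two axes and writes the diagnostic scatter plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


@dataclass
class StructureResult:
    """Sample coordinates on the leading axes of the GRM.

    ``scores[:, j]`` is eigenvector j scaled by sqrt(eigenvalue_j);
    ``variance_explained`` is each eigenvalue's share of the GRM trace.
    """

    scores: np.ndarray
    singular_values: np.ndarray
    variance_explained: np.ndarray

    def to_frame(self, sample_ids) -> pd.DataFrame:
        cols = {f"PC{j + 1}": self.scores[:, j] for j in range(self.scores.shape[1])}
        return pd.DataFrame({"sample_id": list(sample_ids), **cols})


def svd_structure(grm_matrix: np.ndarray, k: int = 10) -> StructureResult:
    """Eigendecompose a GRM and return scores on the top-``k`` axes.

    Signs are fixed so the largest-magnitude loading of each axis is
    positive, making output deterministic across runs and BLAS builds.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    G = np.asarray(grm_matrix, dtype=float)
    n = G.shape[0]
    if G.shape != (n, n):
        raise ValueError("GRM must be square")
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    w, v = eigh(G)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    w_pos = np.clip(w, 0.0, None)
    for j in range(n):
        i = np.argmax(np.abs(v[:, j]))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
    total = w_pos.sum()
    scores = v[:, :k] * np.sqrt(w_pos[:k])
    return StructureResult(
        scores=scores,
        singular_values=w_pos[:k],
        variance_explained=(w_pos[:k] / total) if total > 0 else np.zeros(k),
    )


def _separation(points: np.ndarray, labels: np.ndarray) -> float:
    """Silhouette score of a labeling on the given coordinates (NaN if <2 labels)."""
    from sklearn.metrics import silhouette_score

    uniq = pd.unique(labels)
    if len(uniq) < 2 or any(np.sum(labels == u) < 2 for u in uniq):
        return float("nan")
    return float(silhouette_score(points, labels))


def cluster_report(
    result: StructureResult,
    samples: pd.DataFrame,
    plot_path=None,
) -> dict:
    """Separation diagnostics for breed and group labels on axes 1-2.

    Returns per-label centroids plus a silhouette separation score for the
    breed labeling and the case/control labeling; optionally writes the
    scatter plot (axes 1-2, colored by breed, marker by group).
    """
    if len(samples) != result.scores.shape[0]:
        raise ValueError("samples and scores are not aligned")
    pts = result.scores[:, :2]
    breeds = samples["breed"].fillna("?").astype(str).to_numpy()
    groups = samples["group"].fillna("?").astype(str).to_numpy()
    centroids = (
        pd.DataFrame({"breed": breeds, "group": groups, "PC1": pts[:, 0], "PC2": pts[:, 1]})
        .groupby(["breed", "group"], dropna=False)[["PC1", "PC2"]]
        .mean()
        .reset_index()
    )
    report = {
        "breed_separation": _separation(pts, breeds),
        "group_separation": _separation(pts, groups),
        "centroids": centroids,
    }
    if plot_path is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        markers = {g: m for g, m in zip(pd.unique(groups), "ox^sv*")}
        colors = {b: f"C{i}" for i, b in enumerate(pd.unique(breeds))}
        for b in pd.unique(breeds):
            for g in pd.unique(groups):
                sel = (breeds == b) & (groups == g)
                if sel.any():
                    ax.scatter(pts[sel, 0], pts[sel, 1], c=colors[b],
                               marker=markers[g], s=18, label=f"{b}/{g}")
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return report
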