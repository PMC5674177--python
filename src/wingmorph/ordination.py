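"""Principal component analysis of tangent coordinates (shape ordination).

Covariance (not correlation) PCA: tangent coordinates all share the same
units, and rescaling them per coordinate would distort shape geometry.
An unknown specimen can be projected a posteriori onto the fitted axes
without refitting, which is how a fossil is placed in the morphospace of
an extant reference sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class OrdinationResult:
    """PCA axes, explained-variance percentages and specimen scores."""

    mean: np.ndarray          # (p,) grand mean of the tangent coordinates
    axes: np.ndarray          # (m, p) orthonormal rows, eigenvalue order
    variance_pct: np.ndarray  # (m,) percentages, non-increasing, sum 100
    scores: np.ndarray        # (n, m) centred specimen scores
    specimen_ids: list[str]
    unknown_score: np.ndarray | None = None

    @property
    def n_axes(self) -> int:
        return self.axes.shape[0]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_axes)]
        df = pd.DataFrame(self.scores, columns=cols)
        df.insert(0, "specimen_id", self.specimen_ids)
        return df

    def variance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis": [f"PC{i + 1}" for i in range(self.n_axes)],
                "variance_pct": self.variance_pct,
            }
        )


def pca_shapes(
    tangent_coords: np.ndarray, specimen_ids: list[str] | None = None
) -> OrdinationResult:
    """PCA of tangent coordinates about their grand mean.

    Axes are eigenvectors of the coordinate covariance sorted by
    eigenvalue; directions of numerically zero variance (the null space
    superimposition leaves behind) are dropped, so the retained percentages
    sum to 100 and full-rank score geometry preserves pairwise tangent
    distances.  Each axis is oriented so its largest-magnitude loading is
    positive, making plots reproducible.
    """
    x = np.asarray(tangent_coords, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValidationError("pca_shapes needs an (n >= 3, p) coordinate matrix")
    mean = x.mean(axis=0)
    xc = x - mean
    _, sv, vt = np.linalg.svd(xc, full_matrices=False)
    var = sv**2
    total = var.sum()
    if total == 0.0:
        raise ValidationError("zero total variance: all shapes identical")
    keep = var / total > 1e-14
    axes = vt[keep]
    var = var[keep]
    for j in range(axes.shape[0]):
        i = np.argmax(np.abs(axes[j]))
        if axes[j, i] < 0:
            axes[j] = -axes[j]
    scores = xc @ axes.T
    if specimen_ids is None:
        specimen_ids = [f"specimen_{i + 1}" for i in range(x.shape[0])]
    return OrdinationResult(
        mean=mean,
        axes=axes,
        variance_pct=100.0 * var / total,
        scores=scores,
        specimen_ids=list(specimen_ids),
    )


def project_unknown(result: OrdinationResult, unknown: np.ndarray) -> np.ndarray:
    """Score an unknown tangent vector on already-fitted axes.

    ``score = axes @ (x - mean)``; the axes are unchanged.  The score is
    also stored on ``result.unknown_score`` for plotting.
    """
    x = np.asarray(unknown, dtype=float)
    if x.shape != result.mean.shape:
        raise ValidationError(
            f"unknown vector length {x.shape} does not match the ordination "
            f"basis {result.mean.shape}"
        )
    score = result.axes @ (x - result.mean)
    result.unknown_score = score
    return score


def plot_scores(
    result: OrdinationResult,
    groups: list[str] | None = None,
    path: str | None = None,
    unknown_label: str = "unknown",
):
    """Scatter of PC1 x PC2, optionally coloured by group, unknown starred."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    if groups is None:
        ax.scatter(result.scores[:, 0], result.scores[:, 1], s=18, alpha=0.7)
    else:
        for g in sorted(set(groups)):
            idx = [i for i, gg in enumerate(groups) if gg == g]
            ax.scatter(
                result.scores[idx, 0], result.scores[idx, 1], s=18, alpha=0.7, label=g
            )
        ax.legend(fontsize=8)
    if result.unknown_score is not None:
        ax.scatter(
            [result.unknown_score[0]],
            [result.unknown_score[1]],
            marker="*",
            s=180,
            color="black",
            zorder=5,
            label=unknown_label,
        )
    ax.set_xlabel(f"PC1 ({result.variance_pct[0]:.2f}%)")
    ax.set_ylabel(f"PC2 ({result.variance_pct[1]:.2f}%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
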