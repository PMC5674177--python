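"""Linear discriminant analysis on tangent coordinates and taxon assignment.

The classifier is the classic Gaussian equal-covariance model: each group g
has its own mean shape but all groups share the pooled within-group
covariance.  An unknown specimen x is scored against every group by the
Mahalanobis distance

    MD_g = sqrt((x - mu_g)' S_pooled^-1 (x - mu_g))

and the posterior probability of membership in g is the softmax of
``-MD_g^2 / 2 + log(prior_g)``; the unknown is assigned to the group with
the highest posterior.  With equal priors that is exactly the group at
minimal Mahalanobis distance.

GPA leaves at least four exactly-null directions in the 2k-dimensional
tangent coordinates (two for centring, one for scale, one for rotation), so
the tangent vectors are first reduced to the principal directions of total
variance carrying non-negligible variance; means, pooled covariance and
canonical axes all live in that reduced basis, and the model records the
reduction map so unknowns can be projected through it.

Classifier effectiveness is summarised by the hit-ratio — the percentage of
specimens correctly re-assigned to their own group in leave-one-out
cross-validation, the standard figure of merit for morphometric
discrimination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh

from .errors import SchemeError, SingularCovarianceError, ValidationError
from .procrustes import AlignedShapes, align_to_consensus, gpa
from .tps import LandmarkConfiguration, ShapeDataset

#: Relative total-variance cutoff for the pre-LDA reduction: principal
#: directions whose variance fraction falls below this are treated as the
#: null space left behind by superimposition.
VARIANCE_CUTOFF = 1e-12


@dataclass
class DiscriminantModel:
    """Fitted linear discriminant model in a reduced tangent basis."""

    grouping_level: str
    groups: list[str]
    priors: np.ndarray
    n_per_group: np.ndarray
    grand_mean: np.ndarray          # (p,) in the original tangent space
    components: np.ndarray          # (d, p) rows: reduction map, orthonormal
    group_means: np.ndarray         # (G, d) in the reduced basis
    pooled_cov: np.ndarray          # (d, d) pooled within-group covariance
    axes: np.ndarray                # (d, m) canonical axes, m <= G-1
    axis_eigenvalues: np.ndarray    # (m,) between/within eigenvalues
    shrinkage: float = 0.0
    _chol: tuple = field(default=None, repr=False)

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]

    def reduce(self, x: np.ndarray) -> np.ndarray:
        """Map tangent-space vectors into the model's reduced basis."""
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.grand_mean.shape[0]:
            raise ValidationError(
                f"vector length {x.shape[-1]} does not match the model's "
                f"tangent dimension {self.grand_mean.shape[0]}"
            )
        return (x - self.grand_mean) @ self.components.T

    def canonical_scores(self, x: np.ndarray) -> np.ndarray:
        """Scores on the canonical (discriminant) axes."""
        return self.reduce(x) @ self.axes


@dataclass
class CrossValidationReport:
    """Leave-one-out cross-validation summary."""

    grouping_level: str
    per_group_hit_ratio: dict[str, float]   # percentages
    global_hit_ratio: float                 # percentage
    n_misclassified: int
    n_total: int
    confusion: pd.DataFrame                 # rows: true group, cols: predicted

    def to_dict(self) -> dict:
        return {
            "grouping_level": self.grouping_level,
            "global_hit_ratio": self.global_hit_ratio,
            "n_misclassified": self.n_misclassified,
            "n_total": self.n_total,
            "per_group_hit_ratio": self.per_group_hit_ratio,
            "confusion": {
                true: {pred: int(v) for pred, v in row.items()}
                for true, row in self.confusion.to_dict(orient="index").items()
            },
        }


@dataclass
class AssignmentResult:
    """Posterior probabilities and Mahalanobis distances for one unknown."""

    level: str
    groups: list[str]
    posterior: dict[str, float]
    mahalanobis: dict[str, float]
    assigned_group: str

    def to_dict(self) -> dict:
        order = sorted(self.groups, key=lambda g: -self.posterior[g])
        return {
            "level": self.level,
            "assigned_group": self.assigned_group,
            "candidates": [
                {
                    "group": g,
                    "posterior": self.posterior[g],
                    "mahalanobis": self.mahalanobis[g],
                }
                for g in order
            ],
        }


def _shrink(cov: np.ndarray, lam: float) -> np.ndarray:
    if lam <= 0:
        return cov
    return (1.0 - lam) * cov + lam * np.diag(np.diag(cov))


def fit_lda(
    tangent_coords: np.ndarray,
    labels: list[str] | np.ndarray,
    priors_mode: str = "equal",
    grouping_level: str = "group",
    shrinkage: float = 0.0,
) -> DiscriminantModel:
    """Fit the equal-covariance discriminant model.

    ``priors_mode`` is ``"equal"`` (default: reference collections are
    availability samples of taxa, so group frequencies carry no information
    about an unknown) or ``"proportional"`` (priors follow group sizes, the
    common statistical-package default).  ``shrinkage`` optionally pulls the
    pooled covariance toward its diagonal (0 = plain LDA).
    """
    x = np.asarray(tangent_coords, dtype=float)
    labels = list(labels)
    if x.ndim != 2 or x.shape[0] != len(labels):
        raise ValidationError("tangent_coords must be (n, p) matching labels")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite tangent coordinates")
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    y = np.asarray([groups.index(l) for l in labels])
    counts = np.bincount(y, minlength=len(groups))
    small = [g for g, c in zip(groups, counts) if c < 2]
    if small:
        raise ValidationError(f"groups with fewer than 2 specimens: {small}")

    if priors_mode == "equal":
        priors = np.full(len(groups), 1.0 / len(groups))
    elif priors_mode == "proportional":
        priors = counts / counts.sum()
    else:
        raise ValidationError(f"unknown priors_mode {priors_mode!r}")

    n, p = x.shape
    grand_mean = x.mean(axis=0)
    xc = x - grand_mean
    # principal directions of total variance; directions below the cutoff
    # are the null space that superimposition leaves behind
    _, sv, vt = np.linalg.svd(xc, full_matrices=False)
    var = sv**2
    keep = var / var.sum() > VARIANCE_CUTOFF if var.sum() > 0 else np.zeros(len(var), bool)
    if not np.any(keep):
        raise ValidationError("tangent coordinates have zero total variance")
    # cap at n - G so the pooled within-group covariance can reach full rank
    n_keep = min(int(keep.sum()), n - len(groups))
    if n_keep < 1:
        raise ValidationError("too few specimens for the number of groups")
    components = vt[:n_keep]
    z = xc @ components.T
    d = z.shape[1]

    group_means = np.stack([z[y == g].mean(axis=0) for g in range(len(groups))])
    within = np.zeros((d, d))
    for g in range(len(groups)):
        r = z[y == g] - group_means[g]
        within += r.T @ r
    pooled = _shrink(within / (n - len(groups)), shrinkage)

    try:
        chol = cho_factor(pooled)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "pooled within-group covariance is singular; add specimens or "
            "pass shrinkage > 0"
        ) from exc

    # canonical axes: generalized between/within eigenproblem
    zbar = (counts[:, None] * group_means).sum(axis=0) / n
    between = np.zeros((d, d))
    for g in range(len(groups)):
        diff = group_means[g] - zbar
        between += counts[g] * np.outer(diff, diff)
    between /= n
    evals, evecs = eigh(between, pooled)
    order = np.argsort(evals)[::-1]
    m = min(len(groups) - 1, d)
    axes = evecs[:, order[:m]]
    axis_eigenvalues = evals[order[:m]]
    # sign convention: largest-magnitude loading positive
    for j in range(axes.shape[1]):
        i = np.argmax(np.abs(axes[:, j]))
        if axes[i, j] < 0:
            axes[:, j] = -axes[:, j]

    return DiscriminantModel(
        grouping_level=grouping_level,
        groups=groups,
        priors=priors,
        n_per_group=counts,
        grand_mean=grand_mean,
        components=components,
        group_means=group_means,
        pooled_cov=pooled,
        axes=axes,
        axis_eigenvalues=axis_eigenvalues,
        shrinkage=shrinkage,
        _chol=chol,
    )


def mahalanobis_to_groups(model: DiscriminantModel, x: np.ndarray) -> np.ndarray:
    """Mahalanobis distance from ``x`` (tangent vector) to every group mean."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite input vector")
    z = model.reduce(x)
    diffs = model.group_means - z
    solved = cho_solve(model._chol, diffs.T)
    md2 = np.einsum("gd,dg->g", diffs, solved)
    return np.sqrt(np.maximum(md2, 0.0))


def posterior_probabilities(model: DiscriminantModel, x: np.ndarray) -> np.ndarray:
    """Posterior membership probabilities under the shared-covariance model."""
    md = mahalanobis_to_groups(model, x)
    scores = -0.5 * md**2 + np.log(model.priors)
    scores -= scores.max()
    w = np.exp(scores)
    return w / w.sum()


def classify(model: DiscriminantModel, x: np.ndarray) -> AssignmentResult:
    """Assign a tangent vector to the group with maximal posterior."""
    md = mahalanobis_to_groups(model, x)
    pp = posterior_probabilities(model, x)
    best = int(np.argmax(pp))
    ties = np.flatnonzero(pp == pp[best])
    if len(ties) > 1:
        warnings.warn(
            f"posterior tie between {[model.groups[i] for i in ties]}; "
            "assigning to the lexicographically first",
            RuntimeWarning,
            stacklevel=2,
        )
        best = int(ties.min())  # groups are sorted, so min index is lexicographic
    return AssignmentResult(
        level=model.grouping_level,
        groups=list(model.groups),
        posterior={g: float(p) for g, p in zip(model.groups, pp)},
        mahalanobis={g: float(m) for g, m in zip(model.groups, md)},
        assigned_group=model.groups[best],
    )


def loo_crossvalidate(
    tangent_coords: np.ndarray,
    labels: list[str] | np.ndarray,
    priors_mode: str = "equal",
    grouping_level: str = "group",
    shrinkage: float = 0.0,
) -> CrossValidationReport:
    """Leave-one-out cross-validated hit-ratios.

    For every specimen the model is refitted without it and the specimen is
    assigned by maximal posterior.  The alignment that produced the tangent
    coordinates is deliberately NOT recomputed per fold: refitting the
    superimposition would give every fold its own tangent space, making
    folds incomparable.  Every group needs n >= 3 so each fold keeps n >= 2.
    """
    x = np.asarray(tangent_coords, dtype=float)
    labels = list(labels)
    groups = sorted(set(labels))
    counts = {g: labels.count(g) for g in groups}
    small = [g for g, c in counts.items() if c < 3]
    if small:
        raise ValidationError(
            f"leave-one-out needs n >= 3 per group; too small: {small}"
        )
    n = x.shape[0]
    predicted: list[str] = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = fit_lda(
            x[mask],
            [l for j, l in enumerate(labels) if j != i],
            priors_mode=priors_mode,
            grouping_level=grouping_level,
            shrinkage=shrinkage,
        )
        predicted.append(classify(model, x[i]).assigned_group)
        mask[i] = True

    confusion = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    for true, pred in zip(labels, predicted):
        confusion.loc[true, pred] += 1
    correct = int(np.trace(confusion.values))
    per_group = {
        g: 100.0 * confusion.loc[g, g] / counts[g] for g in groups
    }
    return CrossValidationReport(
        grouping_level=grouping_level,
        per_group_hit_ratio=per_group,
        global_hit_ratio=100.0 * correct / n,
        n_misclassified=n - correct,
        n_total=n,
        confusion=confusion,
    )


def assign_unknown(
    model: DiscriminantModel,
    unknown: LandmarkConfiguration,
    reference: AlignedShapes,
) -> AssignmentResult:
    """Place an unknown specimen a posteriori and assign it to a group.

    The unknown is preshaped, rotated onto the reference consensus (the
    reference alignment is NOT recomputed), projected into the tangent
    space at that consensus, mapped through the model's reduction and
    scored.  This mirrors how a fossil is dropped into a discriminant space
    fitted to extant reference material.
    """
    if unknown.k != reference.k:
        raise SchemeError(
            f"unknown has {unknown.k} landmarks but the reference scheme has {reference.k}"
        )
    _, tangent = align_to_consensus(unknown, reference.consensus)
    return classify(model, tangent)


def hierarchical_assign(
    unknown: LandmarkConfiguration,
    stages: list[tuple[ShapeDataset, str]],
    priors_mode: str = "equal",
    shrinkage: float = 0.0,
) -> list[AssignmentResult]:
    """Run the assignment cascade over nested reference datasets.

    Each stage is a ``(dataset, grouping_level)`` pair and is analysed
    independently — superimposition, discriminant fit, a posteriori
    placement of the unknown — so a later stage is never gated on an
    earlier outcome; the caller chooses the nesting (e.g. all tribes, then
    one genus's subgenera).  Any stage failure aborts the chain with the
    stage index.
    """
    results: list[AssignmentResult] = []
    for i, (dataset, level) in enumerate(stages):
        try:
            aligned = gpa(dataset)
            grp = dataset.labels.groups_at(aligned.specimen_ids, level)
            model = fit_lda(
                aligned.tangent,
                grp,
                priors_mode=priors_mode,
                grouping_level=level,
                shrinkage=shrinkage,
            )
            results.append(assign_unknown(model, unknown, aligned))
        except Exception as exc:
            raise type(exc)(f"stage {i} ({level}): {exc}") from exc
    return results
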