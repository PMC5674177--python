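"""Synthetic landmark datasets with the structure the pipeline assumes.

Real reference collections of digitised wings cannot ship with the
package, so every stage is exercised on generated data instead: a fixed
wing-like template shape, hierarchically displaced group mean shapes
(nested taxa), isotropic Gaussian landmark noise within groups, and a
random similarity nuisance transform (rotation, translation, scale) per
specimen — the part superimposition must remove.  Isotropic noise is the
simplest within-group model consistent with the classifier's shared-
covariance assumption.

Everything is reproducible: the group means are drawn once from the spec's
seed, so the "taxa" are stable fixtures, and two runs from the same spec
are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .tps import LandmarkConfiguration, ShapeDataset, TaxonLabels, mirror as _mirror
from .procrustes import preshape


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study design.

    ``hierarchy`` lists (level name, branching factor) pairs from coarsest
    to finest; e.g. ``(("tribe", 3), ("subgenus", 4))`` gives 3 tribes of 4
    subgenera each (12 terminal groups).  ``within_sd`` is the landmark
    noise standard deviation as a fraction of centroid size; ``separation``
    is the magnitude of each level's mean-shape displacement as a multiple
    of ``within_sd``.  Nuisance ranges control the per-specimen similarity
    transform that carries no shape information.
    """

    k: int = 18
    hierarchy: tuple[tuple[str, int], ...] = (("tribe", 3), ("subgenus", 4))
    n_per_group: int = 25
    within_sd: float = 0.01
    separation: float = 10.0
    level_scales: tuple[float, ...] | None = None
    rotation_range: tuple[float, float] = (0.0, 2.0 * np.pi)
    translation_range: float = 1.0
    log_scale_range: tuple[float, float] = (-0.7, 0.7)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "hierarchy", tuple((str(n), int(c)) for n, c in self.hierarchy)
        )
        if self.level_scales is not None:
            object.__setattr__(self, "level_scales", tuple(float(s) for s in self.level_scales))

    def validate(self) -> None:
        if self.k < 3:
            raise ValidationError("k must be >= 3")
        if self.within_sd <= 0:
            raise ValidationError("within_sd must be > 0")
        if self.separation < 0:
            raise ValidationError("separation must be >= 0")
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if not self.hierarchy:
            raise ValidationError("hierarchy must have at least one level")
        if self.level_scales is not None and len(self.level_scales) != len(self.hierarchy):
            raise ValidationError("level_scales must match hierarchy length")

    @property
    def levels(self) -> list[str]:
        return [name for name, _ in self.hierarchy]

    def scales(self) -> list[float]:
        return list(self.level_scales) if self.level_scales is not None else [1.0] * len(
            self.hierarchy
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        raw = json.loads(text)
        if "hierarchy" in raw:
            raw["hierarchy"] = tuple(tuple(pair) for pair in raw["hierarchy"])
        for key in ("rotation_range", "log_scale_range", "level_scales"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def template_wing(k: int = 18) -> LandmarkConfiguration:
    """Deterministic wing-like template configuration.

    Landmarks sit on an elongated closed outline with asymmetric Fourier
    bumps (a loose caricature of a forewing margin and its vein
    intersections).  The shape is deliberately scalene and mirror-
    asymmetric so that reflection is detectable downstream; the same ``k``
    always yields the same coordinates.
    """
    if k < 3:
        raise ValidationError("k must be >= 3")
    t = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    # fixed low-order harmonics: no symmetry axis, elongated like a wing
    r = 1.0 + 0.35 * np.sin(t) + 0.22 * np.cos(2.0 * t + 0.7) + 0.15 * np.sin(3.0 * t + 1.3)
    x = 2.4 * r * np.cos(t)
    y = 0.9 * r * np.sin(t + 0.25 * np.sin(t))
    coords = np.column_stack([x, y])
    return LandmarkConfiguration(specimen_id="template", coords=coords)


@dataclass
class GroupMeans:
    """Per-terminal-group mean shapes plus their hierarchical labels."""

    means: dict[str, np.ndarray]                 # terminal group -> (k, 2), unit size
    labels: dict[str, dict[str, str]] = field(default_factory=dict)  # terminal -> level -> name

    @property
    def groups(self) -> list[str]:
        return list(self.means)


def make_group_means(spec: SyntheticSpec) -> GroupMeans:
    """Draw the hierarchy of group mean shapes from the spec's seed.

    Starting from the unit-size template, each hierarchy level adds an
    independent centred random displacement field of magnitude
    ``separation * within_sd * level_scale`` to its subtree, so groups
    under one parent share the parent's displacement.  Deterministic given
    the spec.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 0])
    base, _ = preshape(template_wing(spec.k))
    scales = spec.scales()
    out = GroupMeans({})
    counters = {name: 0 for name, _ in spec.hierarchy}

    def descend(level_idx: int, parent_mean: np.ndarray, path: dict[str, str]) -> None:
        name, branching = spec.hierarchy[level_idx]
        magnitude = spec.separation * spec.within_sd * scales[level_idx]
        for _ in range(branching):
            counters[name] += 1
            node = f"{name}{counters[name]}"
            delta = rng.standard_normal((spec.k, 2))
            delta -= delta.mean(axis=0)
            norm = np.linalg.norm(delta)
            delta = delta * (magnitude / norm) if norm > 0 else delta
            mean = parent_mean + delta
            node_path = {**path, name: node}
            if level_idx + 1 == len(spec.hierarchy):
                unit, _ = preshape(mean)
                out.means[node] = unit
                out.labels[node] = node_path
            else:
                descend(level_idx + 1, mean, node_path)

    descend(0, base, {})
    return out


def _nuisance_transform(coords: np.ndarray, rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    theta = rng.uniform(*spec.rotation_range)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, s], [-s, c]])
    scale = float(np.exp(rng.uniform(*spec.log_scale_range)))
    shift = rng.uniform(-spec.translation_range, spec.translation_range, size=2)
    return scale * coords @ rot + shift


def _draw_specimen(
    mean: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    # mean has unit centroid size, so within_sd is directly the fraction
    shape = mean + rng.normal(0.0, spec.within_sd, size=mean.shape)
    return _nuisance_transform(shape, rng, spec)


def generate_dataset(spec: SyntheticSpec) -> ShapeDataset:
    """Generate a labelled dataset under the spec's study design.

    Each specimen is its terminal group's mean shape plus i.i.d. Gaussian
    landmark noise, pushed through a random similarity nuisance transform;
    labels are attached at every hierarchy level.
    """
    spec.validate()
    gm = make_group_means(spec)
    rng = np.random.default_rng([spec.seed, 1])
    configs: list[LandmarkConfiguration] = []
    mapping: dict[str, dict[str, str | None]] = {}
    for group in gm.groups:
        for j in range(spec.n_per_group):
            sid = f"{group}_{j + 1:03d}"
            coords = _draw_specimen(gm.means[group], spec, rng)
            configs.append(LandmarkConfiguration(specimen_id=sid, coords=coords))
            mapping[sid] = dict(gm.labels[group])
    ds = ShapeDataset(configs, TaxonLabels(mapping), scheme_name=f"synthetic_k{spec.k}")
    ds.validate()
    return ds


def make_unknown(
    spec: SyntheticSpec,
    group: str,
    mirrored: bool = False,
    shear: float = 0.0,
    seed: int = 0,
    specimen_id: str = "unknown",
) -> LandmarkConfiguration:
    """Draw one unlabelled specimen from a terminal group's distribution.

    Stands in for a fossil: optionally reflected (as a right wing would be
    against left-wing references) and optionally distorted by an affine
    shear of the stated factor, a crude model of taphonomic compression.
    ``seed`` varies the draw without touching the group means.
    """
    spec.validate()
    gm = make_group_means(spec)
    if group not in gm.means:
        raise ValidationError(
            f"unknown terminal group {group!r}; available: {gm.groups}"
        )
    rng = np.random.default_rng([spec.seed, 2, int(seed)])
    shape = gm.means[group] + rng.normal(0.0, spec.within_sd, size=(spec.k, 2))
    if shear:
        shape = shape @ np.array([[1.0, 0.0], [shear, 1.0]])  # x' = x + shear*y
    coords = _nuisance_transform(shape, rng, spec)
    config = LandmarkConfiguration(specimen_id=specimen_id, coords=coords)
    if mirrored:
        config = _mirror(config)
    return config
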