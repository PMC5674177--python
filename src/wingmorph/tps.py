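"""Landmark data containers and TPS-format input/output.

The TPS dialect accepted here is the common 2-D flavour emitted by the
tps-UTIL/tps-DIG family of digitising tools: each record starts with an
``LM=<count>`` line followed by exactly that many whitespace-separated
``x y`` coordinate lines, then optional ``ID=``, ``IMAGE=`` and ``SCALE=``
lines.  Three-dimensional records (``LM3=``) are rejected: wing venation is
a planar structure and the whole downstream pipeline is strictly 2-D.

Taxon labels are deliberately kept out of the TPS file (the format has no
standard label field) and live in a companion CSV with one row per specimen
and one column per taxonomic level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemeError, TPSParseError, ValidationError

#: Column order used for label CSVs; extra levels are appended after these.
CANONICAL_LEVELS = (
    "family",
    "subfamily",
    "tribe",
    "genus",
    "subgenus",
    "species",
)

#: Named landmark scheme for the 18-landmark bee forewing convention:
#: vein intersections and cell corners of the three submarginal cells,
#: marginal cell and adjacent venation of a left forewing.  Landmark order
#: is positional and encodes homology; it is never re-sorted.
BEE_FOREWING_18 = "bee_forewing_18"


@dataclass
class LandmarkConfiguration:
    """One specimen's 2-D landmark configuration.

    Parameters
    ----------
    specimen_id:
        Unique text identifier.
    coords:
        ``(k, 2)`` array of Cartesian landmark coordinates in arbitrary but
        internally consistent units.  Order is positional (homology).
    scale:
        Optional physical units-per-coordinate factor (TPS ``SCALE=``).
    mirrored:
        Whether the coordinates were reflected (x negated) before analysis;
        toggled by :func:`mirror`.
    """

    specimen_id: str
    coords: np.ndarray
    scale: float | None = None
    mirrored: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError(
                f"{self.specimen_id!r}: coords must be (k, 2), got {self.coords.shape}"
            )

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def validate(self) -> None:
        if self.k < 3:
            raise ValidationError(f"{self.specimen_id!r}: need k >= 3 landmarks, got {self.k}")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"{self.specimen_id!r}: non-finite coordinates")
        # coincident landmarks break homology and degenerate the shape metric
        diffs = self.coords[:, None, :] - self.coords[None, :, :]
        dist2 = np.einsum("ijk,ijk->ij", diffs, diffs)
        iu = np.triu_indices(self.k, 1)
        coincident = dist2[iu] == 0.0
        if np.any(coincident):
            i, j = iu[0][coincident][0], iu[1][coincident][0]
            raise ValidationError(
                f"{self.specimen_id!r}: landmarks {i} and {j} are coincident"
            )


@dataclass
class TaxonLabels:
    """Per-specimen mapping to named hierarchical taxonomic levels.

    ``mapping[specimen_id][level]`` is a group name or ``None``/missing for
    an unknown at that level (e.g. a fossil whose subgenus is to be
    predicted).
    """

    mapping: dict[str, dict[str, str | None]] = field(default_factory=dict)

    @property
    def levels(self) -> list[str]:
        seen: dict[str, None] = {}
        for row in self.mapping.values():
            for level in row:
                seen.setdefault(level)
        return list(seen)

    def group_of(self, specimen_id: str, level: str) -> str | None:
        return self.mapping.get(specimen_id, {}).get(level)

    def groups_at(self, specimen_ids: Sequence[str], level: str) -> list[str]:
        """Labels for ``specimen_ids`` at ``level``; every one must be present."""
        out = []
        for sid in specimen_ids:
            g = self.group_of(sid, level)
            if g is None:
                raise ValidationError(f"specimen {sid!r} has no label at level {level!r}")
            out.append(g)
        return out

    @classmethod
    def from_csv(cls, path: str | Path) -> "TaxonLabels":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if "specimen_id" not in df.columns:
            raise ValidationError(f"{path}: label table must have a 'specimen_id' column")
        mapping: dict[str, dict[str, str | None]] = {}
        for _, row in df.iterrows():
            sid = row["specimen_id"]
            mapping[sid] = {
                level: (row[level] if row[level] != "" else None)
                for level in df.columns
                if level != "specimen_id"
            }
        return cls(mapping)

    def to_csv(self, path: str | Path) -> None:
        levels = self.levels
        ordered = [l for l in CANONICAL_LEVELS if l in levels]
        ordered += [l for l in levels if l not in ordered]
        rows = [
            {"specimen_id": sid, **{l: (row.get(l) or "") for l in ordered}}
            for sid, row in self.mapping.items()
        ]
        pd.DataFrame(rows, columns=["specimen_id", *ordered]).to_csv(path, index=False)


@dataclass
class ShapeDataset:
    """A collection of configurations sharing one landmark scheme."""

    configurations: list[LandmarkConfiguration]
    labels: TaxonLabels = field(default_factory=TaxonLabels)
    scheme_name: str = ""

    @property
    def n(self) -> int:
        return len(self.configurations)

    @property
    def k(self) -> int:
        if not self.configurations:
            raise ValidationError("empty dataset has no landmark count")
        return self.configurations[0].k

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def coords_array(self) -> np.ndarray:
        """Stack all configurations into an ``(n, k, 2)`` array."""
        return np.stack([c.coords for c in self.configurations])

    def validate(self) -> None:
        ks = {c.k for c in self.configurations}
        if len(ks) > 1:
            raise SchemeError(f"inconsistent landmark counts across records: {sorted(ks)}")
        ids = self.specimen_ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate specimen ids: {dupes}")
        for c in self.configurations:
            c.validate()

    def subset(self, specimen_ids: Iterable[str]) -> "ShapeDataset":
        wanted = set(specimen_ids)
        return ShapeDataset(
            [c for c in self.configurations if c.specimen_id in wanted],
            self.labels,
            self.scheme_name,
        )


_FLOAT_PAIR = re.compile(r"^\s*([-+0-9.eE]+)\s+([-+0-9.eE]+)\s*$")


def read_tps(path: str | Path, apply_scale: bool = False) -> ShapeDataset:
    """Read a TPS file into a :class:`ShapeDataset`.

    ``SCALE=`` values are recorded on each configuration; they multiply the
    coordinates only when ``apply_scale`` is true (shape analysis discards
    scale anyway, but centroid sizes become physical units when applied).
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        upper = line.upper()
        if upper.startswith("LM3="):
            raise SchemeError(
                f"{path.name}, record {record + 1}: 3-D landmark records (LM3=) "
                "are not supported; this pipeline is strictly 2-D"
            )
        if not upper.startswith("LM="):
            raise TPSParseError(
                f"{path.name}, line {i + 1}: expected an LM= record header, got {line!r}"
            )
        record += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(
                f"{path.name}, record {record}: malformed landmark count {line!r}"
            ) from exc
        i += 1
        coords = []
        while len(coords) < k:
            if i >= len(lines):
                raise TPSParseError(
                    f"{path.name}, record {record}: declares LM={k} but file ends "
                    f"after {len(coords)} coordinate lines"
                )
            m = _FLOAT_PAIR.match(lines[i])
            if m is None:
                raise TPSParseError(
                    f"{path.name}, record {record}: declares LM={k} but only "
                    f"{len(coords)} coordinate lines precede {lines[i].strip()!r}"
                )
            coords.append((float(m.group(1)), float(m.group(2))))
            i += 1
        specimen_id = None
        scale = None
        while i < len(lines):
            line = lines[i].strip()
            if not line:
                i += 1
                continue
            if line.upper().startswith(("LM=", "LM3=")):
                break
            key, _, value = line.partition("=")
            key = key.strip().upper()
            if key == "ID":
                specimen_id = value.strip()
            elif key == "SCALE":
                scale = float(value)
            elif key in ("IMAGE", "COMMENT", "CURVES", "POINTS", "VARIABLES"):
                pass  # carried by the format but unused here
            else:
                raise TPSParseError(
                    f"{path.name}, record {record}: unrecognised line {line!r}"
                )
            i += 1
        arr = np.asarray(coords, dtype=float)
        if apply_scale and scale is not None:
            arr = arr * scale
        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen_id if specimen_id is not None else f"specimen_{record}",
                coords=arr,
                scale=scale,
            )
        )
    ds = ShapeDataset(configs)
    ds.validate()
    return ds


def write_tps(dataset: ShapeDataset, path: str | Path) -> None:
    """Write a dataset as TPS; ``read_tps(write_tps(d))`` is coordinate-exact.

    Coordinates are serialised with :func:`repr`, the shortest decimal string
    that round-trips the IEEE double exactly.
    """
    out: list[str] = []
    for c in dataset.configurations:
        out.append(f"LM={c.k}")
        for x, y in c.coords:
            out.append(f"{float(x)!r} {float(y)!r}")
        out.append(f"ID={c.specimen_id}")
        if c.scale is not None:
            out.append(f"SCALE={float(c.scale)!r}")
    text = "\n".join(out)
    if text:
        text += "\n"
    Path(path).write_text(text, encoding="utf-8")


def mirror(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Reflect a configuration about the y axis (negate x), toggling ``mirrored``.

    Needed when reference wings are digitised from one side (left forewings)
    but a specimen — typically a fossil — preserves the other: reflection is
    a genuine shape change that superimposition does not remove.
    Applying twice returns the original.
    """
    return replace(
        config,
        coords=config.coords * np.array([-1.0, 1.0]),
        mirrored=not config.mirrored,
    )


def load_dataset(
    tps_path: str | Path,
    labels_path: str | Path | None = None,
    apply_scale: bool = False,
    scheme_name: str = "",
) -> ShapeDataset:
    """Read a TPS file and, optionally, its companion label CSV."""
    ds = read_tps(tps_path, apply_scale=apply_scale)
    if labels_path is not None:
        ds.labels = TaxonLabels.from_csv(labels_path)
    ds.scheme_name = scheme_name
    return ds
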