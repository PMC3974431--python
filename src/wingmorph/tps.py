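"""Reading, writing and symmetrizing landmark data in the TPS text format.

The TPS dialect handled here is the one produced by the tpsUtil/tpsDig
family of digitizing tools: blocks introduced by ``LM=<k>`` followed by
``k`` coordinate lines ("x y"), then optional ``ID=``, ``IMAGE=`` and
``SCALE=`` keywords.  ``CURVES=``/``POINTS=`` semilandmark blocks are
skipped with a warning — this pipeline works on fixed landmarks only.

Group labels (e.g. subfamily) are not a TPS concept; they travel in a
sidecar CSV with header ``specimen_id,group,side``.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkConfiguration",
    "LandmarkDataset",
    "TPSFormatError",
    "TPSParseError",
    "read_tps",
    "write_tps",
    "reflect_configuration",
    "read_metadata",
    "attach_metadata",
    "write_metadata",
]

SIDES = ("left", "right", "unknown")


class TPSParseError(ValueError):
    """A line of a TPS file could not be parsed."""


class TPSFormatError(ValueError):
    """The TPS file is structurally invalid (e.g. mixed landmark counts)."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's planar landmark configuration.

    ``landmarks`` is a (k, 2) float array in digitizing order; that order
    encodes the homology correspondence across specimens and is never
    re-sorted.  ``scale`` is the physical unit per coordinate step as
    recorded by the digitizer (already applied to the coordinates on read).
    """

    specimen_id: str
    landmarks: np.ndarray
    side: str = "unknown"
    group_label: str | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        lm = np.asarray(self.landmarks, dtype=float)
        if lm.ndim != 2 or lm.shape[1] != 2:
            raise ValueError(
                f"{self.specimen_id}: landmarks must be a (k, 2) array, got {lm.shape}"
            )
        if lm.shape[0] < 3:
            raise ValueError(f"{self.specimen_id}: need at least 3 landmarks, got {lm.shape[0]}")
        if not np.all(np.isfinite(lm)):
            raise ValueError(f"{self.specimen_id}: non-finite landmark coordinates")
        centered = lm - lm.mean(axis=0)
        if float(np.sum(centered**2)) == 0.0:
            raise ValueError(f"{self.specimen_id}: all landmarks coincide (zero centroid size)")
        if self.side not in SIDES:
            raise ValueError(f"{self.specimen_id}: side must be one of {SIDES}, got {self.side!r}")
        if self.scale is not None and not self.scale > 0:
            raise ValueError(f"{self.specimen_id}: scale must be positive")
        lm.setflags(write=False)
        object.__setattr__(self, "landmarks", lm)

    @property
    def k(self) -> int:
        return self.landmarks.shape[0]

    def with_group(self, group_label: str | None) -> "LandmarkConfiguration":
        return replace(self, group_label=group_label)


@dataclass(frozen=True)
class LandmarkDataset:
    """An ordered collection of configurations sharing one landmark scheme."""

    configurations: tuple[LandmarkConfiguration, ...]

    def __post_init__(self) -> None:
        configs = tuple(self.configurations)
        if not configs:
            raise ValueError("dataset must contain at least one configuration")
        k = configs[0].k
        for c in configs:
            if c.k != k:
                raise TPSFormatError(
                    f"configuration {c.specimen_id!r} has {c.k} landmarks, expected {k}"
                )
        ids = [c.specimen_id for c in configs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen_ids in dataset: {dup}")
        object.__setattr__(self, "configurations", configs)

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    def __getitem__(self, i: int) -> LandmarkConfiguration:
        return self.configurations[i]

    @property
    def k(self) -> int:
        return self.configurations[0].k

    @property
    def group_labels(self) -> tuple[str, ...]:
        """Distinct labels present, in sorted order (unlabelled specimens excluded)."""
        return tuple(sorted({c.group_label for c in self if c.group_label is not None}))

    @property
    def specimen_ids(self) -> tuple[str, ...]:
        return tuple(c.specimen_id for c in self)

    def coordinates(self) -> np.ndarray:
        """Stacked (n, k, 2) coordinate array in dataset order."""
        return np.stack([c.landmarks for c in self])

    def labels(self) -> tuple[str | None, ...]:
        return tuple(c.group_label for c in self)

    def subset(self, predicate) -> "LandmarkDataset":
        kept = tuple(c for c in self if predicate(c))
        if not kept:
            raise ValueError("subset is empty")
        return LandmarkDataset(kept)

    def restrict_to_groups(self, groups: Iterable[str]) -> "LandmarkDataset":
        wanted = set(groups)
        return self.subset(lambda c: c.group_label in wanted)


# ---------------------------------------------------------------------------
# TPS parsing


def _is_missing(x: float, y: float) -> bool:
    # tpsDig records a landmark the digitizer could not place as "-1 -1";
    # NaN likewise marks an absent point.  Ordinary negative coordinates are
    # legal (centering and reflection produce them routinely).
    return (x == -1.0 and y == -1.0) or math.isnan(x) or math.isnan(y)


def read_tps(path: str | Path) -> LandmarkDataset:
    """Parse a TPS file into a :class:`LandmarkDataset`.

    ``SCALE=`` factors are applied to the coordinates at ingest (tpsDig
    semantics); superimposition removes size, so this only affects reported
    centroid sizes.  ``ID=`` is preferred over ``IMAGE=`` for the specimen
    identifier; a block with neither gets a positional id.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()

    configs: list[LandmarkConfiguration] = []
    i = 0
    block_no = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        upper = line.upper()
        if not upper.startswith("LM="):
            raise TPSParseError(f"{path}:{i + 1}: expected 'LM=' to open a block, got {line!r}")
        block_no += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"{path}:{i + 1}: malformed LM= line {line!r}") from exc
        i += 1
        coords = np.empty((k, 2), dtype=float)
        for j in range(k):
            if i >= n_lines:
                raise TPSParseError(f"{path}: block {block_no} truncated after {j} coordinates")
            parts = lines[i].split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"{path}:{i + 1}: malformed coordinate line {lines[i]!r} "
                    f"(block {block_no}, landmark {j + 1})"
                )
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise TPSParseError(
                    f"{path}:{i + 1}: malformed coordinate line {lines[i]!r}"
                ) from exc
            if _is_missing(x, y):
                raise TPSFormatError(
                    f"{path}:{i + 1}: missing landmark (block {block_no}); "
                    "this pipeline requires complete configurations"
                )
            coords[j] = (x, y)
            i += 1

        spec_id: str | None = None
        image_id: str | None = None
        scale: float | None = None
        while i < n_lines:
            line = lines[i].strip()
            if not line:
                i += 1
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                break
            if upper.startswith("ID="):
                spec_id = line.split("=", 1)[1].strip()
            elif upper.startswith("IMAGE="):
                image_id = line.split("=", 1)[1].strip()
            elif upper.startswith("SCALE="):
                try:
                    scale = float(line.split("=", 1)[1])
                except ValueError as exc:
                    raise TPSParseError(f"{path}:{i + 1}: malformed SCALE= line") from exc
            elif upper.startswith("CURVES="):
                i = _skip_curves(lines, i, path)
                continue
            else:
                raise TPSParseError(f"{path}:{i + 1}: unrecognized line {line!r}")
            i += 1

        if spec_id is None:
            spec_id = image_id if image_id is not None else f"specimen_{block_no}"
        if scale is not None:
            coords = coords * scale
        configs.append(LandmarkConfiguration(specimen_id=spec_id, landmarks=coords, scale=scale))

    if not configs:
        raise TPSFormatError(f"{path}: no LM= blocks found")
    return LandmarkDataset(tuple(configs))


def _skip_curves(lines: list[str], i: int, path: Path) -> int:
    """Skip a CURVES=/POINTS= semilandmark section, returning the next index."""
    n_curves = int(lines[i].strip().split("=", 1)[1])
    logger.warning("%s:%d: skipping CURVES=%d block (semilandmarks unsupported)", path, i + 1, n_curves)
    i += 1
    for _ in range(n_curves):
        if i >= len(lines) or not lines[i].strip().upper().startswith("POINTS="):
            raise TPSParseError(f"{path}:{i + 1}: expected POINTS= inside CURVES block")
        n_pts = int(lines[i].strip().split("=", 1)[1])
        i += 1 + n_pts
    return i


def _fmt(x: float) -> str:
    # shortest decimal string that round-trips the double
    return np.format_float_positional(x, unique=True, trim="0")


def write_tps(dataset: LandmarkDataset, path: str | Path) -> None:
    """Write a dataset as TPS blocks, one per configuration, order preserved.

    When a configuration carries a ``scale``, coordinates are written divided
    by it (undoing the multiplication applied on read) so that read → write →
    read is the identity.
    """
    if len(dataset) == 0:  # pragma: no cover - dataset invariant forbids this
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    out: list[str] = []
    for c in dataset:
        out.append(f"LM={c.k}")
        coords = c.landmarks if c.scale is None else c.landmarks / c.scale
        for x, y in coords:
            out.append(f"{_fmt(x)} {_fmt(y)}")
        out.append(f"ID={c.specimen_id}")
        if c.scale is not None:
            out.append(f"SCALE={_fmt(c.scale)}")
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Reflection (wing symmetrization)


def reflect_configuration(
    config: LandmarkConfiguration,
    landmark_map: Sequence[int] | None = None,
) -> LandmarkConfiguration:
    """Mirror a configuration about the vertical axis through its centroid.

    Used to symmetrize left wings so they are comparable with right wings:
    x-coordinates are negated about the centroid and the side flag flips.
    Landmark order is unchanged; pass ``landmark_map`` (a permutation of
    ``range(k)``) if the digitizing protocol requires re-indexing after
    reflection.
    """
    lm = config.landmarks.copy()
    cx = lm[:, 0].mean()
    lm[:, 0] = 2.0 * cx - lm[:, 0]
    if landmark_map is not None:
        idx = np.asarray(landmark_map)
        if sorted(idx.tolist()) != list(range(config.k)):
            raise ValueError("landmark_map must be a permutation of range(k)")
        lm = lm[idx]
    side = {"left": "right", "right": "left", "unknown": "unknown"}[config.side]
    return replace(config, landmarks=lm, side=side)


# ---------------------------------------------------------------------------
# Sidecar metadata CSV


def read_metadata(path: str | Path) -> dict[str, tuple[str | None, str]]:
    """Read a ``specimen_id,group,side`` CSV into ``{id: (group, side)}``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata CSV not found: {path}")
    meta: dict[str, tuple[str | None, str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"specimen_id", "group", "side"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: metadata CSV must have columns {sorted(required)}")
        for row in reader:
            group = row["group"].strip() or None
            side = row["side"].strip() or "unknown"
            meta[row["specimen_id"].strip()] = (group, side)
    return meta


def attach_metadata(
    dataset: LandmarkDataset, meta: dict[str, tuple[str | None, str]]
) -> LandmarkDataset:
    """Return a dataset with group labels and sides filled in from metadata."""
    out = []
    for c in dataset:
        if c.specimen_id in meta:
            group, side = meta[c.specimen_id]
            out.append(replace(c, group_label=group, side=side))
        else:
            out.append(c)
    return LandmarkDataset(tuple(out))


def write_metadata(dataset: LandmarkDataset, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["specimen_id", "group", "side"])
        for c in dataset:
            writer.writerow([c.specimen_id, c.group_label or "", c.side])
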