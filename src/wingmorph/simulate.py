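"""Synthetic landmark datasets with the structure the pipeline assumes.

Real digitized wings differ by (i) true shape differences between taxa,
(ii) individual shape variation within a taxon, (iii) the nuisance of where
and how large the wing sat under the camera, and (iv) digitization error
when the same wing is clicked more than once.  The generator reproduces
exactly these four ingredients:

* a fixed template shape (a jittered convex arc standing in for a wing's
  vein-intersection scheme);
* per-group mean shapes: the template plus a random displacement field of
  prescribed norm (``effect_size``), projected orthogonal to the template's
  similarity-transform directions so none of the effect is absorbed by
  superimposition;
* i.i.d. isotropic Gaussian landmark noise (``noise_sd``) per specimen, then
  a random similarity transform drawn from the nuisance ranges;
* replicate digitizations of one underlying specimen perturbed by a separate
  ``digitization_sd``.

All quantities are in units of the template's (unit) centroid size.  Every
draw is reproducible from the seed, and each group consumes an independent
spawned random stream, so adding a group never perturbs earlier groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import subfamily_sizes
from .tps import LandmarkConfiguration, LandmarkDataset

__all__ = ["SyntheticSpec", "make_template", "simulate_dataset", "simulate_replicates"]


def _default_groups() -> tuple[tuple[str, int], ...]:
    return tuple(subfamily_sizes().items())


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults mirror the reference bee study: 18 landmarks and the 15
    subfamily sample sizes (totals 360).  ``effect_size`` is the norm of each
    group's mean-shape displacement and ``noise_sd`` the per-landmark,
    per-axis within-group standard deviation, both relative to unit centroid
    size; the defaults (0.05 and 0.01, i.e. 1% landmark noise) give the
    strongly separated, small-variation regime the reference analysis
    operates in.  ``digitization_sd`` (0.005) makes re-clicking a wing about
    half as variable as true individual variation.
    """

    k: int = 18
    groups: tuple[tuple[str, int], ...] = field(default_factory=_default_groups)
    effect_size: float = 0.05
    noise_sd: float = 0.01
    rotation_range: tuple[float, float] = (-np.pi, np.pi)
    translation_range: tuple[float, float] = (-1.0, 1.0)
    log_scale_range: tuple[float, float] = (-0.35, 0.35)
    digitization_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("k must be at least 3")
        if self.effect_size < 0 or self.noise_sd < 0 or self.digitization_sd < 0:
            raise ValueError("effect_size, noise_sd and digitization_sd must be >= 0")
        if not self.groups:
            raise ValueError("at least one group is required")
        for label, n in self.groups:
            if n < 1:
                raise ValueError(f"group {label!r} must have at least 1 specimen")
        labels = [g for g, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")

    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.groups)


def make_template(k: int, seed: int) -> LandmarkConfiguration:
    """A reproducible non-degenerate planar template with unit centroid size.

    Landmarks sit on a flattened elliptical arc (wing-outline-like) with
    seeded jitter, centred and scaled to centroid size 1.
    """
    if k < 3:
        raise ValueError("k must be at least 3")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    t = np.linspace(0.1 * np.pi, 0.9 * np.pi, k)
    pts = np.column_stack([1.8 * np.cos(t), 0.7 * np.sin(t)])
    pts += rng.normal(scale=0.08, size=(k, 2))
    pts -= pts.mean(axis=0)
    pts /= np.linalg.norm(pts)
    return LandmarkConfiguration(specimen_id=f"template_k{k}", landmarks=pts)


def _similarity_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis (4, 2k) of the similarity-transform directions at a shape."""
    k = template.shape[0]
    x, y = template[:, 0], template[:, 1]
    tx = np.column_stack([np.ones(k), np.zeros(k)]).reshape(-1)
    ty = np.column_stack([np.zeros(k), np.ones(k)]).reshape(-1)
    scale = template.reshape(-1)
    rot = np.column_stack([-y, x]).reshape(-1)
    basis, _ = np.linalg.qr(np.stack([tx, ty, scale, rot]).T)
    return basis.T


def _group_stream(spec: SyntheticSpec, index: int) -> np.random.SeedSequence:
    # keyed child stream per group: adding groups never perturbs earlier draws
    return np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, index))


def _group_means(spec: SyntheticSpec) -> dict[str, np.ndarray]:
    """Deterministic mean shape per group: template + pure-shape displacement."""
    template = make_template(spec.k, spec.seed).landmarks
    basis = _similarity_basis(template)
    means: dict[str, np.ndarray] = {}
    for i, (label, _n) in enumerate(spec.groups):
        rng = np.random.default_rng(_group_stream(spec, i))
        d = rng.normal(size=2 * spec.k)
        d -= basis.T @ (basis @ d)  # remove translation/scale/rotation components
        norm = np.linalg.norm(d)
        d = spec.effect_size * d / norm if norm > 0 else d
        means[label] = template + d.reshape(spec.k, 2)
    return means


def _nuisance(rng: np.random.Generator, spec: SyntheticSpec, coords: np.ndarray) -> np.ndarray:
    """Apply a random similarity transform drawn from the spec's nuisance ranges."""
    theta = rng.uniform(*spec.rotation_range)
    s = np.exp(rng.uniform(*spec.log_scale_range))
    shift = rng.uniform(*spec.translation_range, size=2)
    rot = np.array([[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]])
    return s * coords @ rot + shift


def simulate_dataset(spec: SyntheticSpec) -> LandmarkDataset:
    """Draw a labelled multi-group landmark dataset from the spec's model."""
    means = _group_means(spec)
    configs: list[LandmarkConfiguration] = []
    for i, (label, n) in enumerate(spec.groups):
        rng = np.random.default_rng(_group_stream(spec, i))
        rng.normal(size=2 * spec.k)  # skip the displacement draw used by _group_means
        for i in range(n):
            coords = means[label] + rng.normal(scale=spec.noise_sd, size=(spec.k, 2))
            coords = _nuisance(rng, spec, coords)
            configs.append(
                LandmarkConfiguration(
                    specimen_id=f"{label}_{i + 1:03d}",
                    landmarks=coords,
                    side="right",
                    group_label=label,
                )
            )
    return LandmarkDataset(tuple(configs))


def simulate_replicates(
    spec: SyntheticSpec, group_label: str, n_replicates: int, trial: int = 0
) -> list[LandmarkConfiguration]:
    """Replicate digitizations of one unseen specimen from a given group.

    One true underlying wing is drawn from the group's shape model; each
    replicate is that wing re-measured with independent digitization noise
    and its own nuisance transform — the synthetic analogue of several
    experimenters clicking the same fossil.  ``trial`` selects an
    independent unknown specimen without touching the reference draws.
    """
    if group_label not in spec.group_labels:
        raise ValueError(f"unknown group {group_label!r}; spec has {spec.group_labels}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    means = _group_means(spec)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(2, trial)))
    true = means[group_label] + rng.normal(scale=spec.noise_sd, size=(spec.k, 2))
    out = []
    for j in range(n_replicates):
        coords = true + rng.normal(scale=spec.digitization_sd, size=(spec.k, 2))
        coords = _nuisance(rng, spec, coords)
        out.append(
            LandmarkConfiguration(
                specimen_id=f"{group_label}_unknown_r{j + 1}",
                landmarks=coords,
                side="right",  # replicates are already in symmetrized (right) orientation
                group_label=None,
            )
        )
    return out
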