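"""End-to-end pipeline: superimpose, check adequacy, ordinate, cross-validate,
and optionally assign unknowns, writing a CSV/TPS report bundle plus a run
manifest that records every decision knob."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assign as _assign
from .stats import hit_ratios, lda_fit, loo_crossvalidate, pca_fit
from .superimpose import gpa, project_to_tangent, tangent_adequacy
from .tps import LandmarkDataset, attach_metadata, read_metadata, read_tps, write_tps

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Fully serializable description of one pipeline run.

    An identical config applied to identical inputs reproduces identical
    outputs (all randomness is seeded; all algorithms are deterministic).
    """

    tps_path: str
    metadata_path: str
    unknown_tps_path: str | None = None
    replicate_group_by_prefix: bool = True   # replicate ids 'X_r1' collapse to unknown 'X'
    priors: str = "proportional"             # 'proportional' | 'equal'
    n_components: int | str = "auto"
    mode: str = "joint"                      # 'joint' | 'opa'
    out_dir: str = "wingmorph_out"
    seed: int = 0
    verbose: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _replicate_map(ids: list[str]) -> dict[str, str]:
    out = {}
    for i in ids:
        stem, sep, tail = i.rpartition("_r")
        if sep and tail.isdigit():
            out[i] = stem
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle into ``config.out_dir``.

    Returns a dict of in-memory results (gpa, adequacy, pca, lda, confusion,
    assignment report) for programmatic use.  Any stage error aborts with the
    stage name, and files written so far are removed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        written.append(path)
        return path

    stage = "load"
    try:
        dataset = read_tps(config.tps_path)
        meta = read_metadata(config.metadata_path)
        dataset = attach_metadata(dataset, meta)
        unlabelled = [c.specimen_id for c in dataset if c.group_label is None]
        if unlabelled:
            raise ValueError(f"specimens without group label in metadata: {unlabelled[:5]}")
        unknowns: list = []
        if config.unknown_tps_path is not None:
            unknowns = list(read_tps(config.unknown_tps_path))

        stage = "superimpose"
        result = gpa(dataset)
        scores = project_to_tangent(result).matrix
        aligned = LandmarkDataset(
            tuple(
                dataclasses.replace(c, landmarks=p.coordinates, scale=None)
                for c, p in zip(dataset, result.aligned)
            )
        )
        _write("aligned.tps", lambda p: write_tps(aligned, p))

        stage = "adequacy"
        adequacy = tangent_adequacy(result)
        _write(
            "adequacy.csv",
            lambda p: pd.DataFrame(
                [
                    {
                        "slope": adequacy.slope,
                        "correlation": adequacy.correlation,
                        "n_pairs": adequacy.n_pairs,
                    }
                ]
            ).to_csv(p, index=False),
        )

        stage = "pca"
        pca = pca_fit(scores)
        _write(
            "pca_variance.csv",
            lambda p: pd.DataFrame(
                {
                    "component": np.arange(1, pca.n_components + 1),
                    "eigenvalue": pca.eigenvalues,
                    "percent_variance": pca.percent_variance,
                }
            ).to_csv(p, index=False),
        )

        stage = "lda"
        labels = list(dataset.labels())
        model = lda_fit(scores, labels, priors=config.priors, n_components=config.n_components)

        stage = "crossvalidate"
        confusion = loo_crossvalidate(
            scores, labels, priors=config.priors, n_components=config.n_components
        )
        ratios = hit_ratios(confusion)
        _write("confusion.csv", lambda p: confusion.to_dataframe().to_csv(p))
        _write(
            "hit_ratios.csv",
            lambda p: pd.DataFrame(
                [
                    {
                        "overall_hit_ratio": ratios.overall,
                        "n_misclassified": ratios.n_misclassified,
                    }
                ]
            ).to_csv(p, index=False),
        )

        report = None
        if unknowns:
            stage = "assign"
            rep_map = (
                _replicate_map([u.specimen_id for u in unknowns])
                if config.replicate_group_by_prefix
                else {}
            )
            report = _assign.assign_unknowns(
                dataset,
                unknowns,
                priors=config.priors,
                n_components=config.n_components,
                mode=config.mode,
                replicate_of=rep_map,
            )
            _write("assignment.csv", lambda p: _assign.write_assignment_csv(report, p))
            _write(
                "assignment_summary.csv",
                lambda p: _assign.write_assignment_summary_csv(report, p),
            )

        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "n_specimens": len(dataset),
            "n_landmarks": dataset.k,
            "groups": list(dataset.group_labels),
            "gpa_iterations": result.iterations,
            "gpa_converged": bool(result.converged),
            "retained_components": model.n_components,
            "priors": dict(zip(model.groups, model.priors.tolist())),
            "overall_hit_ratio": ratios.overall,
            "n_misclassified": ratios.n_misclassified,
            "adequacy_slope": adequacy.slope,
            "adequacy_correlation": adequacy.correlation,
            "assignment_mode": config.mode if unknowns else None,
            "seed": config.seed,
        }
        _write(
            "manifest.yaml",
            lambda p: p.write_text(yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8"),
        )
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "gpa": result,
        "adequacy": adequacy,
        "pca": pca,
        "lda": model,
        "confusion": confusion,
        "hit_ratios": ratios,
        "assignment": report,
        "manifest": manifest,
    }
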