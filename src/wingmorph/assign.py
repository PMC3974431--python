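"""Placement of unknown specimens (e.g. a fossil wing) among labelled groups.

The workflow mirrors the standard supervised-morphometrics recipe: reference
and unknown configurations are superimposed together, the discriminant space
is built from the reference specimens only, and each unknown is projected
*a posteriori* through the same centring, principal-component and
discriminant maps before Mahalanobis distances and posterior probabilities
to every group are computed.  Replicate digitizations of one physical
specimen stay independent rows and are summarized by a modal vote.

An ``opa`` superimposition mode aligns each unknown to the fixed reference
consensus instead of letting it participate in the joint consensus; it is
provided for sensitivity analysis, since a joint superimposition lets the
unknowns (slightly) influence the consensus everyone is rotated to.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .stats import (
    LDAModel,
    PCAModel,
    classify,
    lda_fit,
    mahalanobis_to_groups,
    pca_fit,
    posterior_probabilities,
)
from .superimpose import GPAResult, gpa, optimal_rotation, project_to_tangent, to_preshape
from .tps import LandmarkConfiguration, LandmarkDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ReplicateAssignment",
    "UnknownSummary",
    "AssignmentReport",
    "assign_unknowns",
    "subspace_pca",
    "write_assignment_csv",
    "write_assignment_summary_csv",
]


@dataclass(frozen=True)
class ReplicateAssignment:
    """Assignment of a single unknown configuration (one replicate row)."""

    replicate_id: str
    unknown_id: str                  # physical specimen this replicate measures
    mahalanobis: dict[str, float]    # per reference group
    posterior: dict[str, float]
    assigned_group: str
    tie_flag: bool
    novelty_flag: bool               # min MD beyond the reference within-group range


@dataclass(frozen=True)
class UnknownSummary:
    """Modal-vote consensus over the replicates of one physical unknown."""

    unknown_id: str
    replicate_ids: tuple[str, ...]
    assigned_group: str
    agreement: float                 # fraction of replicates voting for the modal group
    md_range: tuple[float, float]    # min/max MD to the modal group across replicates
    pp_range: tuple[float, float]    # min/max posterior for the modal group


@dataclass(frozen=True)
class AssignmentReport:
    groups: tuple[str, ...]
    replicates: tuple[ReplicateAssignment, ...]
    summaries: tuple[UnknownSummary, ...]
    mode: str                        # 'joint' or 'opa'
    priors: dict[str, float]
    n_components: int                # dimension MDs are computed in
    novelty_threshold: float         # 99th percentile of reference within-group MDs


def _tangent_rows(result: GPAResult) -> np.ndarray:
    return project_to_tangent(result).matrix


def _project_unknowns_opa(
    unknowns: Sequence[LandmarkConfiguration], result: GPAResult
) -> np.ndarray:
    """Align each unknown to the reference consensus and project to its tangent plane."""
    c = result.consensus.coordinates
    cvec = c.reshape(-1)
    rows = []
    for u in unknowns:
        p = to_preshape(u)
        r = optimal_rotation(p.coordinates, c)
        x = (p.coordinates @ r).reshape(-1)
        rows.append(x - (x @ cvec - 1.0) * cvec - cvec)
    return np.asarray(rows)


def assign_unknowns(
    reference: LandmarkDataset,
    unknowns: Sequence[LandmarkConfiguration],
    priors: str | Mapping[str, float] = "proportional",
    n_components: int | str = "auto",
    mode: str = "joint",
    replicate_of: Mapping[str, str] | None = None,
    gpa_tol: float = 1e-8,
) -> AssignmentReport:
    """Superimpose, discriminate on the reference, and place every unknown.

    ``replicate_of`` maps a replicate's specimen_id to the physical unknown
    it measures; unmapped replicates count as their own physical specimen.
    The default ``joint`` mode superimposes reference and unknowns together;
    ``opa`` aligns unknowns one-by-one onto the reference consensus.
    """
    unknowns = list(unknowns)
    if not unknowns:
        raise ValueError("no unknown configurations supplied")
    for u in unknowns:
        if u.k != reference.k:
            raise ValueError(
                f"unknown {u.specimen_id!r} has {u.k} landmarks, reference has {reference.k}"
            )
    labels = reference.labels()
    if any(l is None for l in labels):
        missing = [c.specimen_id for c in reference if c.group_label is None]
        raise ValueError(f"reference specimens without group label: {missing[:5]}")
    if mode not in ("joint", "opa"):
        raise ValueError(f"mode must be 'joint' or 'opa', got {mode!r}")

    if mode == "joint":
        joint = LandmarkDataset(tuple(reference) + tuple(unknowns))
        result = gpa(joint, tol=gpa_tol)
        rows = _tangent_rows(result)
        ref_rows, unk_rows = rows[: len(reference)], rows[len(reference):]
    else:
        result = gpa(reference, tol=gpa_tol)
        ref_rows = _tangent_rows(result)
        unk_rows = _project_unknowns_opa(unknowns, result)

    model = lda_fit(ref_rows, labels, priors=priors, n_components=n_components)

    # novelty yardstick: distribution of reference specimens' MD to their own group mean
    ref_reduced = model.transform(ref_rows)
    own_md = np.array(
        [
            mahalanobis_to_groups(model, r)[model.groups.index(lab)]
            for r, lab in zip(ref_reduced, labels)
        ]
    )
    novelty_threshold = float(np.percentile(own_md, 99))

    unk_reduced = model.transform(unk_rows)
    assigned, ties = classify(model, unk_reduced)
    replicates = []
    for u, row, lab, tie in zip(unknowns, unk_reduced, assigned, ties):
        md = mahalanobis_to_groups(model, row)
        pp = posterior_probabilities(model, row)
        novel = bool(md.min() > novelty_threshold)
        if novel:
            logger.warning(
                "unknown %s: minimum MD %.2f exceeds the 99th percentile of reference "
                "within-group MDs (%.2f); it may belong to none of the reference groups",
                u.specimen_id,
                md.min(),
                novelty_threshold,
            )
        replicates.append(
            ReplicateAssignment(
                replicate_id=u.specimen_id,
                unknown_id=(replicate_of or {}).get(u.specimen_id, u.specimen_id),
                mahalanobis=dict(zip(model.groups, md.tolist())),
                posterior=dict(zip(model.groups, pp.tolist())),
                assigned_group=str(lab),
                tie_flag=bool(tie),
                novelty_flag=novel,
            )
        )

    summaries = []
    order: list[str] = []
    by_unknown: dict[str, list[ReplicateAssignment]] = {}
    for r in replicates:
        if r.unknown_id not in by_unknown:
            order.append(r.unknown_id)
            by_unknown[r.unknown_id] = []
        by_unknown[r.unknown_id].append(r)
    for uid in order:
        reps = by_unknown[uid]
        votes = [r.assigned_group for r in reps]
        # modal group; ties between modes resolved by group label order
        modal = max(sorted(set(votes)), key=votes.count)
        mds = [r.mahalanobis[modal] for r in reps]
        pps = [r.posterior[modal] for r in reps]
        summaries.append(
            UnknownSummary(
                unknown_id=uid,
                replicate_ids=tuple(r.replicate_id for r in reps),
                assigned_group=modal,
                agreement=votes.count(modal) / len(votes),
                md_range=(min(mds), max(mds)),
                pp_range=(min(pps), max(pps)),
            )
        )

    return AssignmentReport(
        groups=model.groups,
        replicates=tuple(replicates),
        summaries=tuple(summaries),
        mode=mode,
        priors=dict(zip(model.groups, model.priors.tolist())),
        n_components=model.n_components,
        novelty_threshold=novelty_threshold,
    )


def subspace_pca(
    reference: LandmarkDataset,
    groups: Sequence[str],
    unknowns: Sequence[LandmarkConfiguration] = (),
    gpa_tol: float = 1e-8,
) -> tuple[PCAModel, np.ndarray]:
    """Unsupervised ordination within a subset of reference groups.

    The reference is restricted to ``groups``, superimposed and ordinated by
    PCA; unknowns are aligned to the restricted consensus and scored
    a posteriori.  Used to visualize where an unknown falls among its
    candidate relatives (e.g. a fossil among andrenid subfamilies).
    """
    restricted = reference.restrict_to_groups(groups)
    result = gpa(restricted, tol=gpa_tol)
    rows = _tangent_rows(result)
    model = pca_fit(rows)
    if unknowns:
        unk_rows = _project_unknowns_opa(unknowns, result)
        unk_scores = model.transform(unk_rows)
    else:
        unk_scores = np.empty((0, model.n_components))
    return model, unk_scores


# ---------------------------------------------------------------------------
# CSV report writers


def write_assignment_csv(report: AssignmentReport, path: str | Path) -> None:
    """One row per unknown replicate, with per-group MD and PP columns."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        header = ["unknown_id", "replicate_id", "assigned_group", "tie_flag"]
        header += [f"MD_{g}" for g in report.groups] + [f"PP_{g}" for g in report.groups]
        writer.writerow(header)
        for r in report.replicates:
            row = [r.unknown_id, r.replicate_id, r.assigned_group, int(r.tie_flag)]
            row += [f"{r.mahalanobis[g]:.6f}" for g in report.groups]
            row += [f"{r.posterior[g]:.6g}" for g in report.groups]
            writer.writerow(row)


def write_assignment_summary_csv(report: AssignmentReport, path: str | Path) -> None:
    """One row per physical unknown: modal assignment, agreement, MD/PP ranges."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["unknown_id", "n_replicates", "assigned_group", "agreement", "md_min", "md_max", "pp_min", "pp_max"]
        )
        for s in report.summaries:
            writer.writerow(
                [
                    s.unknown_id,
                    len(s.replicate_ids),
                    s.assigned_group,
                    f"{s.agreement:.3f}",
                    f"{s.md_range[0]:.6f}",
                    f"{s.md_range[1]:.6f}",
                    f"{s.pp_range[0]:.6g}",
                    f"{s.pp_range[1]:.6g}",
                ]
            )
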