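"""Cluster-count selection from allocation repeatability and silhouette quality.

Cluster labels are arbitrary per repetition, so repetitions are first
aligned to repetition 1 by the label bijection maximizing overlap (optimal
assignment on the k x k contingency table). Repeatability is then the
percentage of participant-by-repetition allocation records that agree with
the participant's consolidated (modal) label; the final k is the largest k
whose repeatability clears a threshold (default 95%), consolidated labels
being the modal aligned allocation with silhouette tie-breaking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .clustering import ClusterEnsemble

__all__ = [
    "AlignedEnsemble",
    "SelectionReport",
    "align_labels",
    "repeatability",
    "median_allocation",
    "select_k",
    "boundary_analysis",
]

DEFAULT_REPEATABILITY_THRESHOLD = 95.0


@dataclass
class AlignedEnsemble:
    """Labels for one k after relabelling every repetition to repetition 1."""

    k: int
    labels: np.ndarray      # R x n aligned labels, 1..k
    s_values: np.ndarray    # R x n per-participant silhouette values
    mappings: list[dict[int, int]]  # per repetition: original label -> aligned label

    @property
    def n_repetitions(self) -> int:
        return self.labels.shape[0]

    @property
    def n_participants(self) -> int:
        return self.labels.shape[1]


def _best_mapping(reference: np.ndarray, other: np.ndarray, k: int) -> dict[int, int]:
    """Label bijection (other -> reference) maximizing contingency overlap."""
    contingency = np.zeros((k, k))
    for o, r in zip(other, reference):
        contingency[o - 1, r - 1] += 1
    rows, cols = linear_sum_assignment(-contingency)
    return {int(r + 1): int(c + 1) for r, c in zip(rows, cols)}


def align_labels(ensemble: ClusterEnsemble, k: int) -> AlignedEnsemble:
    """Align all repetitions' labels at a given k to repetition 1."""
    raw = ensemble.labels_matrix(k)
    s = ensemble.s_matrix(k)
    if raw.shape[0] < 2:
        raise ValueError("alignment requires at least 2 repetitions")
    aligned = raw.copy()
    mappings: list[dict[int, int]] = []
    for r in range(raw.shape[0]):
        if r == 0:
            mapping = {c: c for c in range(1, k + 1)}
        else:
            mapping = _best_mapping(raw[0], raw[r], k)
            aligned[r] = np.vectorize(mapping.__getitem__)(raw[r])
        mappings.append(mapping)
    return AlignedEnsemble(k=k, labels=aligned, s_values=s, mappings=mappings)


def median_allocation(aligned: AlignedEnsemble) -> np.ndarray:
    """Consolidated cluster label per participant across repetitions.

    The modal aligned label; a tie between labels is broken by the label of
    the repetition where that participant has the highest silhouette value.
    """
    R, n = aligned.labels.shape
    final = np.zeros(n, dtype=int)
    for i in range(n):
        col = aligned.labels[:, i]
        values, counts = np.unique(col, return_counts=True)
        top = values[counts == counts.max()]
        if top.size == 1:
            final[i] = top[0]
        else:
            candidates = np.isin(col, top)
            best_rep = np.flatnonzero(candidates)[
                np.argmax(aligned.s_values[candidates, i])
            ]
            final[i] = col[best_rep]
    return final


def repeatability(aligned: AlignedEnsemble) -> tuple[float, int, int]:
    """Allocation repeatability over participant-by-repetition records.

    Returns (repeatability_pct, n_switch_events, n_switching_participants):
    a record is 'switched' when its aligned label differs from that
    participant's modal label; repeatability_pct = 100 * (1 - switched/records).
    """
    final = median_allocation(aligned)
    switched = aligned.labels != final[None, :]
    n_records = aligned.labels.size
    n_switch_events = int(switched.sum())
    n_switching = int((switched.sum(axis=0) > 0).sum())
    pct = 100.0 * (1.0 - n_switch_events / n_records)
    return pct, n_switch_events, n_switching


@dataclass
class SelectionReport:
    per_k: dict[int, dict[str, float]]
    chosen_k: int
    final_labels: np.ndarray
    boundary_flags: np.ndarray  # per participant: switched and mean s near 0
    fallback: bool = False      # no k met the threshold; fell back to min k
    quality_warning: bool = False  # chosen k has lower mean_s than every smaller k
    threshold: float = DEFAULT_REPEATABILITY_THRESHOLD

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_k": {str(k): v for k, v in self.per_k.items()},
            "chosen_k": self.chosen_k,
            "final_labels": self.final_labels.tolist(),
            "boundary_flags": self.boundary_flags.tolist(),
            "fallback": self.fallback,
            "quality_warning": self.quality_warning,
            "threshold": self.threshold,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_markdown(self) -> str:
        lines = [
            "| k | mean s | SD s | repeatability % | switch events | switching participants |",
            "|---|--------|------|-----------------|---------------|------------------------|",
        ]
        for k in sorted(self.per_k):
            m = self.per_k[k]
            lines.append(
                f"| {k} | {m['mean_s']:.3f} | {m['sd_s']:.3f} | "
                f"{m['repeatability_pct']:.1f} | {int(m['n_switch_events'])} | "
                f"{int(m['n_switching_participants'])} |"
            )
        lines.append("")
        lines.append(f"Chosen k: **{self.chosen_k}**"
                     + (" (fallback: no k met the repeatability threshold)"
                        if self.fallback else ""))
        if self.quality_warning:
            lines.append("Warning: mean silhouette at the chosen k is below "
                         "every smaller k.")
        return "\n".join(lines)


def select_k(ensemble: ClusterEnsemble,
             threshold: float = DEFAULT_REPEATABILITY_THRESHOLD,
             boundary_s: float = 0.1) -> SelectionReport:
    """Choose the largest k with repeatability >= threshold.

    Reports per-k silhouette quality (mean over all repetitions'
    per-participant values) and repeatability; if no k clears the
    threshold, falls back to the smallest k in range with an explicit flag.
    Participants flagged as boundary cases switched allocation at the
    chosen k and have mean silhouette below ``boundary_s``.
    """
    per_k: dict[int, dict[str, float]] = {}
    aligned_by_k: dict[int, AlignedEnsemble] = {}
    for k in ensemble.k_range:
        aligned = align_labels(ensemble, k)
        aligned_by_k[k] = aligned
        pct, events, switching = repeatability(aligned)
        s_all = aligned.s_values
        per_k[k] = {
            "mean_s": float(s_all.mean()),
            "sd_s": float(s_all.std(ddof=0)),
            "repeatability_pct": pct,
            "n_switch_events": float(events),
            "n_switching_participants": float(switching),
        }
    candidates = [k for k in ensemble.k_range
                  if per_k[k]["repeatability_pct"] >= threshold]
    fallback = not candidates
    chosen_k = max(candidates) if candidates else min(ensemble.k_range)
    quality_warning = all(
        per_k[chosen_k]["mean_s"] < per_k[k]["mean_s"]
        for k in ensemble.k_range if k < chosen_k
    ) and chosen_k > min(ensemble.k_range)
    aligned = aligned_by_k[chosen_k]
    final = median_allocation(aligned)
    switched_any = (aligned.labels != final[None, :]).any(axis=0)
    boundary = switched_any & (aligned.s_values.mean(axis=0) < boundary_s)
    return SelectionReport(per_k=per_k, chosen_k=chosen_k, final_labels=final,
                           boundary_flags=boundary, fallback=fallback,
                           quality_warning=quality_warning, threshold=threshold)


def boundary_analysis(aligned: AlignedEnsemble,
                      participant_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-participant mean silhouette vs allocation-switch count.

    Supports the boundary-effect view: records close to a cluster boundary
    (mean s near 0) are the ones that tend to change allocation between
    repetitions.
    """
    final = median_allocation(aligned)
    n_switches = (aligned.labels != final[None, :]).sum(axis=0)
    mean_s = aligned.s_values.mean(axis=0)
    ids = participant_ids if participant_ids is not None else [
        f"P{i + 1:02d}" for i in range(aligned.n_participants)
    ]
    return pd.DataFrame({
        "participant_id": ids,
        "mean_s": mean_s,
        "n_switches": n_switches,
        "final_label": final,
    })
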