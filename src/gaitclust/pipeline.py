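"""End-to-end orchestration: preprocess -> ensemble -> selection -> SPM."""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .clustering import ClusterEnsemble, run_ensemble
from .config import PipelineConfig
from .preprocessing import FeatureMatrix, ParticipantWaveforms, participants_to_matrix
from .selection import SelectionReport, select_k
from .spm import DeviationReport, NDComparisonSet, augment_nd, compare_clusters_to_nd
from .synthetic import NDReference

__all__ = ["PipelineResult", "run_pipeline", "spawn_seed"]


def spawn_seed(master_seed: int, label: str) -> int:
    """Deterministic child seed (< 2^31) for a named pipeline stage."""
    tag = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence([master_seed, tag])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineResult:
    matrix: FeatureMatrix
    ensemble: ClusterEnsemble
    selection: SelectionReport
    deviations: DeviationReport

    def clusters(self, participants: Sequence[ParticipantWaveforms]
                 ) -> dict[int, list[ParticipantWaveforms]]:
        out: dict[int, list[ParticipantWaveforms]] = {}
        for p, lab in zip(participants, self.selection.final_labels):
            out.setdefault(int(lab), []).append(p)
        return out


def run_pipeline(
    participants: Sequence[ParticipantWaveforms],
    nd_reference: NDReference,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on a cohort against an ND reference."""
    cfg = (config or PipelineConfig()).validate()
    matrix = participants_to_matrix(participants)
    ensemble = run_ensemble(
        matrix.values,
        k_range=cfg.k_range,
        n_restarts=cfg.n_restarts,
        n_repetitions=cfg.n_repetitions,
        master_seed=spawn_seed(cfg.master_seed, "ensemble"),
    )
    selection = select_k(ensemble, threshold=cfg.repeatability_threshold)
    clusters: dict[int, list[ParticipantWaveforms]] = {}
    for p, lab in zip(participants, selection.final_labels):
        clusters.setdefault(int(lab), []).append(p)
    nd_set: NDComparisonSet = augment_nd(nd_reference)
    deviations = compare_clusters_to_nd(clusters, nd_set, alpha=cfg.alpha)
    return PipelineResult(matrix=matrix, ensemble=ensemble,
                          selection=selection, deviations=deviations)
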