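"""One-dimensional Statistical Parametric Mapping against the ND reference.

Each cluster's member mean patterns (degrees) are compared per channel with
the augmented normally-developing set (4 mean templates x 5 SD offsets = 20
waveforms) using a pointwise pooled-variance two-sample t field. The
family-wise critical threshold comes from 1D random field theory: residual
smoothness (FWHM) is estimated from the normalized gradient variance of the
residual fields, and the two-tailed threshold t* solves

    2 * [ P(T > t*) + (L / FWHM) * rho1(t*) ] = alpha

where rho1 is the 1D Euler-characteristic density of a t field and L the
field length in samples. Maximal runs where |t| exceeds t* are reported as
inclusive %-stance intervals with the sign of the cluster-minus-reference
difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .channels import CHANNELS, N_SAMPLES, direction_label
from .preprocessing import ParticipantWaveforms, mean_patterns_deg
from .synthetic import NDReference

__all__ = [
    "NDComparisonSet",
    "SPMResult",
    "DeviationReport",
    "ND_OFFSETS",
    "augment_nd",
    "spm_t_two_sample",
    "estimate_fwhm",
    "rft_threshold",
    "suprathreshold_intervals",
    "compare_clusters_to_nd",
]

#: SD multiples used to augment each ND mean template.
ND_OFFSETS = (-1.0, -0.5, 0.0, 0.5, 1.0)

#: Field length in inter-sample units for the 101-sample stance grid.
FIELD_LENGTH = N_SAMPLES - 1


@dataclass
class NDComparisonSet:
    """Per channel: the 20-waveform augmented ND comparison set."""

    waveforms: dict[str, np.ndarray]  # channel -> 20 x 101 array

    def __post_init__(self) -> None:
        for channel, w in self.waveforms.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (len(ND_OFFSETS) * 4, N_SAMPLES):
                raise ValueError(
                    f"channel {channel!r}: expected "
                    f"{len(ND_OFFSETS) * 4} x {N_SAMPLES} waveforms, got {w.shape}"
                )
            self.waveforms[channel] = w


@dataclass
class SPMResult:
    channel: str
    t_field: np.ndarray  # 101 t statistics
    t_crit: float
    df: int
    fwhm_est: float  # % stance
    intervals: list[tuple[int, int, int]]  # (start %, end %, sign)


@dataclass
class DeviationReport:
    """Per cluster x channel: deviation direction labels and stance intervals."""

    entries: dict[tuple[int, str], list[tuple[str, int, int]]] = field(default_factory=dict)
    spm: dict[tuple[int, str], SPMResult] = field(default_factory=dict)
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (cluster, channel), devs in sorted(self.entries.items()):
            if not devs:
                rows.append((cluster, channel, "N/A", np.nan, np.nan))
            for direction, a, b in devs:
                rows.append((cluster, channel, direction, a, b))
        return pd.DataFrame(
            rows, columns=["cluster", "channel", "direction", "start_pct", "end_pct"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_markdown(self) -> str:
        clusters = sorted({c for c, _ in self.entries})
        lines = ["| Cluster | " + " | ".join(CHANNELS) + " |",
                 "|" + "---|" * (len(CHANNELS) + 1)]
        for c in clusters:
            cells = []
            for ch in CHANNELS:
                devs = self.entries.get((c, ch), [])
                cells.append("; ".join(f"{d} {a}–{b}" for d, a, b in devs) or "N/A")
            lines.append(f"| {c} | " + " | ".join(cells) + " |")
        return "\n".join(lines)


def augment_nd(reference: NDReference) -> NDComparisonSet:
    """Expand each channel's 4 mean templates by SD offsets -1,-0.5,0,+0.5,+1.

    The offset-0 members equal the mean templates, and the pointwise mean of
    each 5-offset family equals its template exactly (symmetric offsets).
    """
    waveforms = {}
    for channel in CHANNELS:
        rows = []
        for tpl in reference[channel]:
            if tpl.pointwise_sd is None:  # defensive; templates always carry SDs
                raise ValueError(f"template for {channel!r} lacks pointwise SD")
            for off in ND_OFFSETS:
                rows.append(tpl.base_curve + off * tpl.pointwise_sd)
        waveforms[channel] = np.vstack(rows)
    return NDComparisonSet(waveforms)


def spm_t_two_sample(group_a: np.ndarray, group_b: np.ndarray
                     ) -> tuple[np.ndarray, int, np.ndarray]:
    """Pointwise pooled-variance two-sample t field (A minus B).

    Returns (t_field, df, residuals); residuals are each curve minus its
    group mean, stacked, for smoothness estimation. df = nA + nB - 2.
    """
    A = np.atleast_2d(np.asarray(group_a, dtype=float))
    B = np.atleast_2d(np.asarray(group_b, dtype=float))
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("each group needs at least 2 waveforms")
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share waveform length")
    na, nb = A.shape[0], B.shape[0]
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    ss_a = ((A - mean_a) ** 2).sum(axis=0)
    ss_b = ((B - mean_b) ** 2).sum(axis=0)
    df = na + nb - 2
    pooled_var = (ss_a + ss_b) / df
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mean_a - mean_b) / se, 0.0)
    residuals = np.vstack([A - mean_a, B - mean_b])
    return t, df, residuals


def estimate_fwhm(residuals: np.ndarray) -> float:
    """Residual-field smoothness (FWHM, in inter-sample units).

    Standard 1D estimator: the gradient variance of the component-normalized
    residual fields gives Lambda, and FWHM = sqrt(4 ln 2 / Lambda). For an
    exactly Gaussian-autocorrelated field this recovers the kernel FWHM;
    scaling all residuals leaves the estimate unchanged.
    """
    R = np.atleast_2d(np.asarray(residuals, dtype=float))
    if R.shape[0] < 2:
        raise ValueError("need at least 2 residual curves")
    ssq = (R ** 2).sum(axis=0)
    if not np.any(ssq > 0):
        raise ValueError("all-zero residuals: smoothness undefined")
    grad = np.diff(R, axis=1)
    ssq_mid = 0.5 * (ssq[:-1] + ssq[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = (grad ** 2).sum(axis=0) / ssq_mid
    lam = lam[np.isfinite(lam) & (lam > 0)]
    if lam.size == 0:
        raise ValueError("degenerate residuals: smoothness undefined")
    return float(np.sqrt(4.0 * np.log(2.0) / lam.mean()))


def _ec_density_t(t: float, df: int) -> float:
    """1D Euler-characteristic density rho1 of a t field (per resel)."""
    return (np.sqrt(4.0 * np.log(2.0)) / (2.0 * np.pi)
            * (1.0 + t * t / df) ** (-(df - 1) / 2.0))


def expected_suprathreshold_clusters(t: float, df: int, fwhm: float,
                                     field_length: float = FIELD_LENGTH) -> float:
    """Expected Euler characteristic of the one-tailed excursion set."""
    resels = field_length / fwhm
    return stats.t.sf(t, df) + resels * _ec_density_t(t, df)


def rft_threshold(alpha: float = 0.05, df: int = 1, fwhm_est: float = 10.0,
                  field_length: float = FIELD_LENGTH) -> float:
    """Two-tailed family-wise critical t for a smooth 1D t field.

    Solves E[EC](t*) = alpha/2 per tail with the two-term (EC0 + EC1)
    expected-Euler-characteristic approximation; as FWHM grows without
    bound this tends to the pointwise two-tailed critical value.
    """
    if not (np.isfinite(alpha) and 0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not np.isfinite(df) or df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if not np.isfinite(fwhm_est) or fwhm_est <= 0:
        raise ValueError(f"fwhm_est must be positive and finite, got {fwhm_est}")
    target = alpha / 2.0

    def f(t: float) -> float:
        return expected_suprathreshold_clusters(t, df, fwhm_est, field_length) - target

    lo = float(stats.t.isf(target, df))  # pointwise critical value: f(lo) >= 0
    hi = lo + 1.0
    while f(hi) > 0:
        hi += 5.0
        if hi > 1e4:
            raise RuntimeError("failed to bracket the RFT threshold")
    return float(brentq(f, lo, hi, xtol=1e-8))


def suprathreshold_intervals(t_field: np.ndarray, t_crit: float
                             ) -> list[tuple[int, int, int]]:
    """Maximal runs with |t| > t_crit as inclusive (start%, end%, sign)."""
    t = np.asarray(t_field, dtype=float)
    above = np.abs(t) > t_crit
    intervals: list[tuple[int, int, int]] = []
    i = 0
    n = t.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        sign = int(np.sign(t[i]))
        while j + 1 < n and above[j + 1] and int(np.sign(t[j + 1])) == sign:
            j += 1
        intervals.append((i, j, sign))
        i = j + 1
    return intervals


def compare_clusters_to_nd(
    clusters: Mapping[int, Sequence[ParticipantWaveforms]],
    nd_set: NDComparisonSet,
    alpha: float = 0.05,
) -> DeviationReport:
    """Table-style deviation report: every cluster x channel SPM comparison.

    Cluster members contribute their per-participant mean patterns in
    degrees; a cluster with fewer than 2 members is skipped with a warning.
    Direction labels come from the sign of (cluster mean - ND mean) on each
    suprathreshold interval and the package sign convention.
    """
    report = DeviationReport(alpha=alpha)
    for cluster_id in sorted(clusters):
        members = clusters[cluster_id]
        if len(members) < 2:
            warnings.warn(
                f"cluster {cluster_id} has fewer than 2 members; skipped",
                stacklevel=2,
            )
            continue
        patterns = [mean_patterns_deg(p) for p in members]
        for channel in CHANNELS:
            group_a = np.vstack([pat[channel] for pat in patterns])
            group_b = nd_set.waveforms[channel]
            t, df, residuals = spm_t_two_sample(group_a, group_b)
            fwhm = estimate_fwhm(residuals)
            t_crit = rft_threshold(alpha=alpha, df=df, fwhm_est=fwhm)
            intervals = suprathreshold_intervals(t, t_crit)
            report.spm[(cluster_id, channel)] = SPMResult(
                channel=channel, t_field=t, t_crit=t_crit, df=df,
                fwhm_est=fwhm, intervals=intervals,
            )
            report.entries[(cluster_id, channel)] = [
                (direction_label(channel, sign), a, b) for a, b, sign in intervals
            ]
    return report
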