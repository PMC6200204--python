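"""Synthetic gait cohorts with known archetype structure.

Emulates the statistical structure of a 37-participant spastic-diplegia
cohort: a normally-developing (ND) reference of four mean waveforms per
channel with pointwise SDs, and four kinematic archetypes defined by
channel-specific deviation templates (direction, stance-phase interval,
amplitude). Every generated participant carries a ground-truth archetype
label, so cluster recovery and deviation-interval recovery are testable
end to end.

The ND base curves are smooth parametric stand-ins with physiological
shape and magnitude; they are synthetic, not digitized from any published
figure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal.windows import tukey

from .channels import CHANNELS, N_SAMPLES, check_channel
from .preprocessing import ParticipantWaveforms

__all__ = [
    "ChannelTemplate",
    "Deviation",
    "ArchetypeSpec",
    "NDReference",
    "NoiseParams",
    "SyntheticCohort",
    "default_archetypes",
    "make_nd_reference",
    "render_archetype",
    "generate_cohort",
    "bump_weights",
    "write_cohort_csv",
    "write_nd_csv",
    "read_nd_csv",
]

#: % stance grid, 0..100 inclusive.
STANCE_GRID = np.arange(N_SAMPLES, dtype=float)

#: Default deviation amplitude in degrees (separable but overlapping cohorts).
DEFAULT_AMPLITUDE = 8.0


@dataclass(frozen=True)
class ChannelTemplate:
    """One ND mean waveform with its pointwise SD for a single channel."""

    channel_name: str
    base_curve: np.ndarray  # 101 angles, degrees
    pointwise_sd: np.ndarray  # 101 non-negative degrees

    def __post_init__(self) -> None:
        check_channel(self.channel_name)
        base = np.asarray(self.base_curve, dtype=float)
        sd = np.asarray(self.pointwise_sd, dtype=float)
        if base.shape != (N_SAMPLES,) or sd.shape != (N_SAMPLES,):
            raise ValueError(
                f"template for {self.channel_name} must have {N_SAMPLES} samples"
            )
        if np.any(sd < 0):
            raise ValueError("pointwise_sd must be non-negative everywhere")
        object.__setattr__(self, "base_curve", base)
        object.__setattr__(self, "pointwise_sd", sd)


#: templates per channel: channel -> list of 4 ChannelTemplate variants.
NDReference = dict[str, list[ChannelTemplate]]


@dataclass(frozen=True)
class Deviation:
    """A single archetype deviation: signed smooth bump on one channel.

    ``direction`` is 'increase' or 'decrease' with respect to the package
    sign convention (flexion/adduction/internal-rotation/dorsiflexion
    positive); the stance interval is inclusive in % stance.
    """

    channel: str
    direction: str  # 'increase' | 'decrease'
    start: int  # % stance
    end: int  # % stance
    amplitude: float = DEFAULT_AMPLITUDE  # degrees

    def __post_init__(self) -> None:
        check_channel(self.channel)
        if self.direction not in ("increase", "decrease"):
            raise ValueError(f"direction must be increase/decrease, got {self.direction!r}")
        if not (0 <= self.start <= self.end <= 100):
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")

    @property
    def sign(self) -> int:
        return 1 if self.direction == "increase" else -1


@dataclass(frozen=True)
class ArchetypeSpec:
    archetype_id: int
    deviations: tuple[Deviation, ...]

    def channels_touched(self) -> set[str]:
        return {d.channel for d in self.deviations}


@dataclass(frozen=True)
class NoiseParams:
    """Smooth within-archetype noise.

    ``sd`` is the pointwise SD in degrees on a reference channel; each
    channel's actual noise SD is scaled in proportion to its typical
    variability (see ``NOISE_SCALE``), since low-range channels such as the
    coronal hip vary less in absolute degrees than the sagittal channels.
    ``corr_len`` is the noise FWHM in % stance.
    """

    sd: float = 3.25
    corr_len: float = 10.0


@dataclass
class SyntheticCohort:
    participants: list[ParticipantWaveforms]
    true_labels: list[int]  # archetype_id per participant
    seed: int
    noise_params: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        if len(self.participants) != len(self.true_labels):
            raise ValueError("true_labels length must match participants")


def default_archetypes(amplitude: float = DEFAULT_AMPLITUDE) -> list[ArchetypeSpec]:
    """The four default archetype deviation templates.

    Directions follow the sign convention: an abduction / extension /
    external-rotation / plantarflexion deviation is a 'decrease', the
    opposite deviations are 'increase'.
    """

    def dev(ch: str, direction: str, a: int, b: int) -> Deviation:
        return Deviation(ch, direction, a, b, amplitude)

    return [
        ArchetypeSpec(1, (
            dev("hip_sagittal", "increase", 98, 100),   # flexion
            dev("hip_coronal", "decrease", 0, 94),      # abduction
            dev("hip_transverse", "decrease", 20, 100), # external rotation
            dev("knee_sagittal", "increase", 0, 18),    # flexion
            dev("ankle_sagittal", "increase", 8, 44),   # dorsiflexion
        )),
        ArchetypeSpec(2, (
            dev("hip_sagittal", "increase", 66, 100),
            dev("hip_coronal", "increase", 5, 18),      # adduction
            dev("hip_coronal", "decrease", 41, 60),     # abduction
            dev("hip_transverse", "increase", 0, 11),   # internal rotation
            dev("knee_sagittal", "increase", 0, 20),
            dev("ankle_sagittal", "increase", 8, 31),
            dev("ankle_sagittal", "decrease", 90, 100), # plantarflexion
        )),
        ArchetypeSpec(3, (
            dev("hip_sagittal", "increase", 0, 5),
            dev("hip_sagittal", "increase", 63, 100),
            dev("knee_sagittal", "increase", 0, 18),
            dev("knee_sagittal", "increase", 96, 100),
            dev("ankle_sagittal", "increase", 10, 28),
        )),
        ArchetypeSpec(4, (
            dev("hip_sagittal", "increase", 41, 100),
            dev("hip_coronal", "decrease", 0, 15),
            dev("hip_coronal", "decrease", 18, 40),
            dev("hip_transverse", "decrease", 0, 7),
            dev("knee_sagittal", "increase", 0, 18),
            dev("knee_sagittal", "increase", 60, 100),
            dev("ankle_sagittal", "increase", 11, 33),
            dev("ankle_sagittal", "increase", 49, 86),
        )),
    ]


# ---------------------------------------------------------------------------
# ND reference generation

# Physiological base shapes (degrees) as functions of t in [0, 1] stance.
def _base_shape(channel: str, t: np.ndarray) -> np.ndarray:
    if channel == "hip_sagittal":
        # flexed ~35 deg at heel strike, extending through stance
        return 10.0 + 25.0 * np.cos(1.05 * np.pi * t) + 2.0 * np.sin(2 * np.pi * t)
    if channel == "hip_coronal":
        # mild adduction in loading response, abduction in pre-swing
        return (6.0 * np.exp(-(((t - 0.2) / 0.25) ** 2))
                - 6.0 * np.exp(-(((t - 0.95) / 0.25) ** 2)))
    if channel == "hip_transverse":
        return 2.0 + 4.0 * np.sin(1.4 * np.pi * t + 0.5)
    if channel == "knee_sagittal":
        # loading-response flexion wave, midstance extension, pre-swing flexion
        return (5.0 + 15.0 * np.exp(-(((t - 0.15) / 0.12) ** 2)) + 35.0 * t ** 4)
    if channel == "ankle_sagittal":
        # early plantarflexion, dorsiflexion through midstance, push-off
        return (-6.0 * np.exp(-(((t - 0.06) / 0.07) ** 2))
                + 13.0 * np.exp(-(((t - 0.65) / 0.3) ** 2))
                - 25.0 * np.exp(-(((t - 1.05) / 0.18) ** 2)))
    raise AssertionError(channel)


_SD_LEVEL = {
    "hip_sagittal": 5.0,
    "hip_coronal": 3.0,
    "hip_transverse": 5.0,
    "knee_sagittal": 5.0,
    "ankle_sagittal": 4.0,
}

#: Per-channel noise multiplier: noise scales with channel variability.
NOISE_SCALE = {ch: sd / 5.0 for ch, sd in _SD_LEVEL.items()}

N_VARIANTS = 4

#: Between-variant scatter of the ND mean curves (degrees).
VARIANT_SCATTER = 0.8


def make_nd_reference(seed: int) -> NDReference:
    """Generate four ND mean-waveform variants with pointwise SDs per channel.

    Variants are the channel's base shape plus a seeded low-order Fourier
    perturbation (between-variant scatter ~1 deg), emulating independent
    normative datasets. SD curves are strictly positive and smoothly
    modulated around a channel-typical level.
    """
    rng = np.random.default_rng(seed)
    t = STANCE_GRID / 100.0
    reference: NDReference = {}
    for channel in CHANNELS:
        base = _base_shape(channel, t)
        templates = []
        for _ in range(N_VARIANTS):
            curve = base + rng.normal(0.0, VARIANT_SCATTER)
            for h in (1, 2, 3):
                curve = curve + rng.normal(0.0, VARIANT_SCATTER / h) * np.cos(np.pi * h * t)
                curve = curve + rng.normal(0.0, VARIANT_SCATTER / h) * np.sin(np.pi * h * t)
            phase = rng.uniform(0, 2 * np.pi)
            sd = _SD_LEVEL[channel] * (1.0 + 0.15 * np.cos(2 * np.pi * t + phase))
            templates.append(ChannelTemplate(channel, curve, sd))
        reference[channel] = templates
    return reference


# ---------------------------------------------------------------------------
# Archetype rendering

#: Tukey taper fraction of each deviation bump (raised-cosine shoulders).
BUMP_TAPER = 0.25


def bump_weights(start: int, end: int, n: int = N_SAMPLES) -> np.ndarray:
    """Unit-amplitude smooth bump supported on samples start..end inclusive.

    A Tukey (tapered-cosine) window so the deviation plateaus at full
    amplitude with raised-cosine shoulders inside the stated interval.
    """
    if not (0 <= start <= end <= n - 1):
        raise ValueError(f"invalid interval [{start}, {end}] on 0..{n - 1}")
    w = np.zeros(n)
    w[start:end + 1] = tukey(end - start + 1, alpha=BUMP_TAPER)
    return w


def smooth_noise(rng: np.random.Generator, n: int, sd: float, corr_len: float) -> np.ndarray:
    """Zero-mean Gaussian noise smoothed to FWHM ``corr_len`` samples,
    rescaled so the pointwise SD equals ``sd``."""
    if sd == 0:
        return np.zeros(n)
    sigma = corr_len / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    pad = int(np.ceil(4 * sigma))
    white = rng.standard_normal(n + 2 * pad)
    smoothed = gaussian_filter1d(white, sigma, mode="constant")[pad:pad + n]
    # exact kernel norm so the smoothed field has unit pointwise variance
    impulse = np.zeros(2 * pad + 1)
    impulse[pad] = 1.0
    kernel = gaussian_filter1d(impulse, sigma, mode="constant")
    return smoothed * (sd / np.sqrt(np.sum(kernel ** 2)))


def render_archetype(
    template_set: NDReference,
    spec: ArchetypeSpec,
    noise_params: NoiseParams,
    rng: np.random.Generator,
    participant_id: str = "P00",
) -> ParticipantWaveforms:
    """Render one participant of the given archetype.

    Each channel is a randomly chosen ND base variant plus the archetype's
    signed deviation bumps plus smooth correlated noise; channels the
    archetype does not touch differ from ND only by noise.
    """
    for d in spec.deviations:
        check_channel(d.channel)
    steps: dict[str, list[np.ndarray]] = {}
    for channel in CHANNELS:
        variants = template_set[channel]
        base = variants[rng.integers(len(variants))].base_curve.copy()
        for d in spec.deviations:
            if d.channel == channel:
                base = base + d.sign * d.amplitude * bump_weights(d.start, d.end)
        base = base + smooth_noise(rng, N_SAMPLES,
                                   noise_params.sd * NOISE_SCALE[channel],
                                   noise_params.corr_len)
        steps[channel] = [base]
    return ParticipantWaveforms(participant_id=participant_id, steps=steps)


DEFAULT_SIZES = (5, 12, 12, 8)


def generate_cohort(
    sizes: Sequence[int] = DEFAULT_SIZES,
    amplitude_scale: float = 1.0,
    noise_params: NoiseParams | None = None,
    seed: int = 0,
    nd_reference: NDReference | None = None,
) -> SyntheticCohort:
    """Generate a labelled cohort with the four default archetypes.

    ``sizes`` gives the number of participants per archetype (default
    5, 12, 12, 8 -> 37). ``amplitude_scale`` multiplies every deviation
    amplitude. The ND reference used for rendering defaults to
    ``make_nd_reference(seed)`` so a cohort is fully reproducible from its
    seed alone.
    """
    sizes = tuple(int(s) for s in sizes)
    if len(sizes) != 4:
        raise ValueError("sizes must have exactly 4 entries (one per archetype)")
    if any(s < 0 for s in sizes):
        raise ValueError(f"sizes must be non-negative, got {sizes}")
    noise = noise_params if noise_params is not None else NoiseParams()
    archetypes = default_archetypes(DEFAULT_AMPLITUDE * amplitude_scale)
    reference = nd_reference if nd_reference is not None else make_nd_reference(seed)
    rng = np.random.default_rng(seed)
    participants: list[ParticipantWaveforms] = []
    labels: list[int] = []
    idx = 0
    for spec, size in zip(archetypes, sizes):
        for _ in range(size):
            idx += 1
            participants.append(
                render_archetype(reference, spec, noise, rng, participant_id=f"P{idx:02d}")
            )
            labels.append(spec.archetype_id)
    return SyntheticCohort(participants, labels, seed, noise)


# ---------------------------------------------------------------------------
# I/O

def write_cohort_csv(cohort: SyntheticCohort, csv_path: str | Path,
                     sidecar_path: str | Path | None = None) -> None:
    """Long-format CSV (participant_id,channel,sample_index,value_deg) plus a
    JSON sidecar with seed, noise parameters and true labels."""
    rows = []
    for p in cohort.participants:
        for channel in CHANNELS:
            series = p.steps[channel][0]
            for i, v in enumerate(series):
                rows.append((p.participant_id, channel, i, v))
    df = pd.DataFrame(rows, columns=["participant_id", "channel", "sample_index", "value_deg"])
    df.to_csv(csv_path, index=False)
    if sidecar_path is None:
        sidecar_path = Path(csv_path).with_suffix(".json")
    meta = {
        "seed": cohort.seed,
        "noise_sd_deg": cohort.noise_params.sd,
        "noise_corr_len_pct": cohort.noise_params.corr_len,
        "true_labels": {
            p.participant_id: lab
            for p, lab in zip(cohort.participants, cohort.true_labels)
        },
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=2))


def write_nd_csv(reference: NDReference, path: str | Path) -> None:
    rows = []
    for channel in CHANNELS:
        for variant, tpl in enumerate(reference[channel]):
            for i in range(N_SAMPLES):
                rows.append((channel, variant, i, tpl.base_curve[i], tpl.pointwise_sd[i]))
    pd.DataFrame(
        rows, columns=["channel", "variant", "sample_index", "mean_deg", "sd_deg"]
    ).to_csv(path, index=False)


def read_nd_csv(path: str | Path) -> NDReference:
    df = pd.read_csv(path)
    reference: NDReference = {}
    for channel, cdf in df.groupby("channel", sort=False):
        check_channel(str(channel))
        templates = []
        for _, vdf in cdf.groupby("variant", sort=True):
            vdf = vdf.sort_values("sample_index")
            templates.append(ChannelTemplate(
                str(channel),
                vdf["mean_deg"].to_numpy(),
                vdf["sd_deg"].to_numpy(),
            ))
        reference[str(channel)] = templates
    return {ch: reference[ch] for ch in CHANNELS}
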