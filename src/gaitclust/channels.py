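"""Channel names, ordering and angle sign conventions.

The five analyzed channels and their fixed concatenation order are used
everywhere; every participant vector is laid out in this order. Sign
convention (stated once, used throughout): flexion, adduction, internal
rotation and dorsiflexion are positive; extension, abduction, external
rotation and plantarflexion are negative.
"""

from __future__ import annotations

#: Fixed channel ordering of the concatenated 505-feature participant vector.
CHANNELS: tuple[str, ...] = (
    "hip_sagittal",
    "hip_coronal",
    "hip_transverse",
    "knee_sagittal",
    "ankle_sagittal",
)

#: Samples per channel after time normalization (0..100 % stance inclusive).
N_SAMPLES: int = 101

#: Total participant-vector length.
VECTOR_LENGTH: int = N_SAMPLES * len(CHANNELS)

#: (label for positive deviation, label for negative deviation) per channel.
SIGN_CONVENTION: dict[str, tuple[str, str]] = {
    "hip_sagittal": ("Flex.", "Ext."),
    "hip_coronal": ("Add.", "Abd."),
    "hip_transverse": ("Int. Rot.", "Ext. Rot."),
    "knee_sagittal": ("Flex.", "Ext."),
    "ankle_sagittal": ("Dorsi.", "Plant."),
}


class UnknownChannelError(KeyError):
    """Raised when a channel name outside the five analyzed channels is used."""


def check_channel(name: str) -> str:
    if name not in CHANNELS:
        raise UnknownChannelError(
            f"unknown channel {name!r}; expected one of {CHANNELS}"
        )
    return name


def direction_label(channel: str, sign: int) -> str:
    """Clinical label for a deviation of the given sign on a channel.

    Positive sign means the cluster angle exceeds the reference in the
    positive convention direction, e.g. sign=+1 on hip_coronal -> "↑ Add.",
    sign=-1 -> "↑ Abd.".
    """
    check_channel(channel)
    pos, neg = SIGN_CONVENTION[channel]
    return "↑ " + (pos if sign > 0 else neg)
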