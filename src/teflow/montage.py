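"""Channel rosters for the extended international 10-10 system.

The default roster mirrors a 64-electrode active cap with the two
mastoid-adjacent electrodes (TP9/TP10, used for offline re-referencing)
removed, leaving 62 analysis channels.  The roster is configuration-driven
everywhere it is consumed; this module only supplies sensible defaults.
"""

from __future__ import annotations

# Standard 64-channel 10-10 cap layout (FCz serves as the online reference
# and is not an analysis channel).
CAP_64 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8",
    "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8",
)

# Mastoid-adjacent electrodes consumed by offline re-referencing.
REFERENCE_CHANNELS = ("TP9", "TP10")

#: 62 scalp channels entering the connectivity analysis.
MONTAGE_62 = tuple(ch for ch in CAP_64 if ch not in REFERENCE_CHANNELS)

#: Experimental settings: neutral / androstadienol / estratetraenol odour
#: crossed with female / male storyteller voice.
CONDITIONS = ("NF", "NM", "AF", "AM", "EF", "EM")

#: Odour settings paired with the voice-matched neutral baseline.
NEUTRAL_PAIRING = {"AF": "NF", "EF": "NF", "AM": "NM", "EM": "NM"}


def default_labels(n_channels: int) -> tuple[str, ...]:
    """First ``n_channels`` labels of the 62-channel roster.

    Falls back to synthetic ``CH<i>`` names beyond 62 channels so small
    simulation designs and oversized test designs both get unique labels.
    """
    if n_channels <= len(MONTAGE_62):
        return MONTAGE_62[:n_channels]
    extra = tuple(f"CH{i}" for i in range(len(MONTAGE_62), n_channels))
    return MONTAGE_62 + extra
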