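"""Electrode naming for the 64-channel 10-20 montage used throughout.

The scalp montage is the standard 64-location extended 10-20 layout of a
BioSemi ActiveTwo system; the two earlobe electrodes (``A1``/``A2``) serve as
the reference pair and are carried alongside the scalp channels until
re-referencing.
"""

from __future__ import annotations

#: 64 scalp locations of the extended international 10-20 system.
SCALP_64: tuple[str, ...] = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

#: Earlobe reference electrodes.
EARLOBES: tuple[str, str] = ("A1", "A2")

#: Channels that define the ocular-artefact proxy (mean of Fp1-F1 and Fp2-F2).
OCULAR_CHANNELS: tuple[str, str, str, str] = ("Fp1", "F1", "Fp2", "F2")

# Preference order for reduced montages: the four ocular-proxy channels come
# first (they are required by artefact removal), then a midline/parasagittal
# spread that keeps reduced montages spatially representative.
_REDUCED_PREFERENCE: tuple[str, ...] = (
    "Fp1", "F1", "Fp2", "F2",
    "Cz", "Pz", "POz", "Oz", "CPz", "Fz", "FCz", "AFz",
    "C3", "C4", "P3", "P4", "O1", "O2", "F3", "F4",
    "PO3", "PO4", "CP1", "CP2", "FC1", "FC2", "T7", "T8",
    "P7", "P8", "FT7", "FT8",
)


def default_channel_names(n_channels: int = 64) -> list[str]:
    """Return ``n_channels`` scalp channel names from the 64-location montage.

    For ``n_channels == 64`` the full montage is returned in standard order.
    Smaller montages follow a fixed preference order that always contains
    Fp1, F1, Fp2 and F2 so ocular correction remains possible.
    """
    if not 4 <= n_channels <= 64:
        raise ValueError("n_channels must be between 4 and 64")
    if n_channels == 64:
        return list(SCALP_64)
    names: list[str] = list(_REDUCED_PREFERENCE[:n_channels])
    if len(names) < n_channels:
        names += [ch for ch in SCALP_64 if ch not in names][: n_channels - len(names)]
    return names
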