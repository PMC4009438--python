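"""Default sensor montage.

EEG: eight Ag/AgCl electrodes over the sensorimotor strip in the 10-20 system;
only C3/C4 carry task information in this pipeline, the rest are recorded and
stored but unused by the feature extractors.

NIRS: twelve source-detector channels over the prefrontal cortex (Fp1/Fp2
area), formed from 3 sources and 8 detectors at two wavelengths (760/830 nm).
The exact pairing geometry is a documented plausible layout covering the
prefrontal strip, not a reconstruction of any particular headgear.
"""

EEG_CHANNELS: tuple[str, ...] = ("C3", "C4", "T3", "T4", "P3", "P4", "F3", "F4")

WAVELENGTHS_NM: tuple[float, float] = (760.0, 830.0)

N_NIRS_CHANNELS = 12
N_NIRS_SOURCES = 3
N_NIRS_DETECTORS = 8

#: source-detector pairs (1-based ids) forming the 12 prefrontal channels:
#: each source illuminates four neighbouring detectors along the Fp1-Fp2 strip.
NIRS_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (source, detector)
    for source, first in ((1, 1), (2, 3), (3, 5))
    for detector in range(first, first + 4)
)

NIRS_CHANNEL_NAMES: tuple[str, ...] = tuple(f"ch{i + 1:02d}" for i in range(N_NIRS_CHANNELS))


def nirs_column_names() -> list[str]:
    """Column names for the raw-intensity CSV: ch01_760 ... ch12_830."""
    return [
        f"{ch}_{int(wl)}"
        for ch in NIRS_CHANNEL_NAMES
        for wl in WAVELENGTHS_NM
    ]
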