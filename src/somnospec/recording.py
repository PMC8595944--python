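"""Multi-channel EEG recordings and EDF file I/O.

The in-memory container is :class:`EEGRecording`: a channels x time array of
amplitudes in microvolts with a sampling rate and ordered channel labels.
Reading EDF goes through :func:`mne.io.read_raw_edf`; writing uses a minimal
16-bit EDF+ writer (one data record per second, physical units microvolts).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

#: Standard sleep-montage channels, referenced to mastoids at acquisition.
STANDARD_CHANNELS = ("F3", "F4", "C3", "C4", "O1", "O2", "T3", "T4")


@dataclasses.dataclass
class EEGRecording:
    """Raw or cleaned multi-channel EEG signal.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    sampling_rate : float
        Sampling frequency in Hz. Must exceed twice the upper analysis
        frequency (70 Hz) for the spectral stage to be valid.
    channel_labels : tuple of str
        Ordered channel names, one per row of ``samples``.
    subject_id : str
        Identifier used in file names and error messages.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]
    subject_id: str = "anonymous"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.samples.shape[0]} signal rows"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def copy_with(self, samples: np.ndarray) -> "EEGRecording":
        return dataclasses.replace(self, samples=samples)


def _ascii_field(value, width: int) -> bytes:
    text = f"{value:<{width}}"[:width]
    return text.encode("ascii")


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording to a 16-bit EDF file (microvolt physical units).

    One data record per second; a trailing partial second is dropped.  The
    sampling rate must be a whole number of samples per second.
    """
    path = Path(path)
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = rec.n_samples // fs
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    ns = rec.n_channels

    header = bytearray()
    header += _ascii_field("0", 8)
    header += _ascii_field(rec.subject_id, 80)
    header += _ascii_field("somnospec synthetic EEG", 80)
    header += _ascii_field("01.01.00", 8)
    header += _ascii_field("00.00.00", 8)
    header += _ascii_field(256 * (ns + 1), 8)
    header += _ascii_field("", 44)
    header += _ascii_field(n_records, 8)
    header += _ascii_field(1, 8)
    header += _ascii_field(ns, 4)

    phys_max = np.empty(ns)
    for c in range(ns):
        peak = float(np.max(np.abs(rec.samples[c, : n_records * fs])))
        # Keep the written 8-character decimal exactly representative.
        phys_max[c] = float(f"{max(peak, 1.0) * 1.01:.5g}")

    for field, width in (
        (rec.channel_labels, 16),
        (["EEG"] * ns, 80),
        (["uV"] * ns, 8),
        ([f"{-m:.5g}" for m in phys_max], 8),
        ([f"{m:.5g}" for m in phys_max], 8),
        (["-32768"] * ns, 8),
        (["32767"] * ns, 8),
        ([""] * ns, 80),
        ([str(fs)] * ns, 8),
        ([""] * ns, 32),
    ):
        for value in field:
            header += _ascii_field(value, width)

    scale = 32767.0 / phys_max
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            block = rec.samples[:, r * fs : (r + 1) * fs]
            digital = np.rint(block * scale[:, None]).astype("<i2")
            fh.write(digital.tobytes())
    return path


def read_edf(path: str | Path, subject_id: str | None = None) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # mne returns volts
    if subject_id is None:
        subject_id = Path(path).stem
    return EEGRecording(
        samples=samples,
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        subject_id=subject_id,
    )
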