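"""Whole-night normalized EEG spectra and band-wise features.

The spectral pipeline estimates one power spectral density per channel by the
Blackman-Tukey method: each non-overlapping 30-s epoch (6000 samples at
200 Hz) contributes the Fourier transform of its biased autocorrelation under
a full-length rectangular lag window, the epoch PSDs are averaged over the
night, and the average is normalized to unit sum over the 0.1-70 Hz analysis
range (PSDn).  Two features are then extracted per channel and frequency
band:

* relative power ``RP = sum of PSDn over the band`` -- spectral *activity*;
* spectral entropy ``SpecEn = -(1/log N) * sum p*log(p)`` over the
  band-renormalized PSDn values -- spectral *irregularity*, 0 for a single
  spectral line and 1 for a within-band flat spectrum.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .preprocess import EpochMask
from .recording import EEGRecording, STANDARD_CHANNELS

ANALYSIS_RANGE = (0.1, 70.0)


@dataclasses.dataclass(frozen=True)
class BandDefinition:
    """A frequency band ``[f1, f2)`` in Hz."""

    name: str
    f1: float
    f2: float

    def __post_init__(self) -> None:
        if not (0.1 <= self.f1 < self.f2 <= 70.0):
            raise ValueError(
                f"band {self.name}: limits must satisfy 0.1 <= f1 < f2 <= 70"
            )


#: The eight canonical sleep-EEG bands.  Sigma (spindle band) deliberately
#: overlaps alpha and beta1; the other seven tile the analysis range.
CANONICAL_BANDS = (
    BandDefinition("delta1", 0.1, 2.0),
    BandDefinition("delta2", 2.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("sigma", 10.0, 16.0),
    BandDefinition("beta1", 13.0, 19.0),
    BandDefinition("beta2", 19.0, 30.0),
    BandDefinition("gamma", 30.0, 70.0),
)

#: The seven bands that partition [0.1, 70) exactly (all except sigma).
TILING_BANDS = tuple(b for b in CANONICAL_BANDS if b.name != "sigma")

BAND_BY_NAME = {b.name: b for b in CANONICAL_BANDS}

#: Cohort-table variables carried alongside the EEG features.
PSG_VARIABLES = ("AHI", "AR", "AS", "Nadir_SpO2", "WASO", "SleepEff")
COGNITIVE_VARIABLES = ("DAS", "PPVT3", "EVT", "DesCop", "PhPro", "Tow")


@dataclasses.dataclass
class NormalizedSpectrum:
    """Per-channel whole-night averaged PSD, unit-sum over 0.1-70 Hz."""

    frequencies: np.ndarray  # analysis-range grid, spacing fs/epoch_length
    psdn: np.ndarray  # (n_channels, n_frequencies), each row sums to 1
    channel_labels: tuple[str, ...]
    n_epochs_used: int
    subject_id: str = "anonymous"

    def channel(self, label: str) -> np.ndarray:
        return self.psdn[self.channel_labels.index(label)]

    def channel_mean(self) -> np.ndarray:
        """Cross-channel mean PSDn curve (used for group-level spectra)."""
        return self.psdn.mean(axis=0)


def _blackman_tukey_psd(epoch: np.ndarray) -> np.ndarray:
    """One-sided Blackman-Tukey PSD of one epoch (autocorrelation route).

    The biased linear autocorrelation r[k] = (1/N) sum_n x[n] x[n+k] is taken
    over the full lag range |k| <= N-1 (rectangular lag window spanning the
    epoch), folded onto the N-point frequency grid, and Fourier transformed.
    With this lag window the result coincides with the epoch periodogram,
    which serves as an independent oracle in the tests.
    """
    n = epoch.shape[-1]
    r = fftconvolve(epoch, epoch[..., ::-1], axes=-1) / n  # lags -(N-1)..N-1
    folded = np.zeros(epoch.shape[:-1] + (n,))
    folded[..., 0] = r[..., n - 1]
    folded[..., 1:] = r[..., n:] + r[..., : n - 1]
    psd = np.fft.fft(folded, axis=-1).real[..., : n // 2 + 1]
    return np.clip(psd, 0.0, None)


def band_indices(frequencies: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Indices of grid frequencies inside ``[f1, f2)`` (edge-tolerant)."""
    tol = 1e-9
    idx = np.flatnonzero(
        (frequencies >= band.f1 - tol) & (frequencies < band.f2 - tol)
    )
    if idx.size == 0:
        raise ValueError(f"band {band.name} contains no grid frequencies")
    return idx


def epoch_psd(
    rec: EEGRecording,
    mask: EpochMask | None = None,
    epoch_length: int | None = None,
) -> NormalizedSpectrum:
    """Average Blackman-Tukey epoch PSDs into one normalized spectrum.

    Epochs rejected by ``mask`` are excluded from the average.  The returned
    grid covers the analysis range [0.1, 70) Hz at resolution
    ``sampling_rate / epoch_length`` (1/30 Hz for 30-s epochs at 200 Hz).
    """
    if mask is not None:
        epoch_length = mask.epoch_length
    elif epoch_length is None:
        epoch_length = int(round(30.0 * rec.sampling_rate))
    n_epochs = rec.n_samples // epoch_length
    if mask is not None and len(mask.keep) != n_epochs:
        raise ValueError("mask length does not match the recording epoch grid")
    keep = mask.keep if mask is not None else np.ones(n_epochs, dtype=bool)
    kept = np.flatnonzero(keep)
    if kept.size == 0:
        raise ValueError(f"subject {rec.subject_id}: zero kept epochs")

    freqs = np.arange(epoch_length // 2 + 1) * rec.sampling_rate / epoch_length
    acc = np.zeros((rec.n_channels, freqs.size))
    for e in kept:
        acc += _blackman_tukey_psd(rec.samples[:, e * epoch_length : (e + 1) * epoch_length])
    acc /= kept.size

    tol = 1e-9
    sel = (freqs >= ANALYSIS_RANGE[0] - tol) & (freqs < ANALYSIS_RANGE[1] - tol)
    psdn = acc[:, sel]
    total = psdn.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError(f"subject {rec.subject_id}: zero spectral power")
    return NormalizedSpectrum(
        frequencies=freqs[sel],
        psdn=psdn / total,
        channel_labels=rec.channel_labels,
        n_epochs_used=int(kept.size),
        subject_id=rec.subject_id,
    )


def relative_power(spec: NormalizedSpectrum, band: BandDefinition) -> np.ndarray:
    """Per-channel relative power: sum of PSDn over ``[f1, f2)``."""
    idx = band_indices(spec.frequencies, band)
    return spec.psdn[:, idx].sum(axis=1)


def spectral_entropy(spec: NormalizedSpectrum, band: BandDefinition) -> np.ndarray:
    """Per-channel spectral entropy of the band-renormalized PSDn.

    Values lie in [0, 1]: 0 when all within-band mass sits in one bin, 1 when
    it is spread uniformly.  ``0 * log 0`` is treated as 0.  A channel with
    zero within-band mass is an error (entropy undefined).
    """
    idx = band_indices(spec.frequencies, band)
    p = spec.psdn[:, idx]
    mass = p.sum(axis=1, keepdims=True)
    if np.any(mass <= 0):
        raise ValueError(f"band {band.name}: zero within-band spectral mass")
    p = p / mass
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return -plogp.sum(axis=1) / np.log(idx.size)


def feature_name(measure: str, band: str, channel: str) -> str:
    return f"{measure}_{band}_{channel}"


def eeg_feature_names(
    measures: Sequence[str] = ("rp", "specen"),
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
    channels: Sequence[str] = STANDARD_CHANNELS,
) -> list[str]:
    return [
        feature_name(m, b.name, c) for m in measures for b in bands for c in channels
    ]


def build_feature_table(
    cohort: pd.DataFrame,
    spectra: Mapping[str, NormalizedSpectrum],
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
    channels: Sequence[str] = STANDARD_CHANNELS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the per-subject feature table.

    Returns ``(table, exclusions)``.  ``table`` has one row per subject with
    128 EEG feature columns (8 channels x 8 bands x {rp, specen}, named
    ``{measure}_{band}_{channel}``) plus the PSG variables, cognitive scores,
    age, sex and group carried over from ``cohort``.  Subjects without a
    spectrum, or whose spectrum lacks a required channel, are listed in
    ``exclusions`` with a reason code and left out of ``table``.
    """
    rows: list[dict] = []
    excluded: list[dict] = []
    carry = [
        c
        for c in cohort.columns
        if c in ("age", "sex", "group") + PSG_VARIABLES + COGNITIVE_VARIABLES
    ]
    for _, subject in cohort.iterrows():
        sid = str(subject["id"])
        spec = spectra.get(sid)
        if spec is None:
            excluded.append({"id": sid, "reason": "missing_eeg"})
            continue
        missing = [c for c in channels if c not in spec.channel_labels]
        if missing:
            excluded.append(
                {"id": sid, "reason": f"missing_channel:{','.join(missing)}"}
            )
            continue
        order = [spec.channel_labels.index(c) for c in channels]
        row: dict = {"id": sid}
        for col in carry:
            row[col] = subject[col]
        for band in bands:
            rp = relative_power(spec, band)[order]
            se = spectral_entropy(spec, band)[order]
            for j, ch in enumerate(channels):
                row[feature_name("rp", band.name, ch)] = rp[j]
                row[feature_name("specen", band.name, ch)] = se[j]
        rows.append(row)
    columns = ["id"] + carry + eeg_feature_names(("rp", "specen"), bands, channels)
    table = pd.DataFrame(rows, columns=columns)
    exclusions = pd.DataFrame(excluded, columns=["id", "reason"])
    return table, exclusions


def group_median_spectrum(
    spectra: Iterable[NormalizedSpectrum],
    groups: Mapping[str, str],
) -> dict[str, pd.DataFrame]:
    """Per-group median and quartile curves of the channel-mean PSDn.

    Each subject contributes the mean PSDn over its channels; per frequency
    bin the group median and 25/75% quartiles are taken.
    """
    by_group: dict[str, list[np.ndarray]] = {}
    freqs: np.ndarray | None = None
    for spec in spectra:
        label = groups[spec.subject_id]
        by_group.setdefault(label, []).append(spec.channel_mean())
        if freqs is None:
            freqs = spec.frequencies
        elif len(freqs) != len(spec.frequencies):
            raise ValueError("spectra are not on a common frequency grid")
    out = {}
    for label, curves in by_group.items():
        stack = np.vstack(curves)
        out[label] = pd.DataFrame(
            {
                "frequency": freqs,
                "median": np.median(stack, axis=0),
                "q25": np.percentile(stack, 25, axis=0),
                "q75": np.percentile(stack, 75, axis=0),
            }
        )
    return out


@dataclasses.dataclass(frozen=True)
class SpectralPeak:
    frequency: float
    amplitude: float
    at_boundary: bool


def find_spectral_peak(
    frequencies: np.ndarray,
    curve: np.ndarray,
    search_band: tuple[float, float],
) -> SpectralPeak:
    """Locate the maximum of ``curve`` within ``search_band`` (inclusive).

    Used to track the slow-oscillation peak in group-median spectra.  A peak
    landing on either edge of the search band is flagged ``at_boundary``.
    """
    lo, hi = search_band
    tol = 1e-9
    idx = np.flatnonzero((frequencies >= lo - tol) & (frequencies <= hi + tol))
    if idx.size == 0:
        raise ValueError("search band contains no grid frequencies")
    k = idx[np.argmax(curve[idx])]
    return SpectralPeak(
        frequency=float(frequencies[k]),
        amplitude=float(curve[k]),
        at_boundary=bool(k == idx[0] or k == idx[-1]),
    )
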