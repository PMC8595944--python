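"""Synthetic overnight EEG and cohort tables with planted structure.

Every downstream stage of the pipeline (preprocessing, spectral features,
correlation networks, reporting) is validated against data from this module,
because the clinical recordings the analysis was designed for are not
public.  Two generators are provided:

* :func:`synthesize_eeg` -- multi-channel colored-noise EEG whose per-band
  power fractions, broadband 1/f slope, optional low-frequency narrowband
  peak (emulating the slow oscillation) and artifact bursts are all planted
  and therefore recoverable;
* :func:`synthesize_cohort` -- a three-group cohort table (controls / mild /
  moderate-severe apnea) with configurable marginal distributions per
  variable and a Gaussian-copula latent correlation structure, plus one EEG
  synthesis spec per subject tied to the subject's severity.

The generators emulate the *statistical* structure the analysis consumes
(spectral shape, rank correlations, group marginals), not sleep physiology:
there are no sleep stages, spindle trains or REM cycles.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt
from scipy.special import ndtr, ndtri

from .recording import EEGRecording, STANDARD_CHANNELS
from .spectral import COGNITIVE_VARIABLES, PSG_VARIABLES, TILING_BANDS

TILING_NAMES = tuple(b.name for b in TILING_BANDS)
COHORT_VARIABLES = PSG_VARIABLES + COGNITIVE_VARIABLES
GROUP_LABELS = ("controls", "mild", "moderate_severe")

#: Overall signal scale (root-mean-square amplitude, microvolts).
SIGNAL_RMS_UV = 30.0

#: Default per-band power fractions of the broadband background for a
#: control-like spectrum (delta-dominated, tails thin with frequency).
CONTROL_FRACTIONS = {
    "delta1": 0.35,
    "delta2": 0.20,
    "theta": 0.15,
    "alpha": 0.10,
    "beta1": 0.08,
    "beta2": 0.07,
    "gamma": 0.05,
}

#: Severe-apnea-like spectrum: more low-delta mass, flatter fast bands.
SEVERE_FRACTIONS = {
    "delta1": 0.40,
    "delta2": 0.21,
    "theta": 0.13,
    "alpha": 0.08,
    "beta1": 0.07,
    "beta2": 0.06,
    "gamma": 0.05,
}

#: Slow-oscillation peak regime per severity group: frequency slows and
#: relative amplitude grows as severity increases.
SO_SEVERITY_REGIME = {
    "controls": (0.75, 0.08),
    "mild": (0.417, 0.10),
    "moderate_severe": (0.267, 0.13),
}


class SpecValidationError(ValueError):
    """A synthesis spec field violates its contract."""


@dataclasses.dataclass
class EEGSynthesisSpec:
    """Parameters of one synthetic EEG recording.

    ``band_power_fractions`` prescribes the share of broadband background
    power per tiling band (the seven canonical bands excluding sigma) and
    must sum to 1.  ``background_exponent`` is the 1/f^slope of the
    within-band spectral floor.  An optional narrowband peak at
    ``peak_frequency`` carries ``peak_relative_amplitude`` of the total
    signal power.  Artifact transients are raised-cosine bursts of 0.5-2 s,
    Poisson-placed at ``artifact_rate`` events/hour with amplitude
    ``artifact_amplitude_factor`` times the background RMS.
    """

    duration: float = 600.0  # seconds; whole-night runs override this
    n_channels: int = 8
    sampling_rate: float = 200.0
    band_power_fractions: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(CONTROL_FRACTIONS)
    )
    background_exponent: float = 1.0
    peak_frequency: float | None = None
    peak_relative_amplitude: float = 0.0
    artifact_rate: float = 0.0  # events per hour
    artifact_amplitude_factor: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration < 60:
            raise SpecValidationError("duration: must be >= 60 s")
        if self.n_channels < 1 or self.n_channels > len(STANDARD_CHANNELS):
            raise SpecValidationError(
                f"n_channels: must be in [1, {len(STANDARD_CHANNELS)}]"
            )
        if self.sampling_rate <= 140:
            raise SpecValidationError("sampling_rate: must exceed 140 Hz")
        bad = set(self.band_power_fractions) - set(TILING_NAMES)
        if bad:
            raise SpecValidationError(
                f"band_power_fractions: unknown band(s) {sorted(bad)}"
            )
        vals = np.array(list(self.band_power_fractions.values()), dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise SpecValidationError(
                "band_power_fractions: values must lie in [0, 1]"
            )
        if abs(vals.sum() - 1.0) > 1e-9:
            raise SpecValidationError(
                f"band_power_fractions: must sum to 1 (got {vals.sum():.12g})"
            )
        if self.peak_frequency is not None and not (
            0.1 <= self.peak_frequency <= 70.0
        ):
            raise SpecValidationError(
                "peak_frequency: must lie inside [0.1, 70] Hz"
            )
        if not 0.0 <= self.peak_relative_amplitude < 1.0:
            raise SpecValidationError(
                "peak_relative_amplitude: must lie in [0, 1)"
            )
        if self.artifact_rate < 0:
            raise SpecValidationError("artifact_rate: must be >= 0")


def _colored_bandlimited_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    band: tuple[float, float],
    exponent: float,
    sos: np.ndarray,
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise with a 1/f^exponent floor."""
    white = rng.standard_normal(n)
    if exponent != 0.0:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, 1.0 / fs)
        shaping = np.zeros_like(freqs)
        shaping[1:] = freqs[1:] ** (-exponent / 2.0)
        white = np.fft.irfft(spec * shaping, n)
    x = sosfiltfilt(sos, white)
    std = x.std()
    return x / std if std > 0 else x


def synthesize_eeg(spec: EEGSynthesisSpec) -> EEGRecording:
    """Generate a multi-channel EEG recording from a synthesis spec.

    Per channel the signal is a sum of independent band-limited Gaussian
    processes (forward-backward Butterworth band-pass of 1/f-colored white
    noise, rescaled to the exact target variance per band), plus an optional
    fixed-frequency sinusoid carrying ``peak_relative_amplitude`` of the
    total power, plus Poisson-placed raised-cosine artifact bursts shared
    across channels.  Bit-identical under a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    peak_frac = (
        spec.peak_relative_amplitude if spec.peak_frequency is not None else 0.0
    )
    background = 1.0 - peak_frac

    sos_by_band = {
        b.name: butter(4, (b.f1, b.f2), btype="bandpass", fs=fs, output="sos")
        for b in TILING_BANDS
        if spec.band_power_fractions.get(b.name, 0.0) > 0
    }
    band_edges = {b.name: (b.f1, b.f2) for b in TILING_BANDS}

    out = np.zeros((spec.n_channels, n))
    t = np.arange(n) / fs
    for c in range(spec.n_channels):
        for name, frac in spec.band_power_fractions.items():
            if frac <= 0:
                continue
            x = _colored_bandlimited_noise(
                rng, n, fs, band_edges[name], spec.background_exponent,
                sos_by_band[name],
            )
            out[c] += np.sqrt(frac * background) * x
        if peak_frac > 0:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            out[c] += np.sqrt(2.0 * peak_frac) * np.sin(
                2.0 * np.pi * spec.peak_frequency * t + phase
            )
    out *= SIGNAL_RMS_UV

    if spec.artifact_rate > 0:
        n_events = rng.poisson(spec.artifact_rate * spec.duration / 3600.0)
        for _ in range(n_events):
            burst_dur = rng.uniform(0.5, 2.0)
            width = int(round(burst_dur * fs))
            start = rng.integers(0, max(n - width, 1))
            window = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
            burst = spec.artifact_amplitude_factor * SIGNAL_RMS_UV * window
            out[:, start : start + width] += burst[: n - start]

    return EEGRecording(
        samples=out,
        sampling_rate=fs,
        channel_labels=STANDARD_CHANNELS[: spec.n_channels],
        subject_id=f"synthetic-{spec.seed}",
    )


# ---------------------------------------------------------------------------
# Cohort synthesis
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Marginal:
    """A per-group marginal given as median and quartiles.

    ``family`` is ``"normal"`` (location-scale Gaussian) or ``"lognormal"``
    (Gaussian on the log scale) -- the latter for nonnegative, right-skewed
    clinical indices.  ``bounds`` optionally truncates the distribution (used
    to keep AHI inside its severity-group interval).
    """

    median: float
    q1: float
    q3: float
    family: str = "normal"
    bounds: tuple[float, float] | None = None

    def _mu_sigma(self) -> tuple[float, float]:
        if self.family == "lognormal":
            return np.log(self.median), (np.log(self.q3) - np.log(self.q1)) / 1.349
        return self.median, (self.q3 - self.q1) / 1.349

    def _cdf(self, x: float) -> float:
        mu, sigma = self._mu_sigma()
        if sigma <= 0:
            return 0.0 if x < mu else 1.0
        if self.family == "lognormal":
            if x <= 0:
                return 0.0
            z = (np.log(x) - mu) / sigma
        else:
            z = (x - mu) / sigma
        return float(ndtr(z))

    def ppf(self, u: np.ndarray) -> np.ndarray:
        mu, sigma = self._mu_sigma()
        if self.bounds is not None:
            lo, hi = self.bounds
            flo = self._cdf(lo) if np.isfinite(lo) else 0.0
            fhi = self._cdf(hi) if np.isfinite(hi) else 1.0
            u = flo + u * (fhi - flo)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        z = ndtri(u)
        if self.family == "lognormal":
            return np.exp(mu + sigma * z)
        return mu + sigma * z


def _default_marginals() -> dict[str, dict[str, Marginal]]:
    """Group-wise marginals matching the reference cohort's summary table."""
    ln, no = "lognormal", "normal"
    spec = {
        # var: family, (controls), (mild), (moderate_severe), bounds per group
        "AHI": (ln, (0.40, 0.10, 0.60), (1.50, 1.20, 2.20), (9.20, 7.30, 17.20),
                [(0.0, 1.0), (1.0, 5.0), (5.0, np.inf)]),
        "AR": (ln, (0.30, 0.05, 0.80), (1.00, 0.40, 2.82), (7.30, 4.88, 9.55), None),
        "AS": (ln, (6.70, 4.70, 9.00), (6.60, 4.20, 9.00), (3.10, 1.52, 6.88), None),
        "Nadir_SpO2": (no, (94.0, 92.0, 95.0), (91.0, 89.0, 94.0), (84.0, 75.0, 87.0),
                       [(50.0, 100.0)] * 3),
        "WASO": (ln, (45.5, 27.0, 79.5), (37.5, 23.3, 64.3), (41.0, 19.8, 75.4), None),
        "SleepEff": (no, (90.6, 84.03, 94.1), (91.0, 85.23, 94.5), (91.0, 85.45, 95.05),
                     [(40.0, 100.0)] * 3),
        "DAS": (no, (101.5, 92.0, 111.5), (100.5, 86.0, 111.0), (97.0, 85.0, 104.0), None),
        "PPVT3": (no, (99.0, 89.5, 110.0), (98.0, 89.8, 109.3), (96.0, 88.25, 101.5), None),
        "EVT": (no, (100.0, 89.3, 108.0), (97.0, 85.5, 105.0), (96.5, 91.0, 99.0), None),
        "DesCop": (no, (11.0, 8.0, 13.0), (10.0, 7.0, 12.0), (9.0, 7.5, 11.0), None),
        "PhPro": (no, (10.0, 8.0, 12.0), (9.0, 8.0, 13.0), (7.5, 5.5, 10.0), None),
        "Tow": (no, (12.0, 10.0, 14.0), (11.0, 9.0, 14.0), (9.5, 7.0, 11.5), None),
    }
    out: dict[str, dict[str, Marginal]] = {}
    for var, (family, *groups, bounds) in spec.items():
        out[var] = {}
        for g, label in enumerate(GROUP_LABELS):
            med, q1, q3 = groups[g]
            b = bounds[g] if bounds is not None else None
            out[var][label] = Marginal(med, q1, q3, family=family, bounds=b)
    return out


DEFAULT_MARGINALS = _default_marginals()


def spearman_to_pearson(rho_s: np.ndarray) -> np.ndarray:
    """Gaussian-copula conversion from Spearman targets to Pearson inputs.

    Inverse of the classical identity ``rho_S = (6/pi) arcsin(rho_P / 2)``
    for bivariate Gaussians, so the copula reproduces the requested Spearman
    correlation after any monotone marginal transform.
    """
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)


def planted_correlation(
    pairs: Mapping[tuple[str, str], float],
    variables: tuple[str, ...] = COHORT_VARIABLES,
) -> pd.DataFrame:
    """Build a target Spearman correlation matrix from sparse pairs."""
    mat = pd.DataFrame(
        np.eye(len(variables)), index=variables, columns=variables
    )
    for (a, b), rho in pairs.items():
        mat.loc[a, b] = rho
        mat.loc[b, a] = rho
    return mat


#: A plausible dependence structure for demonstration runs: severity indices
#: co-vary, oxygenation opposes them, cognitive scores co-vary and weakly
#: oppose severity.  The magnitudes are free parameters (see docs/methods.md).
REALISTIC_CORRELATION = planted_correlation(
    {
        ("AHI", "AR"): 0.55,
        ("AHI", "Nadir_SpO2"): -0.45,
        ("AR", "Nadir_SpO2"): -0.35,
        ("WASO", "SleepEff"): -0.60,
        ("DAS", "PPVT3"): 0.45,
        ("DAS", "EVT"): 0.40,
        ("PPVT3", "EVT"): 0.55,
        ("PhPro", "PPVT3"): 0.35,
        ("DesCop", "Tow"): 0.30,
        ("AHI", "DAS"): -0.20,
        ("AHI", "PhPro"): -0.20,
        ("AHI", "Tow"): -0.15,
    }
)


@dataclasses.dataclass
class CohortSynthesisSpec:
    """Parameters of one synthetic cohort draw."""

    group_sizes: tuple[int, int, int] = (176, 98, 20)
    age_range: tuple[float, float] = (5.0, 9.0)
    age_median: float = 6.9
    age_iqr: float = 0.92
    male_fraction: float = 0.57
    marginal_params: Mapping[str, Mapping[str, Marginal]] = dataclasses.field(
        default_factory=lambda: DEFAULT_MARGINALS
    )
    latent_correlation: pd.DataFrame | None = None  # Spearman targets
    severity_regime: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(SO_SEVERITY_REGIME)
    )
    eeg_duration: float = 600.0
    eeg_channels: int = 8
    artifact_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if any(s < 0 for s in self.group_sizes) or sum(self.group_sizes) < 1:
            raise SpecValidationError("group_sizes: need >= 1 subject overall")
        if self.latent_correlation is not None:
            mat = self.latent_correlation
            unknown = set(mat.columns) - set(COHORT_VARIABLES)
            if unknown:
                raise SpecValidationError(
                    f"latent_correlation: unknown variable(s) {sorted(unknown)}"
                )
            arr = mat.to_numpy(dtype=float)
            if not np.allclose(arr, arr.T, atol=1e-12):
                raise SpecValidationError("latent_correlation: must be symmetric")
            if not np.allclose(np.diag(arr), 1.0, atol=1e-12):
                raise SpecValidationError("latent_correlation: diagonal must be 1")
            if np.linalg.eigvalsh(arr).min() < -1e-8:
                raise SpecValidationError(
                    "latent_correlation: not positive semidefinite"
                )


@dataclasses.dataclass
class CohortResult:
    table: pd.DataFrame
    eeg_specs: dict[str, EEGSynthesisSpec]


def _full_correlation(spec: CohortSynthesisSpec) -> np.ndarray:
    """Pearson copula correlation over all 12 cohort variables."""
    rho_s = np.eye(len(COHORT_VARIABLES))
    if spec.latent_correlation is not None:
        sub = spec.latent_correlation
        idx = [COHORT_VARIABLES.index(v) for v in sub.columns]
        rho_s[np.ix_(idx, idx)] = sub.to_numpy(dtype=float)
    rho_p = spearman_to_pearson(rho_s)
    np.fill_diagonal(rho_p, 1.0)
    w, v = np.linalg.eigh(rho_p)
    if w.min() < -1e-8:
        raise SpecValidationError("latent_correlation: not positive semidefinite")
    # Clip tiny negative eigenvalues introduced by the Spearman->Pearson map.
    w = np.clip(w, 1e-12, None)
    rho_p = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(rho_p))
    return rho_p / np.outer(d, d)


def synthesize_cohort(spec: CohortSynthesisSpec) -> CohortResult:
    """Draw a cohort table and per-subject EEG synthesis specs.

    Cross-variable dependence is induced by a Gaussian copula matching the
    requested Spearman ``latent_correlation`` and then mapped to the
    per-group marginals, so group membership always respects the AHI
    severity cutoffs.  Each subject receives an EEG spec whose band
    fractions interpolate between control-like and severe-like regimes, and
    whose slow-oscillation peak follows the subject's severity group.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = np.linalg.cholesky(
        _full_correlation(spec) + 1e-12 * np.eye(len(COHORT_VARIABLES))
    )

    rows = []
    eeg_specs: dict[str, EEGSynthesisSpec] = {}
    subject_index = 0
    control_vec = np.array([CONTROL_FRACTIONS[b] for b in TILING_NAMES])
    severe_vec = np.array([SEVERE_FRACTIONS[b] for b in TILING_NAMES])

    for g_idx, (label, size) in enumerate(zip(GROUP_LABELS, spec.group_sizes)):
        if size == 0:
            continue
        z = rng.standard_normal((size, len(COHORT_VARIABLES))) @ L.T
        u = ndtr(z)
        values = {
            var: spec.marginal_params[var][label].ppf(u[:, j])
            for j, var in enumerate(COHORT_VARIABLES)
        }
        age = np.clip(
            spec.age_median + (spec.age_iqr / 1.349) * rng.standard_normal(size),
            *spec.age_range,
        )
        sex = np.where(rng.random(size) < spec.male_fraction, "M", "F")
        u_ahi = u[:, COHORT_VARIABLES.index("AHI")]
        severity = (g_idx + u_ahi) / 3.0  # in (0, 1), ordered by group
        peak_freq, peak_amp = spec.severity_regime[label]

        for i in range(size):
            sid = f"s{subject_index:04d}"
            row = {"id": sid, "age": age[i], "sex": sex[i], "group": label}
            row.update({var: values[var][i] for var in COHORT_VARIABLES})
            rows.append(row)
            fractions = (1 - severity[i]) * control_vec + severity[i] * severe_vec
            fractions = fractions / fractions.sum()
            child_seed = int(
                np.random.SeedSequence([spec.seed, subject_index]).generate_state(1)[0]
                % (2**31)
            )
            eeg_specs[sid] = EEGSynthesisSpec(
                duration=spec.eeg_duration,
                n_channels=spec.eeg_channels,
                band_power_fractions=dict(zip(TILING_NAMES, fractions)),
                peak_frequency=peak_freq,
                peak_relative_amplitude=peak_amp,
                artifact_rate=spec.artifact_rate,
                seed=child_seed,
            )
            subject_index += 1

    columns = ["id", "age", "sex", "group", *COHORT_VARIABLES]
    return CohortResult(
        table=pd.DataFrame(rows, columns=columns), eeg_specs=eeg_specs
    )
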