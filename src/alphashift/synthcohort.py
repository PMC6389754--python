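"""Synthetic resting-EEG cohort generator.

Emulates the statistical structure the downstream analysis assumes:
20-s eyes-closed segments at 256 Hz over the 19-channel 10-20 montage,
containing a narrowband alpha oscillation with a controllable peak
frequency and a posterior-dominant amplitude topography, superposed on
1/f background noise, plus a per-subject covariate table (group,
syndrome, seizure-control label, age, gender, AED load, 12-month
seizure count) mirroring a three-group clinical cohort: healthy
subjects (HS) and epilepsy patients with good (GSC, < 4 seizures/12
months) or poor (PSC, >= 4) seizure control.

The alpha component is synthesized as random-phase narrowband noise
(spectral synthesis within peak_freq +/- bandwidth/2) rather than a pure
sinusoid, so band power has physiological trial-to-trial variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import MontageLayout, standard_1020_layout
from .segment import EEGSegment

COHORT_COLUMNS = ("subject_id", "group", "syndrome", "seizure_control",
                  "age", "gender", "aed_load", "seizure_count_12m")

#: Patients are labelled poor-control at or above this 12-month count.
PSC_SEIZURE_THRESHOLD = 4


@dataclass(frozen=True)
class OscillatorSpec:
    """Narrowband alpha component of one group's EEG.

    anterior_spread in [0, 1]: 0 gives a strictly posterior topography
    (amplitude decays linearly to zero at the frontal pole), 1 a
    spatially uniform one.
    """

    peak_freq: float  # Hz
    bandwidth: float = 2.0  # Hz, full spectral width
    amplitude: float = 2.0  # a.u. (RMS of the alpha waveform at occiput)
    anterior_spread: float = 0.2

    def __post_init__(self) -> None:
        if not 2 < self.peak_freq < 20:
            raise ValueError("peak_freq must lie in (2, 20) Hz")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not 0 <= self.anterior_spread <= 1:
            raise ValueError("anterior_spread must be in [0, 1]")


@dataclass(frozen=True)
class NoiseSpec:
    """Background noise: white noise of sd ``white_sd`` spectrally shaped
    to a 1/f^a power law; exponent 0 gives plain white noise, white_sd 0
    switches the background off entirely."""

    one_over_f_exponent: float = 1.0
    white_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.one_over_f_exponent < 0:
            raise ValueError("one_over_f_exponent must be >= 0")
        if self.white_sd < 0:
            raise ValueError("white_sd must be >= 0")


@dataclass(frozen=True)
class GroupCovariates:
    """Covariate distributions for one cohort group."""

    age_mean: float
    age_sd: float
    female_prop: float
    aed_mean: float = 0.0
    aed_sd: float = 0.0
    fe_proportion: float = 0.0  # fraction with a focal syndrome (patients)

    def __post_init__(self) -> None:
        for p in (self.female_prop, self.fe_proportion):
            if not 0 <= p <= 1:
                raise ValueError("proportions must be in [0, 1]")


@dataclass(frozen=True)
class CohortDesign:
    """Full specification of a synthetic cohort."""

    n_per_group: dict[str, int]
    group_oscillators: dict[str, OscillatorSpec]
    covariates: dict[str, GroupCovariates]
    noise: NoiseSpec = NoiseSpec()
    # negative-binomial (n, p) of the seizure count per control level;
    # GSC draws are clipped below the PSC threshold, PSC counts are
    # threshold + draw, so the dichotomization rule holds by construction.
    seizure_nb: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"GSC": (1.0, 0.5), "PSC": (1.5, 0.111)})
    # between-subject variability of the oscillator
    peak_freq_sd: float = 0.5  # Hz
    amplitude_cv: float = 0.3
    duration: float = 20.0  # s
    fs: float = 256.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_group:
            raise ValueError("cohort design has no groups")
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {g!r} must have >= 2 subjects")
            if g not in self.group_oscillators:
                raise ValueError(f"no oscillator spec for group {g!r}")
            if g not in self.covariates:
                raise ValueError(f"no covariate spec for group {g!r}")


def default_design(seed: int = 0) -> CohortDesign:
    """A 39/25/38 (HS/GSC/PSC) cohort with clinically plausible covariates.

    Alpha peaks: HS 10.5 Hz, GSC 10 Hz (both high-alpha), PSC 8 Hz
    (low-alpha), with the PSC topography spread anteriorly — the
    slowing-plus-anteriorization phenotype the analysis targets.
    """
    return CohortDesign(
        n_per_group={"HS": 39, "GSC": 25, "PSC": 38},
        group_oscillators={
            "HS": OscillatorSpec(10.5, 2.0, 2.0, 0.15),
            "GSC": OscillatorSpec(10.0, 2.0, 2.0, 0.25),
            "PSC": OscillatorSpec(8.0, 2.0, 2.0, 0.60),
        },
        covariates={
            "HS": GroupCovariates(30, 9, 0.49),
            "GSC": GroupCovariates(33, 12, 0.60, aed_mean=1.4, aed_sd=0.9,
                                   fe_proportion=0.40),
            "PSC": GroupCovariates(38, 14, 0.50, aed_mean=1.5, aed_sd=0.8,
                                   fe_proportion=0.71),
        },
        seed=seed,
    )


def _alpha_waveforms(n_ch: int, n: int, fs: float, osc: OscillatorSpec,
                     rng: np.random.Generator) -> np.ndarray:
    """Per-channel unit-RMS random-phase narrowband waveforms.

    Channels carry independent realizations of the same narrowband
    process (inter-channel alpha coherence is not modeled), so a
    common-average reference does not fold a shared source back into
    alpha-free channels.
    """
    freqs = np.fft.rfftfreq(n, 1 / fs)
    lo, hi = osc.peak_freq - osc.bandwidth / 2, osc.peak_freq + osc.bandwidth / 2
    band = (freqs >= lo) & (freqs <= hi) & (freqs > 0)
    if not band.any():  # degenerate narrow band: take the nearest bin
        band[np.argmin(np.abs(freqs - osc.peak_freq))] = True
    coefs = np.zeros((n_ch, len(freqs)), dtype=complex)
    k = int(band.sum())
    coefs[:, band] = (rng.standard_normal((n_ch, k))
                      + 1j * rng.standard_normal((n_ch, k)))
    waves = np.fft.irfft(coefs, n=n, axis=1)
    rms = np.sqrt(np.mean(waves ** 2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return waves / rms


def _background(n_ch: int, n: int, fs: float, noise: NoiseSpec,
                rng: np.random.Generator) -> np.ndarray:
    """Per-channel independent 1/f^a-shaped noise of RMS ``white_sd``."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-noise.one_over_f_exponent / 2.0)
    coefs = (rng.standard_normal((n_ch, len(freqs)))
             + 1j * rng.standard_normal((n_ch, len(freqs)))) * shape
    pink = np.fft.irfft(coefs, n=n, axis=1)
    rms = np.sqrt(np.mean(pink ** 2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return noise.white_sd * pink / rms


def topography_gain(osc: OscillatorSpec, layout: MontageLayout) -> np.ndarray:
    """Per-channel alpha amplitude gain.

    Linearly decays from 1 at the most posterior electrode toward the
    most anterior one; anterior_spread interpolates toward a flat
    topography (spread = 1 gives gain 1 everywhere).
    """
    y = layout.xy[:, 1]
    g0 = (y.max() - y) / (y.max() - y.min())
    return osc.anterior_spread + (1 - osc.anterior_spread) * g0


def generate_segment(osc: OscillatorSpec, noise: NoiseSpec,
                     layout: MontageLayout | None = None,
                     duration: float = 20.0, fs: float = 256.0,
                     seed: int = 0) -> EEGSegment:
    """One synthetic EEG segment: topographic alpha plus 1/f background.

    Each channel carries an independent narrowband alpha realization
    scaled by the posterior-to-anterior topographic gain; background
    noise is independent per channel.  Identical (parameters, seed)
    gives identical output.
    """
    if layout is None:
        layout = standard_1020_layout()
    if fs <= 2 * osc.peak_freq:
        raise ValueError(
            f"fs = {fs} Hz aliases a {osc.peak_freq} Hz oscillator")
    n_float = duration * fs
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9 or n < fs:
        raise ValueError("duration * fs must be an integer >= fs")
    rng = np.random.default_rng(seed)
    n_ch = len(layout.labels)
    waves = _alpha_waveforms(n_ch, n, fs, osc, rng)
    gain = topography_gain(osc, layout)
    data = osc.amplitude * gain[:, None] * waves
    data = data + _background(n_ch, n, fs, noise, rng)
    return EEGSegment(data=data, fs=fs, channel_labels=layout.labels,
                      layout=layout)


@dataclass(frozen=True)
class SubjectRecord:
    """One row of the cohort table."""

    subject_id: str
    group: str  # "HS" or "patient"
    syndrome: str  # "FE", "IGE", or "none"
    seizure_control: str  # "GSC", "PSC", or "none"
    age: float
    gender: str  # "F" or "M"
    aed_load: float
    seizure_count_12m: int

    def __post_init__(self) -> None:
        if self.group == "HS":
            if (self.syndrome != "none" or self.seizure_control != "none"
                    or self.aed_load != 0):
                raise ValueError("HS must have no syndrome, control label, "
                                 "or AED load")
        if self.aed_load < 0 or self.seizure_count_12m < 0:
            raise ValueError("aed_load and seizure count must be >= 0")
        if self.seizure_control == "PSC" and \
                self.seizure_count_12m < PSC_SEIZURE_THRESHOLD:
            raise ValueError("PSC requires >= 4 seizures in 12 months")
        if self.seizure_control == "GSC" and \
                self.seizure_count_12m >= PSC_SEIZURE_THRESHOLD:
            raise ValueError("GSC requires < 4 seizures in 12 months")


def _draw_subject(group: str, design: CohortDesign, idx: int,
                  rng: np.random.Generator) -> SubjectRecord:
    cov = design.covariates[group]
    age = float(np.clip(rng.normal(cov.age_mean, cov.age_sd), 18, 90))
    gender = "F" if rng.random() < cov.female_prop else "M"
    is_patient = group in design.seizure_nb
    if is_patient:
        aed = float(max(rng.normal(cov.aed_mean, cov.aed_sd), 0.1))
        syndrome = "FE" if rng.random() < cov.fe_proportion else "IGE"
        nb_n, nb_p = design.seizure_nb[group]
        draw = int(rng.negative_binomial(nb_n, nb_p))
        if group == "GSC":
            count = min(draw, PSC_SEIZURE_THRESHOLD - 1)
        else:
            count = PSC_SEIZURE_THRESHOLD + draw
        control = group
    else:
        aed, syndrome, control, count = 0.0, "none", "none", 0
    return SubjectRecord(
        subject_id=f"{group}{idx + 1:03d}", group="patient" if is_patient
        else "HS", syndrome=syndrome, seizure_control=control, age=age,
        gender=gender, aed_load=aed, seizure_count_12m=count)


def generate_cohort(design: CohortDesign,
                    layout: MontageLayout | None = None
                    ) -> tuple[list[EEGSegment], pd.DataFrame]:
    """Generate one segment and one covariate row per subject.

    Per-subject oscillators jitter around the group spec (peak frequency
    normal with sd ``peak_freq_sd``, amplitude lognormal with coefficient
    of variation ``amplitude_cv``); the true per-subject peak is recorded
    in the extra ``alpha_peak_hz`` column.  Fully reproducible from
    ``design.seed``.
    """
    if layout is None:
        layout = standard_1020_layout()
    root = np.random.SeedSequence(design.seed)
    segments: list[EEGSegment] = []
    rows: list[dict] = []
    sigma = float(np.sqrt(np.log1p(design.amplitude_cv ** 2)))
    for group in design.n_per_group:
        n = design.n_per_group[group]
        osc0 = design.group_oscillators[group]
        for i, child in enumerate(root.spawn(n)):
            rng = np.random.default_rng(child)
            rec = _draw_subject(group, design, i, rng)
            peak = float(np.clip(
                rng.normal(osc0.peak_freq, design.peak_freq_sd), 3.0, 19.0))
            amp = osc0.amplitude * float(
                np.exp(rng.normal(-sigma ** 2 / 2, sigma)))
            osc = replace(osc0, peak_freq=peak, amplitude=amp)
            seg_seed = int(child.generate_state(1)[0] >> 1)
            segments.append(generate_segment(
                osc, design.noise, layout, design.duration, design.fs,
                seed=seg_seed))
            row = {k: getattr(rec, k) for k in COHORT_COLUMNS}
            row["cohort_group"] = group  # HS / GSC / PSC stratum
            row["alpha_peak_hz"] = peak
            rows.append(row)
    return segments, pd.DataFrame(rows)
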