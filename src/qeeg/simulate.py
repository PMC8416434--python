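"""Synthetic resting-state EEG cohorts with controllable group effects.

Each channel is a sum of six band-limited Gaussian oscillators (white
noise band-pass filtered with a 4th-order Butterworth, normalised to a
target RMS amplitude in microvolts), a 1/f (pink) background, and
independent sensor noise. Group effects are expressed exactly in the
feature space the analysis measures:

* power effects multiply a (channel, band) oscillator amplitude in the
  case group, so the case/control band-power ratio is the squared
  multiplier;
* coupling effects add a shared band-limited latent source with weight w
  to both channels of a pair, raising their band coherence monotonically
  with w (closed form approximately (w^2 / (1 + w^2 + r))^2 with r the
  in-band background-to-oscillator power ratio).

Covariates follow the clinical cohort the generator emulates: the
control distributions default to a healthy-control profile (age
25.72 +/- 4.55 y, 63.2 % male, education 14.91 +/- 2.06 y, IQ
116.24 +/- 10.94) and case groups override them via presets (e.g. the
schizophrenia-like preset draws IQ from 89.62 +/- 17.51). Covariates are
independent of the EEG effects unless an IQ-power coupling is requested,
so feature-recovery tests are clean by default.

Between-subject variability enters as independent log-normal jitter of
each (channel, band) oscillator amplitude; this is what limits
single-feature effect sizes and keeps classification nontrivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ValidationError
from .montage import DEFAULT_MONTAGE, ChannelMontage
from .recording import Recording, save_recording_csv
from .spectral import BAND_BY_NAME, DEFAULT_BANDS

#: Baseline oscillator RMS amplitudes, microvolts: eyes-closed resting EEG
#: with the posterior-dominant alpha strongest and fast activity weakest.
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "delta": 6.0,
    "theta": 4.0,
    "alpha": 8.0,
    "beta": 3.0,
    "high_beta": 1.5,
    "gamma": 1.0,
}

#: Healthy-control covariate profile: (mean, SD) or male proportion.
HC_COVARIATES = {
    "age": (25.72, 4.55),
    "education": (14.91, 2.06),
    "iq": (116.24, 10.94),
    "male_p": 0.632,
}

#: Case covariate presets keyed by clinical group.
COVARIATE_PRESETS: dict[str, dict] = {
    "healthy_control": dict(HC_COVARIATES),
    "schizophrenia": {"age": (31.73, 12.10), "education": (12.84, 2.95), "iq": (89.62, 17.51), "male_p": 0.556},
    "depressive": {"age": (31.26, 13.23), "education": (13.05, 2.51), "iq": (101.85, 15.28), "male_p": 0.548},
    "bipolar": {"age": (29.71, 11.01), "education": (14.11, 2.21), "iq": (100.81, 16.98), "male_p": 0.627},
    "anxiety": {"age": (29.01, 10.56), "education": (13.14, 2.42), "iq": (98.31, 16.31), "male_p": 0.738},
    "obsessive_compulsive": {"age": (28.48, 9.83), "education": (13.93, 2.33), "iq": (107.80, 15.24), "male_p": 0.826},
    "addictive": {"age": (29.63, 10.89), "education": (13.23, 2.53), "iq": (103.88, 16.19), "male_p": 0.882},
    "trauma_stress": {"age": (36.09, 13.82), "education": (13.57, 2.45), "iq": (98.89, 15.86), "male_p": 0.344},
}

#: Posterior (centro-parieto-occipital) channels targeted by the
#: alpha-power recovery preset.
ALPHA_EFFECT_CHANNELS: tuple[str, ...] = ("Cz", "P7", "P3", "Pz", "P4", "P8", "O1", "O2")


@dataclass(frozen=True)
class EffectSpec:
    """Group-difference structure applied to the case group."""

    power_effects: tuple[tuple[str, str, float], ...] = ()  # (channel, band, amplitude multiplier)
    coupling_effects: tuple[tuple[tuple[str, str], str, float], ...] = ()  # (pair, band, weight)
    covariate_shift: dict = field(default_factory=dict)  # e.g. {"iq": (89.62, 17.51)}
    iq_power_slope: float = 0.0  # log-amplitude per IQ z-score; couples EEG to IQ

    def validate(self, montage: ChannelMontage = DEFAULT_MONTAGE) -> None:
        labels = {l.upper() for l in montage.labels}
        for ch, band, mult in self.power_effects:
            if ch.upper() not in labels:
                raise ValidationError(f"power effect on unknown channel {ch!r}")
            if band not in BAND_BY_NAME:
                raise ValidationError(f"power effect on unknown band {band!r}")
            if not mult > 0:
                raise ValidationError("power multiplier must be > 0")
        for (x, y), band, w in self.coupling_effects:
            if x.upper() not in labels or y.upper() not in labels:
                raise ValidationError(f"coupling effect on unknown pair ({x}, {y})")
            if band not in BAND_BY_NAME:
                raise ValidationError(f"coupling effect on unknown band {band!r}")
            if w < 0:
                raise ValidationError("coupling weight must be >= 0")


EFFECT_PRESETS: dict[str, EffectSpec] = {
    "null": EffectSpec(),
    "alpha_power": EffectSpec(
        power_effects=tuple((ch, "alpha", 1.5) for ch in ALPHA_EFFECT_CHANNELS)
    ),
    "schizophrenia_like": EffectSpec(
        power_effects=tuple((ch, "alpha", 1.5) for ch in ALPHA_EFFECT_CHANNELS),
        covariate_shift=COVARIATE_PRESETS["schizophrenia"],
    ),
    "alpha_coupling": EffectSpec(
        coupling_effects=(
            (("O1", "O2"), "alpha", 1.0),
            (("P3", "P4"), "alpha", 1.0),
            (("O1", "P3"), "alpha", 1.0),
            (("O2", "P4"), "alpha", 1.0),
        )
    ),
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation parameters."""

    n_cases: int = 60
    n_controls: int = 60
    duration_s: float = 60.0
    rate: float = 128.0
    band_amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES))
    background_1f_scale: float = 5.0  # microvolts RMS of the pink background
    sensor_noise_sd: float = 2.0  # microvolts
    amplitude_jitter_sigma: float = 0.5  # log-normal sigma per (channel, band)
    seed: int = 0
    montage: ChannelMontage = DEFAULT_MONTAGE

    def validate(self) -> None:
        if self.duration_s < 60:
            raise ValidationError("duration_s must be >= 60")
        if any(v < 0 for v in self.band_amplitudes.values()):
            raise ValidationError("band amplitudes must be >= 0")
        if self.background_1f_scale < 0 or self.sensor_noise_sd < 0:
            raise ValidationError("noise scales must be >= 0")


def _soft_limit(x: np.ndarray, knee: float = 60.0, headroom: float = 20.0) -> np.ndarray:
    """Smooth amplitude saturation above ``knee`` microvolts.

    Identity below the knee; beyond it amplitudes compress toward
    knee + headroom (< the 100 uV rejection threshold), emulating the
    bounded dynamic range of scalp EEG. At the default scales fewer than
    one sample per recording reaches the knee, so spectra are unaffected,
    but clean synthetic records never trip the artifact rejector -
    rejection behaviour is exercised with explicitly injected spikes.
    """
    over = np.abs(x) > knee
    if not over.any():
        return x
    out = x.copy()
    out[over] = np.sign(x[over]) * (knee + headroom * np.tanh((np.abs(x[over]) - knee) / headroom))
    return out


def _unit_rms(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


_RESPONSE_CACHE: dict[tuple, np.ndarray] = {}


def _band_response(band_name: str, n: int, rate: float, order: int = 4) -> np.ndarray:
    """Magnitude response of the band's Butterworth band-pass on the rfft grid."""
    key = (band_name, n, rate, order)
    h = _RESPONSE_CACHE.get(key)
    if h is None:
        b = BAND_BY_NAME[band_name]
        sos = sps.butter(order, [b.low, b.high], btype="bandpass", fs=rate, output="sos")
        freqs = np.fft.rfftfreq(n, d=1.0 / rate)
        _, resp = sps.sosfreqz(sos, worN=freqs, fs=rate)
        h = np.abs(resp)
        _RESPONSE_CACHE[key] = h
    return h


def _filtered_noise(
    rng: np.random.Generator, band_name: str, shape: tuple, n: int, rate: float, order: int = 4
) -> np.ndarray:
    """Band-limited unit-RMS Gaussian noise.

    White Gaussian noise shaped in the frequency domain by the magnitude
    response of a Butterworth band-pass (default 4th order) - the
    steady-state equivalent of filtering, without start-up transients.
    """
    h = _band_response(band_name, n, rate, order)
    white = rng.standard_normal(shape[:-1] + (n,))
    out = np.fft.irfft(np.fft.rfft(white, axis=-1) * h, n=n, axis=-1)
    return _unit_rms(out)


def _pink_noise(rng: np.random.Generator, shape: tuple, n: int) -> np.ndarray:
    """1/f-power spectrally shaped Gaussian noise, unit RMS."""
    white = rng.standard_normal(shape[:-1] + (n,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** -0.5  # amplitude exponent 0.5 <-> power exponent 1
    scale[0] = 0.0
    return _unit_rms(np.fft.irfft(spec * scale, n=n, axis=-1))


def generate_subject(
    config: CohortConfig,
    effects: EffectSpec | None,
    group: str,
    subject_seed,
    subject_id: str = "sub",
    iq_z: float = 0.0,
) -> Recording:
    """Generate one subject's recording; deterministic given the seed.

    ``group`` is "case" or "control"; effects apply to cases only.
    ``iq_z`` feeds the optional IQ-power coupling.
    """
    config.validate()
    effects = effects or EffectSpec()
    effects.validate(config.montage)
    rng = np.random.default_rng(subject_seed)
    n = int(round(config.duration_s * config.rate))
    C = len(config.montage)
    ch_index = {l.upper(): i for i, l in enumerate(config.montage.labels)}
    is_case = group == "case"

    # per-(channel, band) amplitudes with independent log-normal jitter
    amps = np.empty((C, len(DEFAULT_BANDS)))
    for bi, band in enumerate(DEFAULT_BANDS):
        base = config.band_amplitudes.get(band.name, 0.0)
        jitter = np.exp(config.amplitude_jitter_sigma * rng.standard_normal(C))
        amps[:, bi] = base * jitter
    if is_case:
        for ch, band, mult in effects.power_effects:
            bi = [b.name for b in DEFAULT_BANDS].index(band)
            amps[ch_index[ch.upper()], bi] *= mult
    if effects.iq_power_slope:
        amps *= np.exp(effects.iq_power_slope * iq_z)

    data = np.zeros((C, n))
    for bi, band in enumerate(DEFAULT_BANDS):
        if not np.any(amps[:, bi] > 0):
            continue
        osc = _filtered_noise(rng, band.name, (C, n), n, config.rate)
        data += amps[:, bi : bi + 1] * osc
        if is_case:
            for (x, y), bname, w in effects.coupling_effects:
                if bname != band.name or w == 0:
                    continue
                shared = _filtered_noise(rng, band.name, (n,), n, config.rate)
                base = config.band_amplitudes.get(band.name, 0.0)
                for ch in (x, y):
                    data[ch_index[ch.upper()]] += w * base * shared
    if config.background_1f_scale > 0:
        data += config.background_1f_scale * _pink_noise(rng, (C, n), n)
    if config.sensor_noise_sd > 0:
        data += config.sensor_noise_sd * rng.standard_normal((C, n))
    return Recording(subject_id, _soft_limit(data), config.rate, config.montage)


def _draw_covariates(rng: np.random.Generator, n: int, profile: dict) -> pd.DataFrame:
    age = np.clip(rng.normal(*profile["age"], size=n), 18, 70)
    sex = (rng.random(n) < profile["male_p"]).astype(int)  # male=1, female=0
    edu = np.clip(rng.normal(*profile["education"], size=n), 6, 22)
    iq = rng.normal(*profile["iq"], size=n)
    return pd.DataFrame({"age": age, "sex": sex, "education": edu, "iq": iq})


def generate_cohort(
    config: CohortConfig,
    effects: EffectSpec | None = None,
) -> tuple[list[Recording], pd.DataFrame]:
    """Generate a labelled cohort: recordings plus covariate table.

    Returns the recordings (cases first) and a covariate DataFrame
    indexed by subject id with columns age, sex, education, iq, label
    (case=1, control=0). Byte-identical for identical seeds.
    """
    config.validate()
    effects = effects or EffectSpec()
    effects.validate(config.montage)
    if config.n_cases < 1 or config.n_controls < 1:
        raise ValidationError("both groups need at least one subject")
    root = np.random.SeedSequence(config.seed)
    cov_ss, subj_ss = root.spawn(2)
    cov_rng = np.random.default_rng(cov_ss)

    case_profile = dict(HC_COVARIATES)
    case_profile.update(effects.covariate_shift)
    covs_case = _draw_covariates(cov_rng, config.n_cases, case_profile)
    covs_ctrl = _draw_covariates(cov_rng, config.n_controls, HC_COVARIATES)
    covs = pd.concat([covs_case, covs_ctrl], ignore_index=True)
    covs["label"] = [1] * config.n_cases + [0] * config.n_controls
    ids = [f"case_{i:03d}" for i in range(config.n_cases)] + [
        f"ctrl_{i:03d}" for i in range(config.n_controls)
    ]
    covs.index = pd.Index(ids, name="subject_id")

    iq_mu, iq_sd = case_profile["iq"]
    hc_mu, hc_sd = HC_COVARIATES["iq"]
    recs = []
    seeds = subj_ss.spawn(len(ids))
    for k, sid in enumerate(ids):
        group = "case" if covs["label"].iloc[k] == 1 else "control"
        mu, sd = (iq_mu, iq_sd) if group == "case" else (hc_mu, hc_sd)
        iq_z = (covs["iq"].iloc[k] - mu) / sd
        recs.append(
            generate_subject(config, effects, group, seeds[k], subject_id=sid, iq_z=iq_z)
        )
    return recs, covs


def save_cohort(recs: list[Recording], covs: pd.DataFrame, out_dir) -> None:
    """Write one CSV recording per subject plus a manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in recs:
        save_recording_csv(rec, out / f"{rec.subject_id}.csv")
    covs.to_csv(out / "manifest.csv")
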