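"""Sliding-window FFT cross-spectra, band absolute power and coherence.

The estimator follows the classic clinical-QEEG recipe: 2-s (256-point at
128 samples/s) Hann-tapered FFT windows advanced in 64-point steps (75 %
overlap), accumulating per-frequency-bin sums of the cosine/sine
coefficient products across the N windows of the artifact-free record.
With a(x), b(x) the cosine/sine coefficients of channel x and u(y), v(y)
those of channel y at frequency f, the accumulated sums are

    auto_power(x, f)   = sum_N a(x)^2 + b(x)^2
    cross_real(x,y,f)  = sum_N a(x)u(y) + b(x)v(y)
    cross_imag(x,y,f)  = sum_N a(x)v(y) - b(x)u(y)

and the magnitude-squared coherence per bin is

    coh(f) = (cross_real^2 + cross_imag^2) / (auto_power(x) * auto_power(y)).

Band values average coh(f) over the band's 0.5-Hz bins; band absolute
power sums auto_power over the band, normalised (Parseval, taper power
correction) so that summing every band recovers the signal variance in
the analysis range, in microvolts squared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, UndefinedCoherenceError, ValidationError
from .montage import ChannelMontage
from .recording import Recording


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: low must be < high")

    def bin_mask(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.low) & (freqs < self.high)


#: The six canonical clinical bands. Shared edges belong to the upper band.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 25.0),
    BandDefinition("high_beta", 25.0, 30.0),
    BandDefinition("gamma", 30.0, 40.0),
)

BAND_BY_NAME: dict[str, BandDefinition] = {b.name: b for b in DEFAULT_BANDS}


@dataclass(frozen=True)
class CrossSpectrum:
    """Accumulated sliding-window cross-spectral sums for one recording.

    ``auto_power`` has shape (C, F); ``cross_real``/``cross_imag`` have
    shape (C, C, F) with only the upper triangle (i < j) populated.
    ``norm`` is the power normalisation 2 / (window_len * sum(taper^2))
    that converts per-bin accumulated auto-power sums (divided by
    n_windows) into microvolts-squared per bin.
    """

    montage: ChannelMontage
    bin_freqs: np.ndarray
    n_windows: int
    auto_power: np.ndarray
    cross_real: np.ndarray
    cross_imag: np.ndarray
    norm: float

    def channel_index(self, label: str) -> int:
        return self.montage.index(label)

    def to_table(self, subject_id: str = ""):
        """Long-format view (subject, pair-or-channel, bin_Hz, statistic,
        value) of the accumulated sums, for inspection and export."""
        import pandas as pd

        labels = self.montage.labels
        rows = []
        for c, label in enumerate(labels):
            for f, freq in enumerate(self.bin_freqs):
                rows.append((subject_id, label, freq, "auto_power", self.auto_power[c, f]))
        for i, j in ((i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))):
            name = f"{labels[i]}_{labels[j]}"
            for f, freq in enumerate(self.bin_freqs):
                rows.append((subject_id, name, freq, "cross_real", self.cross_real[i, j, f]))
                rows.append((subject_id, name, freq, "cross_imag", self.cross_imag[i, j, f]))
        return pd.DataFrame(
            rows, columns=["subject", "element", "bin_hz", "statistic", "value"]
        )


def sliding_cross_spectrum(
    rec: Recording,
    window_len: int = 256,
    step: int = 64,
    taper: str = "hann",
    fmin: float = 0.5,
    fmax: float = 40.0,
) -> CrossSpectrum:
    """Accumulate Hann-tapered FFT cross-spectra over sliding windows.

    Windows advance in ``step``-sample increments within each accepted
    (artifact-free) span of the recording; the sliding sequence restarts
    at each span so no window straddles a rejected epoch. Bins at
    ``fmin`` .. ``fmax`` (inclusive, spacing rate/window_len) are kept.
    """
    if window_len & (window_len - 1):
        raise ValueError("window_len must be a power of two")
    if step > window_len:
        raise ValueError("step must be <= window_len")
    if taper in ("hann", "boxcar"):
        # periodic (DFT-even) window, the spectral-estimation convention
        from scipy.signal import get_window

        w = get_window(taper, window_len, fftbins=True)
    else:
        raise ValueError(f"unknown taper {taper!r}")

    freqs = np.fft.rfftfreq(window_len, d=1.0 / rec.rate)
    keep = (freqs >= fmin - 1e-9) & (freqs <= fmax + 1e-9)
    bin_freqs = freqs[keep]

    segments = []
    for a, b in rec.spans:
        span = rec.data[:, a:b]
        n = span.shape[1]
        if n < window_len:
            continue
        n_win = (n - window_len) // step + 1
        idx = np.arange(window_len)[None, :] + step * np.arange(n_win)[:, None]
        # (n_win, C, window_len) tapered windows for this span
        segments.append(span[:, idx].transpose(1, 0, 2) * w)
    if not segments:
        raise InsufficientDataError(
            f"no accepted span holds a full {window_len}-sample window"
        )
    wins = np.concatenate(segments, axis=0)
    n_windows = wins.shape[0]

    F = np.fft.rfft(wins, axis=2)[:, :, keep]  # (N, C, F) complex
    auto = np.einsum("ncf,ncf->cf", F.real, F.real) + np.einsum(
        "ncf,ncf->cf", F.imag, F.imag
    )
    S = np.einsum("ncf,ndf->cdf", F, F.conj())  # cross-spectral sums
    C = len(rec.montage)
    iu, ju = np.triu_indices(C, k=1)
    cross_real = np.zeros((C, C, bin_freqs.size))
    cross_imag = np.zeros_like(cross_real)
    cross_real[iu, ju] = S.real[iu, ju]
    cross_imag[iu, ju] = S.imag[iu, ju]

    norm = 2.0 / (window_len * np.sum(w**2))
    return CrossSpectrum(
        montage=rec.montage,
        bin_freqs=bin_freqs,
        n_windows=n_windows,
        auto_power=auto,
        cross_real=cross_real,
        cross_imag=cross_imag,
        norm=norm,
    )


def _band_mask(cs: CrossSpectrum, band: BandDefinition) -> np.ndarray:
    if band.low < cs.bin_freqs[0] - 1e-9 or band.high > cs.bin_freqs[-1] + 0.5 + 1e-9:
        raise ValidationError(
            f"band {band.name} [{band.low}, {band.high}) outside the "
            f"{cs.bin_freqs[0]}-{cs.bin_freqs[-1]} Hz grid"
        )
    mask = band.bin_mask(cs.bin_freqs)
    if not mask.any():
        raise ValidationError(f"band {band.name} covers no frequency bins")
    return mask


def band_psd(cs: CrossSpectrum, channel: str, band: BandDefinition) -> float:
    """Absolute band power in microvolts squared at one channel.

    Mean over windows of the accumulated auto-power, summed over the
    band's bins and Parseval/taper-normalised: summing all six bands
    approximates the signal variance within 1-40 Hz.
    """
    ci = cs.channel_index(channel)
    mask = _band_mask(cs, band)
    return float(cs.norm * cs.auto_power[ci, mask].sum() / cs.n_windows)


def coherence(
    cs: CrossSpectrum,
    pair: tuple[str, str],
    band: BandDefinition,
    aggregate: str = "mean",
) -> float:
    """Band magnitude-squared coherence for an unordered channel pair.

    With ``aggregate="mean"`` (default) coherence is computed per bin
    from the accumulated cross-spectral sums and averaged (unweighted)
    over the band's bins, preserving the per-frequency form of the
    estimator. ``aggregate="pooled"`` instead pools the sums across the
    band's bins before normalising - a sensitivity-check variant.
    Symmetric in the pair and bounded in [0, 1]. Bins where either
    channel has zero accumulated power are excluded; if that exhausts
    the band the coherence is undefined and an error is raised rather
    than silently returning 0.
    """
    x, y = pair
    i, j = cs.channel_index(x), cs.channel_index(y)
    if i == j:
        raise ValidationError("coherence requires two distinct channels")
    if i > j:
        i, j = j, i
    mask = _band_mask(cs, band)
    denom = cs.auto_power[i, mask] * cs.auto_power[j, mask]
    ok = denom > 0
    if not ok.any():
        raise UndefinedCoherenceError(
            f"zero auto-power over every {band.name} bin for pair ({x}, {y})"
        )
    if aggregate == "pooled":
        cr = cs.cross_real[i, j, mask][ok].sum()
        ci = cs.cross_imag[i, j, mask][ok].sum()
        return float(
            (cr**2 + ci**2)
            / (cs.auto_power[i, mask][ok].sum() * cs.auto_power[j, mask][ok].sum())
        )
    if aggregate != "mean":
        raise ValueError(f"unknown aggregate {aggregate!r}")
    num = cs.cross_real[i, j, mask] ** 2 + cs.cross_imag[i, j, mask] ** 2
    return float(np.mean(num[ok] / denom[ok]))
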