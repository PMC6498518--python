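"""Epoching, multitaper cross-spectra, and PLI/wPLI connectivity.

Recordings are cut into non-overlapping 4-s epochs.  Per frequency band a
tapered FFT is computed for every epoch: a single Hanning taper for the slow
bands (delta, theta) and DPSS multitapers for alpha/beta/gamma, with K =
2*T*W - 1 tapers for half-bandwidth W and epoch length T.  Every
(epoch, taper, in-band frequency bin) triple contributes one complex
cross-spectral observation S_xyt = X_x(f) * conj(X_y(f)) per channel pair.

The connectivity estimators are the phase lag index

    PLI_xy  = | mean_t sgn(imag(S_xyt)) |

and the weighted phase lag index

    wPLI_xy = | sum_t imag(S_xyt) | / sum_t |imag(S_xyt)|

both in [0, 1].  wPLI weights each phase lead/lag by the magnitude of the
imaginary cross-spectrum and ignores zero- and pi-phase-lag coupling, which
makes it robust to volume conduction.  When the denominator is zero (perfect
zero/pi lag or identical channels) wPLI is defined as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numba
import numpy as np
from scipy import fft as _fft
from scipy.signal.windows import dpss as dpss_windows

__all__ = [
    "EEGRecording",
    "EpochedData",
    "BandSpec",
    "CrossSpectralObservations",
    "ConnectivityMatrix",
    "BANDS",
    "segment_epochs",
    "drop_epochs",
    "cross_spectra",
    "pli",
    "wpli",
]


@dataclass
class EEGRecording:
    """A multichannel EEG recording (channels x samples)."""

    subject_id: str
    condition: str
    fs: float
    channel_labels: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("number of labels must match number of rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class EpochedData:
    """Non-overlapping epochs (epochs x channels x samples) of one recording."""

    data: np.ndarray
    fs: float
    epoch_length_s: float
    channel_labels: tuple[str, ...]
    subject_id: str = ""
    condition: str = ""
    dropped: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        expected = int(round(self.fs * self.epoch_length_s))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"samples per epoch {self.data.shape[2]} != round(fs*length) {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band with its taper scheme.

    ``smoothing_hz`` is the multitaper half-bandwidth W; it is required for
    DPSS bands and must be absent for Hanning bands.
    """

    name: str
    f_lo: float
    f_hi: float
    taper: str = "hanning"
    smoothing_hz: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("need 0 < f_lo < f_hi")
        if self.taper not in ("hanning", "dpss"):
            raise ValueError(f"unknown taper {self.taper!r}")
        if self.taper == "dpss" and not self.smoothing_hz:
            raise ValueError("dpss taper requires smoothing_hz")
        if self.taper == "hanning" and self.smoothing_hz is not None:
            raise ValueError("hanning taper takes no smoothing_hz")

    def n_tapers(self, epoch_length_s: float) -> int:
        """Number of tapers: 1 for Hanning, 2*T*W - 1 for DPSS."""
        if self.taper == "hanning":
            return 1
        k = int(round(2 * epoch_length_s * float(self.smoothing_hz) - 1))
        return max(k, 1)


#: Default band presets.  Methods-table beta is 13-30 Hz; the alternative
#: ``beta_low`` preset (13-18 Hz) matches the band the results are reported
#: in.  DPSS half-bandwidths: alpha +-1 Hz, beta +-2 Hz, gamma +-4 Hz.
BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 2.0, 4.0, "hanning"),
    "theta": BandSpec("theta", 4.0, 7.0, "hanning"),
    "alpha": BandSpec("alpha", 7.0, 13.0, "dpss", 1.0),
    "beta": BandSpec("beta", 13.0, 30.0, "dpss", 2.0),
    "beta_low": BandSpec("beta_low", 13.0, 18.0, "dpss", 2.0),
    "gamma": BandSpec("gamma", 30.0, 60.0, "dpss", 4.0),
}


@numba.njit(cache=False)
def _pair_imag_sums(A, B, iu, ju, with_sign):  # pragma: no cover - jitted
    """Streaming sums of imag(x_i conj(x_j)) = B_i*A_j - A_i*B_j per pair."""
    n_pairs = iu.size
    n_cols = A.shape[1]
    p_im = np.zeros(n_pairs)
    p_abs = np.zeros(n_pairs)
    p_sgn = np.zeros(n_pairs)
    for p in range(n_pairs):
        i, j = iu[p], ju[p]
        s = 0.0
        sa = 0.0
        sg = 0.0
        for c in range(n_cols):
            v = B[i, c] * A[j, c] - A[i, c] * B[j, c]
            s += v
            sa += abs(v)
            if with_sign:
                if v > 0:
                    sg += 1.0
                elif v < 0:
                    sg -= 1.0
        p_im[p] = s
        p_abs[p] = sa
        p_sgn[p] = sg
    return p_im, p_abs, p_sgn


@dataclass
class CrossSpectralObservations:
    """Cross-spectral observations of one epoched recording in one band.

    Stored as tapered Fourier coefficients ``coeffs`` with shape
    (epochs*tapers, channels, in-band bins); the implied observation index is
    t = (epoch, taper, bin).  ``from_observations`` builds the container from
    explicit per-observation cross-spectral matrices instead (used for small
    fixtures and oracle tests).
    """

    band: BandSpec
    channel_labels: tuple[str, ...]
    coeffs: np.ndarray | None = None
    explicit: np.ndarray | None = None  # (n_obs, n_ch, n_ch) complex
    freqs: np.ndarray = field(default_factory=lambda: np.empty(0))
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        if (self.coeffs is None) == (self.explicit is None):
            raise ValueError("provide exactly one of coeffs or explicit")

    @classmethod
    def from_observations(
        cls,
        obs: np.ndarray,
        band: BandSpec | None = None,
        channel_labels: Sequence[str] | None = None,
    ) -> "CrossSpectralObservations":
        """Build from explicit cross-spectral matrices (n_obs, n_ch, n_ch)."""
        obs = np.asarray(obs, dtype=complex)
        if obs.ndim != 3 or obs.shape[1] != obs.shape[2]:
            raise ValueError("obs must be (n_obs, n_ch, n_ch)")
        if obs.size and not np.allclose(
            obs, np.conj(obs.transpose(0, 2, 1)), atol=1e-9
        ):
            raise ValueError("cross-spectra must satisfy S_yx = conj(S_xy)")
        n_ch = obs.shape[1]
        labels = (
            tuple(channel_labels)
            if channel_labels is not None
            else tuple(f"ch{i}" for i in range(n_ch))
        )
        band = band or BandSpec("adhoc", 1.0, 2.0, "hanning")
        return cls(band=band, channel_labels=labels, explicit=obs)

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def n_observations(self) -> int:
        if self.explicit is not None:
            return self.explicit.shape[0]
        return self.coeffs.shape[0] * self.coeffs.shape[2]

    def iter_cross_spectra(self) -> Iterator[np.ndarray]:
        """Yield cross-spectral matrices (n_ch, n_ch, n_obs_chunk) lazily."""
        if self.explicit is not None:
            yield np.moveaxis(self.explicit, 0, -1)
            return
        # Chunk over the epoch x taper axis, keeping each chunk ~tens of MB.
        n_ch, n_bins = self.coeffs.shape[1], self.coeffs.shape[2]
        chunk = max(1, int(2e6 // max(n_ch * n_ch * n_bins, 1)) or 1)
        for start in range(0, self.coeffs.shape[0], chunk):
            x = self.coeffs[start : start + chunk]  # (c, n_ch, n_bins)
            s = x[:, :, None, :] * np.conj(x[:, None, :, :])
            yield np.moveaxis(s, 0, -1).reshape(n_ch, n_ch, -1)

    def pair_observations(self, i: int, j: int) -> np.ndarray:
        """All S_ijt for one ordered channel pair, as a 1-D complex array."""
        if self.explicit is not None:
            return self.explicit[:, i, j]
        return (self.coeffs[:, i, :] * np.conj(self.coeffs[:, j, :])).ravel()

    def imag_sums(
        self, per_bin: bool = False, with_sign: bool = True
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
        """Accumulate (sum imag, sum |imag|, sum sgn(imag)) over observations.

        With ``per_bin=True`` the sums keep a trailing frequency-bin axis
        (only available for coefficient-backed containers).
        """
        n = self.n_channels
        if per_bin:
            if self.explicit is not None:
                raise ValueError("per-bin sums need coefficient-backed observations")
            n_bins = self.coeffs.shape[2]
            s_im = np.zeros((n, n, n_bins))
            s_abs = np.zeros((n, n, n_bins))
            s_sgn = np.zeros((n, n, n_bins))
            chunk = max(1, int(2e6 // max(n * n * n_bins, 1)) or 1)
            for start in range(0, self.coeffs.shape[0], chunk):
                x = self.coeffs[start : start + chunk]
                im = np.imag(x[:, :, None, :] * np.conj(x[:, None, :, :]))
                s_im += im.sum(axis=0)
                s_abs += np.abs(im).sum(axis=0)
                s_sgn += np.sign(im).sum(axis=0)
            return s_im, s_abs, s_sgn
        if self.explicit is not None:
            im = np.imag(self.explicit)
            return (
                im.sum(axis=0),
                np.abs(im).sum(axis=0),
                np.sign(im).sum(axis=0) if with_sign else None,
            )
        # Work on unique pairs with real arithmetic:
        # imag(x_i conj(x_j)) = Im_i*Re_j - Re_i*Im_j.
        iu, ju = np.triu_indices(n, k=1)
        n_pairs = iu.size
        c = self.coeffs
        A = np.ascontiguousarray(c.real.transpose(1, 0, 2).reshape(n, -1))
        B = np.ascontiguousarray(c.imag.transpose(1, 0, 2).reshape(n, -1))
        p_im, p_abs, p_sgn = _pair_imag_sums(A, B, iu, ju, with_sign)

        def square(v):
            out = np.zeros((n, n))
            out[iu, ju] = v
            return out

        s_im = square(p_im)
        s_im -= s_im.T  # S_yx = conj(S_xy): imaginary part is antisymmetric
        s_abs = square(p_abs)
        s_abs += s_abs.T
        if with_sign:
            s_sgn = square(p_sgn)
            s_sgn -= s_sgn.T
        else:
            s_sgn = None
        return s_im, s_abs, s_sgn


@dataclass
class ConnectivityMatrix:
    """Symmetric connectivity matrix in [0, 1] with zero diagonal."""

    values: np.ndarray
    channel_labels: tuple[str, ...]
    band: str = ""
    condition: str = ""
    subject_id: str = ""
    estimator: str = "wpli"
    n_observations: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if len(self.channel_labels) != v.shape[0]:
            raise ValueError("labels must match matrix size")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12:
            raise ValueError("values must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def segment_epochs(rec: EEGRecording, epoch_length_s: float = 4.0) -> EpochedData:
    """Cut a recording into non-overlapping epochs; drop the trailing partial one."""
    spe = int(round(rec.fs * epoch_length_s))
    n_epochs = rec.data.shape[1] // spe
    if n_epochs < 1:
        raise ValueError(
            f"recording of {rec.duration_s:.2f}s shorter than one "
            f"{epoch_length_s}s epoch"
        )
    cut = rec.data[:, : n_epochs * spe]
    data = cut.reshape(rec.n_channels, n_epochs, spe).transpose(1, 0, 2)
    return EpochedData(
        data=data.copy(),
        fs=rec.fs,
        epoch_length_s=epoch_length_s,
        channel_labels=rec.channel_labels,
        subject_id=rec.subject_id,
        condition=rec.condition,
    )


def drop_epochs(epoched: EpochedData, indices: Sequence[int]) -> EpochedData:
    """Remove epochs by index (e.g. artifact rejection), recording provenance."""
    idx = sorted(set(int(i) for i in indices))
    if any(i < 0 or i >= epoched.n_epochs for i in idx):
        raise IndexError(f"epoch indices out of range: {idx}")
    keep = [i for i in range(epoched.n_epochs) if i not in idx]
    if not keep:
        raise ValueError("cannot drop all epochs")
    return EpochedData(
        data=epoched.data[keep],
        fs=epoched.fs,
        epoch_length_s=epoched.epoch_length_s,
        channel_labels=epoched.channel_labels,
        subject_id=epoched.subject_id,
        condition=epoched.condition,
        dropped=epoched.dropped + tuple(idx),
    )


def _tapers(band: BandSpec, n_samples: int, epoch_length_s: float) -> np.ndarray:
    """Taper matrix (n_tapers, n_samples), each taper with unit power."""
    if band.taper == "hanning":
        w = np.hanning(n_samples)[None, :]
    else:
        nw = epoch_length_s * float(band.smoothing_hz)
        k = band.n_tapers(epoch_length_s)
        w = dpss_windows(n_samples, nw, Kmax=k)
    return w / np.sqrt(np.sum(w**2, axis=1, keepdims=True))


def cross_spectra(epoched: EpochedData, band: BandSpec) -> CrossSpectralObservations:
    """Tapered FFT cross-spectral observations for all in-band frequency bins."""
    fs = epoched.fs
    if band.f_hi >= fs / 2:
        raise ValueError(f"band {band.name} exceeds Nyquist ({fs/2} Hz)")
    spe = epoched.data.shape[2]
    freqs = np.fft.rfftfreq(spe, d=1.0 / fs)
    in_band = np.flatnonzero((freqs >= band.f_lo) & (freqs <= band.f_hi))
    if in_band.size == 0:
        raise ValueError(f"no FFT bins inside band {band.name}")
    tapers = _tapers(band, spe, epoched.epoch_length_s)
    k = tapers.shape[0]
    n_ep, n_ch = epoched.n_epochs, epoched.n_channels
    # Per-epoch mean removal before tapering.
    demeaned = (epoched.data - epoched.data.mean(axis=2, keepdims=True)).astype(
        np.float32
    )
    tapers32 = tapers.astype(np.float32)
    coeffs = np.empty((n_ep * k, n_ch, in_band.size), dtype=np.complex64)
    for e in range(n_ep):
        tapered = demeaned[e][None, :, :] * tapers32[:, None, :]  # (k, ch, spe)
        spec = _fft.rfft(tapered, axis=2)[:, :, in_band]
        coeffs[e * k : (e + 1) * k] = spec
    return CrossSpectralObservations(
        band=band,
        channel_labels=epoched.channel_labels,
        coeffs=coeffs,
        freqs=freqs[in_band],
        subject_id=epoched.subject_id,
        condition=epoched.condition,
    )


def _finalize(values: np.ndarray, obs: CrossSpectralObservations, estimator: str) -> ConnectivityMatrix:
    values = np.clip(values, 0.0, 1.0)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(
        values=values,
        channel_labels=obs.channel_labels,
        band=obs.band.name,
        condition=obs.condition,
        subject_id=obs.subject_id,
        estimator=estimator,
        n_observations=obs.n_observations,
    )


def pli(obs: CrossSpectralObservations) -> ConnectivityMatrix:
    """Phase lag index: |mean_t sgn(imag(S_xyt))| per channel pair."""
    if obs.n_observations == 0:
        raise ValueError("no cross-spectral observations")
    _, _, s_sgn = obs.imag_sums()
    values = np.abs(s_sgn) / obs.n_observations
    return _finalize(values, obs, "pli")


def wpli(obs: CrossSpectralObservations, per_bin: bool = False) -> ConnectivityMatrix:
    """Weighted phase lag index per channel pair.

    By default a single ratio is formed over all pooled observations
    (epoch x taper x in-band bin); ``per_bin=True`` computes a wPLI per
    frequency bin and averages the per-bin values across the band instead.
    Pairs whose imaginary cross-spectra vanish identically get wPLI 0.
    """
    if obs.n_observations == 0:
        raise ValueError("no cross-spectral observations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if per_bin:
            s_im, s_abs, _ = obs.imag_sums(per_bin=True)
            per = np.where(s_abs > 0, np.abs(s_im) / np.where(s_abs > 0, s_abs, 1.0), 0.0)
            values = per.mean(axis=2)
        else:
            s_im, s_abs, _ = obs.imag_sums(with_sign=False)
            values = np.where(s_abs > 0, np.abs(s_im) / np.where(s_abs > 0, s_abs, 1.0), 0.0)
    return _finalize(values, obs, "wpli")
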