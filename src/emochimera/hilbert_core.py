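"""Analytic-signal decomposition of audio into envelope and temporal fine structure.

A real signal :math:`x(t)` has the analytic signal
:math:`A(t) = x(t) + i\\,\\mathcal{H}[x](t)` where :math:`\\mathcal{H}` is the
Hilbert transform.  Its magnitude :math:`|A(t)|` is the (Hilbert) envelope
(ENV) — the slowly varying amplitude — and the cosine of its instantaneous
phase, :math:`\\cos\\varphi(t)` with :math:`\\varphi = \\operatorname{atan2}
(\\mathrm{Im}\\,A, \\mathrm{Re}\\,A)`, is the temporal fine structure (TFS) —
the rapid oscillation carrying pitch information.  By construction
``envelope * fine_structure`` reconstructs the input exactly, which is the
identity the chimera-synthesis pipeline relies on.

The module also holds the ``Waveform`` container and WAV file I/O used
throughout the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal
from scipy.io import wavfile

logger = logging.getLogger("emochimera")

#: Emotion categories a stimulus may carry.
LABELS = ("happy", "sad", "none")

#: Upper analysis-band edge (Hz); input rates must Nyquist-cover it.
TOP_BAND_EDGE_HZ = 8820.0


class InvalidInputError(ValueError):
    """Raised when a waveform violates its invariants."""


class InvalidParameterError(ValueError):
    """Raised when a processing parameter is out of range."""


@dataclass(frozen=True)
class Waveform:
    """A labelled mono audio signal.

    Parameters
    ----------
    samples : ndarray
        Real-valued samples, nominal full scale ±1.
    rate : float
        Sampling rate in Hz; must exceed twice the top band edge (8820 Hz).
    label : str
        Emotion category, one of ``happy``, ``sad``, ``none``.
    id : str
        Stimulus identifier.
    """

    samples: np.ndarray
    rate: float
    label: str = "none"
    id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size == 0:
            raise InvalidInputError("waveform must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise InvalidInputError("waveform contains non-finite samples")
        if self.rate <= 2 * TOP_BAND_EDGE_HZ:
            raise InvalidInputError(
                f"rate {self.rate} Hz does not Nyquist-cover {TOP_BAND_EDGE_HZ} Hz"
            )
        if self.label not in LABELS:
            raise InvalidInputError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    def scaled(self, gain: float) -> "Waveform":
        return replace(self, samples=self.samples * gain)


@dataclass(frozen=True)
class AnalyticDecomposition:
    """Envelope |A(t)| and fine structure cos φ(t) of one signal.

    Invariants: ``envelope >= 0``, ``|fine_structure| <= 1``, equal lengths.
    ``envelope * fine_structure`` equals the original real signal when the
    envelope has not been smoothed.
    """

    envelope: np.ndarray
    fine_structure: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        env = np.asarray(self.envelope, dtype=np.float64)
        tfs = np.asarray(self.fine_structure, dtype=np.float64)
        object.__setattr__(self, "envelope", env)
        object.__setattr__(self, "fine_structure", tfs)
        if env.shape != tfs.shape:
            raise InvalidInputError("envelope and fine_structure must share a shape")

    def reconstruct(self) -> np.ndarray:
        """Return ``envelope * fine_structure`` (the real signal, pre-smoothing)."""
        return self.envelope * self.fine_structure


def analytic_signal(w: Waveform) -> np.ndarray:
    """Complex analytic signal ``x + i·H[x]`` of a waveform.

    The real part is the input bit-for-bit; the imaginary part is the
    Hilbert transform computed over the whole record (no windowing — edge
    transients are negligible for multi-second stimuli).
    """
    # keep the real part exactly the input (the FFT round trip perturbs it)
    return w.samples + 1j * scipy.signal.hilbert(w.samples).imag


def extract_env_tfs(w: Waveform) -> AnalyticDecomposition:
    """Split a waveform into Hilbert envelope (ENV) and fine structure (TFS).

    ``fine_structure`` is cos of atan2(imag, real), computed stably as
    ``Re A / |A|``; where the envelope vanishes the fine structure is set
    to 0 so the reconstruction identity still holds.
    """
    a = analytic_signal(w)
    env = np.abs(a)
    with np.errstate(invalid="ignore", divide="ignore"):
        tfs = np.where(env > 0, a.real / np.where(env > 0, env, 1.0), 0.0)
    np.clip(tfs, -1.0, 1.0, out=tfs)
    return AnalyticDecomposition(envelope=env, fine_structure=tfs, rate=w.rate)


def smooth_envelope(
    d: AnalyticDecomposition, cutoff: float, order: int = 4
) -> AnalyticDecomposition:
    """Low-pass the envelope with a zero-phase Butterworth filter.

    Used only to reproduce display-style smoothed envelopes (e.g. a 1 Hz or
    40 Hz modulator trace); chimera synthesis uses the raw envelope.  The
    filter is order ``order`` applied forward and backward (zero phase,
    effective order ``2*order``).  The fine structure is untouched.
    """
    if not (0 < cutoff < d.rate / 2):
        raise InvalidParameterError(
            f"cutoff must lie in (0, rate/2) = (0, {d.rate / 2}); got {cutoff}"
        )
    sos = scipy.signal.butter(order, cutoff, btype="low", fs=d.rate, output="sos")
    smoothed = scipy.signal.sosfiltfilt(sos, d.envelope)
    return AnalyticDecomposition(
        envelope=smoothed, fine_structure=d.fine_structure, rate=d.rate
    )


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------

def read_wav(path, label: str = "none", id: str | None = None) -> Waveform:
    """Read a WAV file (PCM 16/24/32-bit or float) as a mono float Waveform.

    Integer PCM is rescaled to ±1 full scale.  Stereo files are downmixed by
    channel averaging with a logged warning.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # wavfile chunk warnings
        rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        logger.warning("downmixing %d-channel file %s to mono by averaging", data.shape[1], path)
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    stem = str(path).rsplit("/", 1)[-1]
    return Waveform(samples=data, rate=float(rate), label=label,
                    id=id if id is not None else stem.rsplit(".", 1)[0])


def write_wav(path, w: Waveform) -> None:
    """Write a waveform as 32-bit float WAV (deterministic byte output)."""
    wavfile.write(str(path), int(w.rate), w.samples.astype(np.float32))
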