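"""Time-frequency scalogram images from the analytic Morse-wavelet CWT.

The CNN-facing representation of a record is a single 1-D series — ten
seconds of the eight independent leads (I, II, V1–V6) concatenated with
their median beats — transformed with a continuous wavelet transform built
on the generalized Morse wavelet, rendered as the magnitude (scalogram) and
resized to a 224 x 224 x 3 colour image.

The generalized Morse wavelet family is defined in the frequency domain as

    Psi(w)  ~  w^beta * exp(-w^gamma),   w > 0  (exactly analytic),

parameterised by the symmetry ``gamma`` and the time-bandwidth product
``P^2 = beta * gamma``.  The defaults gamma = 3, P^2 = 60 (hence beta = 20)
give a nearly symmetric, tightly localised wavelet; scales are geometric
with 12 voices per octave.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .io import ECGRecord
from .preprocessing import MedianBeat

INPUT_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")
IMAGE_SIZE = 224
DEFAULT_GAMMA = 3.0
DEFAULT_TIME_BANDWIDTH = 60.0
DEFAULT_VOICES = 12


@dataclass
class ScalogramImage:
    """224 x 224 x 3 uint8 scalogram with its provenance."""

    pixels: np.ndarray
    source_id: str = ""
    frequencies_hz: np.ndarray = field(default_factory=lambda: np.array([]))
    colormap_name: str = "jet"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
            raise ValueError(f"scalogram image must be {IMAGE_SIZE}x{IMAGE_SIZE}x3, "
                             f"got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be uint8 in [0, 255]")

    def to_jpeg(self, path, quality: int = 95) -> None:
        Image.fromarray(self.pixels, mode="RGB").save(path, "JPEG", quality=quality)


def build_input_vector(rec: ECGRecord, beat: MedianBeat, window_s: float = 10.0) -> np.ndarray:
    """Concatenate ``window_s`` seconds of the eight independent leads with
    their median beats into a single series.

    Records shorter than the window are cyclically tiled (avoids a silent-gap
    artefact); longer ones are truncated to the first ``window_s`` seconds.
    """
    n_target = int(round(window_s * rec.fs))
    parts = [np.resize(rec.lead(name), n_target) for name in INPUT_LEADS]
    parts += [beat.lead(name) for name in INPUT_LEADS]
    return np.concatenate(parts)


def _morse_filter(omega: np.ndarray, gamma: float, beta: float) -> np.ndarray:
    """Unit-peak analytic Morse filter evaluated at angular frequencies >= 0."""
    omega_p = (beta / gamma) ** (1.0 / gamma)  # peak angular frequency
    out = np.zeros_like(omega)
    pos = omega > 0
    w = omega[pos]
    # log-domain for numerical stability at large beta
    log_psi = beta * np.log(w / omega_p) - (w ** gamma - omega_p ** gamma)
    out[pos] = 2.0 * np.exp(log_psi)
    return out


def morse_cwt(series: np.ndarray, fs: float, voices_per_octave: int = DEFAULT_VOICES,
              gamma: float = DEFAULT_GAMMA, time_bandwidth: float = DEFAULT_TIME_BANDWIDTH,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Continuous wavelet transform with the generalized Morse wavelet.

    Returns ``(coeffs, freqs_hz)`` where ``coeffs`` has one row per scale,
    ordered from the highest centre frequency down, and ``freqs_hz`` gives
    each row's centre frequency.  The scale grid is geometric with
    ``voices_per_octave`` subdivisions per factor two of frequency, spanning
    from just below Nyquist down to the lowest frequency whose wavelet
    support still fits the series.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("morse_cwt expects a 1-D series")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    n = series.size
    if n < 4:
        raise ValueError("series too short for a wavelet transform")
    beta = time_bandwidth / gamma
    p = np.sqrt(time_bandwidth)  # time-bandwidth parameter P

    f_max = 0.45 * fs
    # lowest frequency whose wavelet (duration ~ P / (pi f)) fits the series
    f_min_possible = p * fs / (np.pi * n)
    n_octaves = np.log2(f_max / max(f_min_possible, 1e-12))
    if n_octaves < 1:
        n_octaves = 1.0
    n_scales = int(np.floor(n_octaves * voices_per_octave)) + 1
    freqs = f_max * 2.0 ** (-np.arange(n_scales) / voices_per_octave)

    x_hat = np.fft.fft(series)
    omega = 2.0 * np.pi * np.fft.fftfreq(n)  # rad/sample
    omega_p = (beta / gamma) ** (1.0 / gamma)
    coeffs = np.empty((n_scales, n), dtype=complex)
    for i, f in enumerate(freqs):
        scale = omega_p * fs / (2.0 * np.pi * f)  # peak response at frequency f
        coeffs[i] = np.fft.ifft(x_hat * _morse_filter(scale * omega, gamma, beta))
    return coeffs, freqs


def render_scalogram(coeffs: np.ndarray, freqs_hz: np.ndarray | None = None,
                     source_id: str = "", colormap: str = "jet") -> ScalogramImage:
    """Render CWT magnitude as a 224 x 224 x 3 image.

    The magnitude is normalised per image to [0, 1] (so the image is
    invariant to uniform amplitude scaling), bilinearly resized, and mapped
    through the colormap with frequency increasing upward.  An all-zero
    input renders as the uniform lowest colour.
    """
    coeffs = np.asarray(coeffs)
    if coeffs.size == 0:
        raise ValueError("empty coefficient matrix")
    mag = np.abs(coeffs).astype(np.float32)
    peak = float(mag.max())
    if peak > 0:
        mag /= peak
    img = Image.fromarray(mag, mode="F").resize((IMAGE_SIZE, IMAGE_SIZE), Image.BILINEAR)
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)

    import matplotlib
    cmap = matplotlib.colormaps[colormap]
    rgb = (cmap(arr)[..., :3] * 255.0).round().astype(np.uint8)
    return ScalogramImage(pixels=rgb, source_id=source_id,
                          frequencies_hz=np.asarray(freqs_hz if freqs_hz is not None else []),
                          colormap_name=colormap)


def record_scalogram(rec: ECGRecord, beat: MedianBeat, colormap: str = "jet",
                     **cwt_kwargs) -> ScalogramImage:
    """Convenience pipeline: input vector -> Morse CWT -> rendered image."""
    vec = build_input_vector(rec, beat)
    coeffs, freqs = morse_cwt(vec, rec.fs, **cwt_kwargs)
    return render_scalogram(coeffs, freqs, source_id=rec.record_id, colormap=colormap)
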