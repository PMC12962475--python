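"""Spectrogram-image featurization of syllables.

Each syllable waveform becomes a fixed-length pixel vector through a
deliberately image-like pipeline: a high-time-resolution STFT
(n_fft = 512, win_length = 256, hop_length = 8) in decibels, rendered
through a diverging blue-white-red colormap onto a square canvas,
bilinearly resized to 28 x 28 per color channel, and flattened to a
2352-element vector in [0, 1].  Stacking these vectors row-wise and
z-scoring each pixel column yields the feature matrix that the 2-D
embedding and clustering stages consume.

All steps are deterministic and duration-independent: a 20 ms and a
500 ms syllable both map to 2352 features.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import rfft
from scipy.ndimage import map_coordinates
from scipy.signal import get_window

from .syllables import Waveform

__all__ = [
    "SpectrogramImage",
    "FeatureMatrix",
    "stft_db",
    "render_colormap",
    "resize_flatten",
    "featurize_waveform",
    "zscore_matrix",
    "N_PIXEL_FEATURES",
]

N_PIXEL_FEATURES = 28 * 28 * 3  # 2352
_DB_RANGE = 80.0  # clip floor, dB below per-image max


@dataclass(frozen=True)
class SpectrogramImage:
    """RGB spectrogram image with values in [0, 1].

    Rows are frequency (highest frequency in row 0, as displayed),
    columns are time; any square or rectangular size is accepted, the
    28 x 28 target is produced by :func:`resize_flatten`.
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got {px.shape}")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))


@dataclass
class FeatureMatrix:
    """Per-syllable pixel features with optional 2-D embedding.

    ``X`` is (n_syllables, 2352); ``ids`` labels the rows.  After
    :func:`zscore_matrix`, ``zscored`` is True and ``constant_columns``
    marks pixel columns that had zero variance (set to 0).
    """

    X: np.ndarray
    ids: list[str]
    zscored: bool = False
    constant_columns: np.ndarray | None = None
    embedding: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[1] != N_PIXEL_FEATURES:
            raise ValueError(
                f"feature matrix must be (n, {N_PIXEL_FEATURES}), got {self.X.shape}"
            )
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("ids length must match number of rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def to_csv(self, path) -> None:
        cols = [f"px{i + 1:04d}" for i in range(N_PIXEL_FEATURES)]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "syllable_id", self.ids)
        if self.embedding is not None:
            df["umap1"] = self.embedding[:, 0]
            df["umap2"] = self.embedding[:, 1]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        px_cols = [c for c in df.columns if re.fullmatch(r"px\d{4}", c)]
        if len(px_cols) != N_PIXEL_FEATURES:
            raise ValueError(
                f"{path}: expected {N_PIXEL_FEATURES} pixel columns, found {len(px_cols)}"
            )
        emb = None
        if {"umap1", "umap2"} <= set(df.columns):
            emb = df[["umap1", "umap2"]].to_numpy(dtype=np.float64)
        return cls(
            X=df[px_cols].to_numpy(dtype=np.float64),
            ids=[str(s) for s in df["syllable_id"]],
            embedding=emb,
        )


def stft_db(
    w: Waveform,
    n_fft: int = 512,
    win_length: int = 256,
    hop_length: int = 8,
    db_range: float = _DB_RANGE,
) -> np.ndarray:
    """Power STFT in decibels, shaped (frames, n_fft // 2 + 1).

    No center padding: frame count is ``floor((N - win_length) /
    hop_length) + 1``.  Hann-windowed frames are zero-padded to
    ``n_fft`` points; power is expressed as 10 log10 and clipped to
    ``db_range`` dB below the per-image maximum so silence has a finite
    floor.
    """
    x = w.samples
    if x.size < win_length:
        raise ValueError(
            f"waveform of {x.size} samples shorter than win_length={win_length}; "
            f"need at least {win_length} samples"
        )
    frames = np.lib.stride_tricks.sliding_window_view(x, win_length)[::hop_length]
    window = get_window("hann", win_length, fftbins=True)
    spec = rfft(frames * window, n=n_fft, axis=1)
    power = np.abs(spec) ** 2
    db = 10.0 * np.log10(power + 1e-20)
    return np.maximum(db, db.max() - db_range)


def _bwr(v: np.ndarray) -> np.ndarray:
    """Diverging blue-white-red transfer on [0, 1], piecewise linear.

    0 -> (0, 0, 1); 0.5 -> (1, 1, 1); 1 -> (1, 0, 0), interpolated
    linearly per channel on each half (the continuous form of the
    standard ``bwr`` diverging map).
    """
    v = np.asarray(v, dtype=np.float64)
    r = np.clip(2 * v, 0.0, 1.0)
    b = np.clip(2 - 2 * v, 0.0, 1.0)
    g = np.minimum(r, b)
    return np.stack([r, g, b], axis=-1)


def render_colormap(db_matrix: np.ndarray, source_id: str = "") -> SpectrogramImage:
    """Render a dB spectrogram onto a square blue-white-red canvas.

    The matrix is min-max normalized per image (so overall gain drops
    out), the time axis is linearly resampled to match the frequency
    axis length (a square canvas regardless of syllable duration), and
    values pass through the blue-white-red transfer.  Rows of the output
    image run from high frequency (top) to low (bottom), as displayed.
    """
    m = np.asarray(db_matrix, dtype=np.float64)
    if m.size == 0:
        raise ValueError("empty spectrogram matrix")
    lo, hi = m.min(), m.max()
    if hi == lo:
        warnings.warn(
            "constant spectrogram: mapping uniformly to colormap midpoint",
            RuntimeWarning,
            stacklevel=2,
        )
        norm = np.full_like(m, 0.5)
    else:
        norm = (m - lo) / (hi - lo)

    n_t, n_f = norm.shape
    side = n_f
    # resample time axis to `side` points (linear interpolation)
    if n_t == 1:
        sq = np.repeat(norm, side, axis=0)
    else:
        t_old = np.linspace(0.0, 1.0, n_t)
        t_new = np.linspace(0.0, 1.0, side)
        sq = np.empty((side, n_f))
        for j in range(n_f):
            sq[:, j] = np.interp(t_new, t_old, norm[:, j])
    # image orientation: frequency on rows, high frequency on top
    img = _bwr(sq.T[::-1])
    return SpectrogramImage(img, source_id=source_id)


def _bilinear_resize(channel: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resample with centered pixel coordinates (no antialias).

    Output pixel (i, j) samples the input at ((i + 0.5) * H/out_h - 0.5,
    (j + 0.5) * W/out_w - 0.5); at exact 2x decimation this is the
    average of each 2 x 2 block.
    """
    h, w = channel.shape
    rows = (np.arange(out_h) + 0.5) * (h / out_h) - 0.5
    cols = (np.arange(out_w) + 0.5) * (w / out_w) - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(channel, [rr, cc], order=1, mode="nearest")


def resize_flatten(img: SpectrogramImage) -> np.ndarray:
    """Resize an image to 28 x 28 per channel and flatten to 2352 values.

    Flattening is row-major with channels interleaved last (C order of
    the (28, 28, 3) array): index = (row * 28 + col) * 3 + channel.
    """
    out = np.stack(
        [_bilinear_resize(img.pixels[:, :, c], 28, 28) for c in range(3)], axis=-1
    )
    return np.clip(out, 0.0, 1.0).ravel(order="C")


def featurize_waveform(w: Waveform, source_id: str = "", **stft_kwargs) -> np.ndarray:
    """Full waveform -> 2352-vector pipeline (STFT, colormap, resize)."""
    return resize_flatten(render_colormap(stft_db(w, **stft_kwargs), source_id=source_id))


def zscore_matrix(m: FeatureMatrix) -> FeatureMatrix:
    """Z-score each pixel column across syllables (sample SD, ddof=1).

    Zero-variance columns are set to 0 and flagged in
    ``constant_columns``.  Requires at least two rows.
    """
    if m.n < 2:
        raise ValueError("z-scoring needs >= 2 rows (SD undefined for one syllable)")
    mean = m.X.mean(axis=0)
    sd = m.X.std(axis=0, ddof=1)
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    Z = (m.X - mean) / sd_safe
    Z[:, constant] = 0.0
    return FeatureMatrix(
        X=Z,
        ids=list(m.ids),
        zscored=True,
        constant_columns=constant,
        embedding=None if m.embedding is None else m.embedding.copy(),
    )
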