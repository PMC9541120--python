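"""Stimulus preparation: luminance equalization and Fourier phase scrambling.

Pupil size reacts strongly to luminance, so stimulus images shown in a
pupillometry experiment must carry equal overall brightness: each image has
its per-image median subtracted and the corpus-wide mean of those medians
added back, which puts every image's median grey level at a common value.

The pre-trial baseline screen is a *phase-scrambled* version of the upcoming
stimulus: the image's 2-D Fourier amplitude spectrum (and hence its
luminance and contrast statistics) is kept while its phases are randomised,
destroying all recognisable spatial structure.  Random phase offsets are
drawn once per frequency and antisymmetrised so the spectrum keeps conjugate
symmetry and the inverse transform is exactly real; self-conjugate bins (DC
and Nyquist) receive a zero offset, so the image mean is preserved.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from PIL import Image

GREY_LEVELS = 255.0


def load_grayscale(path) -> np.ndarray:
    """Load an image as a float64 single-channel array in [0, 255]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=float)


def save_grayscale(pixels: np.ndarray, path) -> None:
    """Export as 8-bit grayscale PNG, clipping to [0, 255]."""
    arr = np.clip(np.asarray(pixels, dtype=float), 0, GREY_LEVELS)
    Image.fromarray(np.round(arr).astype(np.uint8), mode="L").save(path)


def equalize_luminance(corpus: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Equalize median luminance across a corpus of grayscale images.

    Each output is ``image - median(image) + M`` with ``M`` the corpus mean
    of per-image medians, clipped to [0, 255].  Absent clipping, every output
    image's median equals ``M`` and the operation is idempotent.
    """
    corpus = [np.asarray(im, dtype=float) for im in corpus]
    if not corpus:
        raise ValueError("cannot equalize an empty corpus")
    medians = np.array([np.median(im) for im in corpus])
    m = medians.mean()
    return [np.clip(im - med + m, 0, GREY_LEVELS) for im, med in zip(corpus, medians)]


def corpus_median_stats(corpus: Sequence[np.ndarray]) -> dict[str, float]:
    """Mean / median / SD of the per-image median grey levels of a corpus."""
    medians = np.array([np.median(np.asarray(im, dtype=float)) for im in corpus])
    return {
        "mean": float(medians.mean()),
        "median": float(np.median(medians)),
        "sd": float(medians.std(ddof=1)) if len(medians) > 1 else 0.0,
    }


def phase_scramble(image: np.ndarray, seed: int) -> np.ndarray:
    """Randomise an image's Fourier phases, keeping its amplitude spectrum.

    A random offset is added to every phase; offsets are antisymmetrised
    over conjugate frequency pairs (zero at self-conjugate bins), so the
    output of the inverse transform is real, the per-frequency amplitudes
    are unchanged, and the DC component — the image mean — is preserved.
    Deterministic for a given ``seed``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("phase_scramble expects a 2-D grayscale image")
    h, w = img.shape
    rng = np.random.default_rng(seed)
    phi = rng.uniform(-np.pi, np.pi, size=(h, w))
    # conjugate bin of (i, j) is ((-i) mod h, (-j) mod w); the antisymmetric
    # part vanishes at self-conjugate bins (DC, Nyquist rows/columns)
    conj = phi[(-np.arange(h)) % h][:, (-np.arange(w)) % w]
    delta = 0.5 * (phi - conj)
    spectrum = np.fft.fft2(img) * np.exp(1j * delta)
    return np.fft.ifft2(spectrum).real
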