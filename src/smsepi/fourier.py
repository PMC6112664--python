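"""Centered 2-D Fourier transforms with orthonormal scaling.

Conventions used throughout the package: the DC sample sits at index
``N // 2`` on each axis (0-based), the phase-encode direction is the
second-to-last axis (``y``) and readout the last axis (``x``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["fft2c", "ifft2c", "fft1c", "ifft1c"]

_AXES2 = (-2, -1)


def fft2c(img: np.ndarray) -> np.ndarray:
    """Image -> k-space, centered, orthonormal."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=_AXES2), axes=_AXES2, norm="ortho"),
        axes=_AXES2,
    )


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    """k-space -> image, centered, orthonormal."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ksp, axes=_AXES2), axes=_AXES2, norm="ortho"),
        axes=_AXES2,
    )


def fft1c(arr: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fft(np.fft.ifftshift(arr, axes=axis), axis=axis, norm="ortho"),
        axes=axis,
    )


def ifft1c(arr: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(arr, axes=axis), axis=axis, norm="ortho"),
        axes=axis,
    )
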