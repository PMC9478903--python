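"""Fourier basis patterns for three-step phase-shifting single-pixel imaging.

A Fourier single-pixel imager measures one complex Fourier coefficient of the
scene per displayed *pattern triplet*.  Each triplet consists of three
sinusoidal fringe patterns with initial phases 0, 2*pi/3 and 4*pi/3::

    P_phi(x, y; u, v) = 1/2 + 1/2 * cos(2*pi*u*x/M + 2*pi*v*y/N + phi)

on an M x N pixel grid (x indexes rows, y columns, both 0-based).  Because a
digital micromirror device can only display binary masks, the grayscale
fringes are binarized with Floyd-Steinberg error diffusion.

Real scenes have Hermitian-symmetric spectra, so only one representative of
every conjugate pair (u, v) <-> (M-u mod M, N-v mod N) needs to be acquired.
:func:`circular_sampling_plan` selects representatives of lowest centered
radial frequency first until a target fraction of the spectrum is covered --
the standard low-pass ("circular") undersampling strategy of fast FSI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "PHASES",
    "PatternTriplet",
    "SamplingPlan",
    "fourier_pattern",
    "dither",
    "triplet_for",
    "circular_sampling_plan",
    "random_sampling_plan",
    "conjugate_coord",
    "is_self_conjugate",
    "is_canonical",
    "centered_radius",
    "export_pattern",
]

#: The three initial phases (radians) of the phase-shifting scheme.
PHASES: tuple[float, float, float] = (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0)


def _validate_shape(shape) -> tuple[int, int]:
    M, N = int(shape[0]), int(shape[1])
    if M < 1 or N < 1:
        raise ValueError(f"grid shape must be at least 1x1, got {M}x{N}")
    return M, N


def _validate_freq(u: int, v: int, shape) -> tuple[int, int, int, int]:
    M, N = _validate_shape(shape)
    u, v = int(u), int(v)
    if not (0 <= u < M and 0 <= v < N):
        raise ValueError(
            f"frequency coordinate ({u}, {v}) out of range for {M}x{N} grid"
        )
    return u, v, M, N


def fourier_pattern(u: int, v: int, shape, phase: float) -> np.ndarray:
    """Grayscale fringe pattern for coefficient (u, v) at one phase step.

    Parameters
    ----------
    u, v
        Integer frequency coordinate, ``0 <= u < M``, ``0 <= v < N``.
    shape
        Grid shape ``(M, N)``.
    phase
        One of :data:`PHASES` (0, 2*pi/3 or 4*pi/3 radians).

    Returns
    -------
    ndarray of shape (M, N) with values in [0, 1].
    """
    u, v, M, N = _validate_freq(u, v, shape)
    if not any(abs(phase - p) < 1e-9 for p in PHASES):
        raise ValueError(f"phase must be one of {PHASES}, got {phase}")
    x = np.arange(M, dtype=np.float64)[:, None]
    y = np.arange(N, dtype=np.float64)[None, :]
    return 0.5 + 0.5 * np.cos(2.0 * np.pi * u * x / M + 2.0 * np.pi * v * y / N + phase)


@njit(cache=False)
def _fs_dither_serpentine(img: np.ndarray) -> np.ndarray:
    """Serpentine Floyd-Steinberg error diffusion; border error is dropped."""
    M, N = img.shape
    work = img.copy()
    out = np.zeros((M, N), dtype=np.uint8)
    for i in range(M):
        forward = i % 2 == 0
        for k in range(N):
            j = k if forward else N - 1 - k
            old = work[i, j]
            new = 1.0 if old >= 0.5 else 0.0
            out[i, j] = np.uint8(new)
            err = old - new
            ahead = 1 if forward else -1
            if 0 <= j + ahead < N:
                work[i, j + ahead] += err * (7.0 / 16.0)
            if i + 1 < M:
                if 0 <= j - ahead < N:
                    work[i + 1, j - ahead] += err * (3.0 / 16.0)
                work[i + 1, j] += err * (5.0 / 16.0)
                if 0 <= j + ahead < N:
                    work[i + 1, j + ahead] += err * (1.0 / 16.0)
    return out


def dither(pattern: np.ndarray) -> np.ndarray:
    """Binarize a grayscale pattern by Floyd-Steinberg error diffusion.

    Scan order is serpentine (left-to-right on even rows, right-to-left on
    odd rows) with the classic 7/16, 3/16, 5/16, 1/16 kernel mirrored on
    reverse rows; quantization error falling outside the grid is dropped.
    The threshold maps values >= 0.5 to 1.  Deterministic, and idempotent
    on already-binary input.

    Returns a uint8 array of {0, 1}.
    """
    pattern = np.asarray(pattern, dtype=np.float64)
    if pattern.ndim != 2:
        raise ValueError("pattern must be 2-D")
    if not np.all(np.isfinite(pattern)) or pattern.min() < 0.0 or pattern.max() > 1.0:
        raise ValueError("pattern values must lie in [0, 1]")
    return _fs_dither_serpentine(pattern)


@dataclass(frozen=True)
class PatternTriplet:
    """The three phase-shifted patterns (grayscale and binary) for one (u, v)."""

    u: int
    v: int
    shape: tuple[int, int]
    grayscale: np.ndarray  #: float64, shape (3, M, N), values in [0, 1]
    binary: np.ndarray  #: uint8, shape (3, M, N), values in {0, 1}

    def __post_init__(self):
        if self.grayscale.shape != (3, *self.shape):
            raise ValueError("grayscale stack must have shape (3, M, N)")
        if self.binary.shape != (3, *self.shape):
            raise ValueError("binary stack must have shape (3, M, N)")


def triplet_for(u: int, v: int, shape) -> PatternTriplet:
    """Build the grayscale and dithered pattern triplet for coefficient (u, v)."""
    u, v, M, N = _validate_freq(u, v, shape)
    gray = np.stack([fourier_pattern(u, v, (M, N), p) for p in PHASES])
    binary = np.stack([dither(g) for g in gray])
    return PatternTriplet(u=u, v=v, shape=(M, N), grayscale=gray, binary=binary)


# ---------------------------------------------------------------------------
# Frequency-domain geometry
# ---------------------------------------------------------------------------


def conjugate_coord(u: int, v: int, shape) -> tuple[int, int]:
    """Coordinate of the Hermitian conjugate of (u, v)."""
    u, v, M, N = _validate_freq(u, v, shape)
    return (M - u) % M, (N - v) % N


def is_self_conjugate(u: int, v: int, shape) -> bool:
    """True when (u, v) is its own conjugate (coefficient is real)."""
    u, v, M, N = _validate_freq(u, v, shape)
    return (2 * u) % M == 0 and (2 * v) % N == 0


def is_canonical(u: int, v: int, shape) -> bool:
    """True when (u, v) is the chosen representative of its conjugate pair.

    The canonical half-plane keeps ``0 < v < N/2`` unconditionally; on the
    self-mirrored columns ``v = 0`` and (even N) ``v = N/2``, ties are broken
    by ``u <= M - u``.  Every pair has exactly one canonical member.
    """
    u, v, M, N = _validate_freq(u, v, shape)
    if 0 < 2 * v < N:
        return True
    if 2 * v == N or v == 0:
        return 2 * u <= M
    return False


def centered_radius(u: int, v: int, shape) -> float:
    """Wrap-around radial frequency sqrt(min(u, M-u)^2 + min(v, N-v)^2)."""
    u, v, M, N = _validate_freq(u, v, shape)
    return math.hypot(min(u, M - u), min(v, N - v))


@dataclass(frozen=True)
class SamplingPlan:
    """Ordered Fourier-domain acquisition plan.

    ``coords`` holds one canonical representative per conjugate pair, ordered
    by increasing centered radius (ties broken by (u, v)).  ``coverage`` is
    the fraction of all M*N coefficients covered, counting each selected
    non-self-conjugate coefficient together with its implied conjugate.
    """

    shape: tuple[int, int]
    coords: tuple[tuple[int, int], ...]
    ratio: float  #: requested sampling ratio
    coverage: float  #: achieved covered fraction of the M*N spectrum
    strategy: str = "circular"
    conjugate_counting: bool = True

    def __len__(self) -> int:
        return len(self.coords)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "index": i,
                "u": u,
                "v": v,
                "radius": centered_radius(u, v, self.shape),
                "self_conjugate": int(is_self_conjugate(u, v, self.shape)),
            }
            for i, (u, v) in enumerate(self.coords)
        ]
        return pd.DataFrame(rows, columns=["index", "u", "v", "radius", "self_conjugate"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, shape, ratio=float("nan"), strategy="circular") -> "SamplingPlan":
        df = pd.read_csv(path)
        coords = tuple((int(r.u), int(r.v)) for r in df.itertuples())
        covered = sum(1 if is_self_conjugate(u, v, shape) else 2 for u, v in coords)
        M, N = _validate_shape(shape)
        return cls(
            shape=(M, N),
            coords=coords,
            ratio=float(ratio),
            coverage=covered / (M * N),
            strategy=strategy,
        )


def _canonical_by_radius(shape) -> list[tuple[float, int, int]]:
    M, N = _validate_shape(shape)
    out = []
    for u in range(M):
        for v in range(N):
            if is_canonical(u, v, (M, N)):
                out.append((centered_radius(u, v, (M, N)), u, v))
    out.sort()
    return out


def circular_sampling_plan(shape, ratio: float, conjugate_counting: bool = True) -> SamplingPlan:
    """Low-frequency-first ("circular") Fourier sampling plan.

    Selects canonical conjugate-pair representatives in order of increasing
    centered radius until the covered fraction of the M x N spectrum reaches
    ``ratio``.  With ``conjugate_counting`` (default) a non-self-conjugate
    selection covers two coefficients (itself and its implied conjugate);
    a self-conjugate selection covers one.  With it off, coverage counts
    only the displayed representatives.

    The DC coefficient (0, 0) has radius zero and is always selected first.
    """
    M, N = _validate_shape(shape)
    if not (0.0 < ratio <= 1.0):
        raise ValueError(f"sampling ratio must be in (0, 1], got {ratio}")
    total = M * N
    target = ratio * total
    coords: list[tuple[int, int]] = []
    covered = 0
    for _, u, v in _canonical_by_radius((M, N)):
        if covered >= target and coords:
            break
        coords.append((u, v))
        if conjugate_counting:
            covered += 1 if is_self_conjugate(u, v, (M, N)) else 2
        else:
            covered += 1
    return SamplingPlan(
        shape=(M, N),
        coords=tuple(coords),
        ratio=float(ratio),
        coverage=covered / total,
        strategy="circular",
        conjugate_counting=conjugate_counting,
    )


def random_sampling_plan(shape, ratio: float, seed: int = 0,
                         conjugate_counting: bool = True) -> SamplingPlan:
    """Uniformly random plan over conjugate-pair representatives (DC always first)."""
    M, N = _validate_shape(shape)
    if not (0.0 < ratio <= 1.0):
        raise ValueError(f"sampling ratio must be in (0, 1], got {ratio}")
    rng = np.random.default_rng(seed)
    pool = [(u, v) for _, u, v in _canonical_by_radius((M, N)) if (u, v) != (0, 0)]
    rng.shuffle(pool)
    total = M * N
    target = ratio * total
    coords = [(0, 0)]
    covered = 1
    for u, v in pool:
        if covered >= target:
            break
        coords.append((u, v))
        if conjugate_counting:
            covered += 1 if is_self_conjugate(u, v, (M, N)) else 2
        else:
            covered += 1
    return SamplingPlan(
        shape=(M, N),
        coords=tuple(coords),
        ratio=float(ratio),
        coverage=covered / total,
        strategy="random",
        conjugate_counting=conjugate_counting,
    )


def export_pattern(pattern: np.ndarray, path) -> None:
    """Write a pattern as an 8-bit grayscale image (PGM/PNG by extension).

    Grayscale values in [0, 1] are scaled by 255 and rounded; binary {0, 1}
    patterns map to {0, 255}.
    """
    import imageio.v3 as iio

    arr = np.asarray(pattern)
    if arr.dtype == np.uint8 and arr.max(initial=0) <= 1:
        img = (arr * 255).astype(np.uint8)
    else:
        img = np.rint(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    iio.imwrite(path, img)
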