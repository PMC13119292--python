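"""Synthetic Raman spectra with known pure signal, baseline and noise.

The simulator builds a composite spectrum from three additive
components on a uniform wavenumber grid:

* a *pure* spectrum — a sum of Gaussian and Lorentzian peaks covering
  sharp peaks, overlapping peaks of different shapes, and weak broad
  peaks buried in noise;
* a *baseline* — a slowly varying background made of a linear trend, a
  long-period sinusoid and a broad Gaussian bump, standing in for
  fluorescence and instrument response;
* white Gaussian *noise* scaled post hoc so that the achieved
  signal-to-noise ratio ``10 log10(Es / En)`` (signal energy over noise
  energy) matches the request exactly.

Because the baseline is known analytically, the error of any corrector
can be scored against ground truth — the basis of the benchmark in
:mod:`aispls.evaluate`.

Two Gaussian parameterizations coexist in the field: the normalized
form ``H exp(-((x - mu)/sigma)^2)`` and the raw-denominator form
``H exp(-(x - mu)^2 / c)``.  The benchmark peak table uses the
raw-denominator convention (c values such as 80 or 30 correspond to
widths of a few cm^-1); :func:`gaussian_peak` takes ``c`` directly and
``sigma**2`` can be passed for the normalized form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "PeakSpec",
    "BaselineSpec",
    "SimulatedSpectrum",
    "gaussian_peak",
    "lorentzian_peak",
    "pure_spectrum",
    "true_baseline",
    "add_noise",
    "simulate_dataset",
    "default_grid",
    "BENCHMARK_PEAKS",
]


@dataclass
class Spectrum:
    """A 1-D spectrum: wavenumber grid plus intensity vector.

    Invariants: equal lengths of at least 3, strictly increasing grid,
    all values finite.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1 or self.x.size != self.y.size:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.x.size < 3:
            raise ValueError("a spectrum needs at least 3 points")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("spectrum contains non-finite values")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class PeakSpec:
    """One peak of the simulated pure spectrum.

    ``kind='gaussian'`` uses ``H exp(-(x - mu)^2 / width)`` where
    ``width`` is the raw exponent denominator ``c``.
    ``kind='lorentzian'`` uses ``H p1 / ((x - mu)^2 + p2)`` with
    ``width = (p1, p2)``.
    """

    kind: Literal["gaussian", "lorentzian"]
    H: float
    mu: float
    width: float | tuple[float, float]

    def __post_init__(self) -> None:
        if self.H <= 0:
            raise ValueError("peak amplitude H must be positive")
        if self.kind == "gaussian":
            if not np.isscalar(self.width) or self.width <= 0:  # type: ignore[operator]
                raise ValueError("gaussian width must be a positive scalar")
        elif self.kind == "lorentzian":
            p1, p2 = self.width  # type: ignore[misc]
            if p1 <= 0 or p2 <= 0:
                raise ValueError("lorentzian width components must be positive")
        else:
            raise ValueError(f"unknown peak kind {self.kind!r}")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "gaussian":
            return gaussian_peak(x, self.H, self.mu, float(self.width))  # type: ignore[arg-type]
        p1, p2 = self.width  # type: ignore[misc]
        return lorentzian_peak(x, self.H, self.mu, p1, p2)


#: Peak table of the benchmark pure spectrum: 5 Gaussian and 9
#: Lorentzian peaks on the 0-1600 cm^-1 range.  Gaussian widths are raw
#: exponent denominators; Lorentzian widths are (p1, p2) pairs with
#: p2 the squared half-width.
BENCHMARK_PEAKS: tuple[PeakSpec, ...] = (
    PeakSpec("gaussian", 20.0, 100.0, 80.0),
    PeakSpec("gaussian", 90.0, 500.0, 30.0),
    PeakSpec("gaussian", 20.0, 400.0, 60.0),
    PeakSpec("gaussian", 10.0, 1100.0, 70.0),
    PeakSpec("gaussian", 10.0, 1300.0, 70.0),
    PeakSpec("lorentzian", 1200.0, 200.0, (30.0, 900.0)),
    PeakSpec("lorentzian", 300.0, 250.0, (20.0, 400.0)),
    PeakSpec("lorentzian", 1000.0, 550.0, (15.0, 225.0)),
    PeakSpec("lorentzian", 1300.0, 600.0, (20.0, 400.0)),
    PeakSpec("lorentzian", 600.0, 800.0, (15.0, 225.0)),
    PeakSpec("lorentzian", 500.0, 1000.0, (15.0, 225.0)),
    PeakSpec("lorentzian", 300.0, 1200.0, (15.0, 225.0)),
    PeakSpec("lorentzian", 400.0, 1250.0, (15.0, 225.0)),
    PeakSpec("lorentzian", 200.0, 1450.0, (15.0, 900.0)),
)


def _linear(a: float, b: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda x: a + b * x


def _sinusoid(amp: float, period: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda x: amp * np.sin(math.pi * x / period)


def _gaussian_bump(amp: float, mu: float, s: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda x: amp * np.exp(-(((x - mu) / s) ** 2))


@dataclass
class BaselineSpec:
    """Additive baseline model: a list of evaluable components."""

    components: list[Callable[[np.ndarray], np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("baseline needs at least one component")

    @classmethod
    def benchmark(cls) -> "BaselineSpec":
        """Linear drift + slow sinusoid + broad Gaussian bump at 700 cm^-1."""
        return cls(
            components=[
                _linear(30.0, 0.0005),
                _sinusoid(10.0, 2000.0),
                _gaussian_bump(20.0, 700.0, 600.0),
            ]
        )

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        total = np.zeros_like(x)
        for comp in self.components:
            total = total + comp(x)
        return total


@dataclass
class SimulatedSpectrum:
    """A simulated spectrum with its ground-truth decomposition."""

    grid: np.ndarray
    pure: np.ndarray
    baseline: np.ndarray
    noise: np.ndarray
    snr_db: float
    seed: int | None

    @property
    def composite(self) -> np.ndarray:
        return self.pure + self.baseline + self.noise

    def as_spectrum(self) -> Spectrum:
        return Spectrum(self.grid, self.composite)

    def achieved_snr_db(self) -> float:
        """SNR of (pure + baseline) against the stored noise realization."""
        es = float(np.sum((self.pure + self.baseline) ** 2))
        en = float(np.sum(self.noise**2))
        if en == 0.0:
            return math.inf
        return 10.0 * math.log10(es / en)


def gaussian_peak(x: np.ndarray, H: float, mu: float, c: float) -> np.ndarray:
    """Gaussian peak ``H exp(-(x - mu)^2 / c)`` with raw denominator c.

    For the sigma-parameterized form pass ``c = sigma**2``.
    """
    if c <= 0:
        raise ValueError(f"gaussian denominator c must be positive, got {c}")
    x = np.asarray(x, dtype=float)
    return H * np.exp(-((x - mu) ** 2) / c)


def lorentzian_peak(x: np.ndarray, H: float, mu: float, p1: float, p2: float) -> np.ndarray:
    """Lorentzian peak ``H p1 / ((x - mu)^2 + p2)``.

    The benchmark peak table uses ``p2 = (half-width)^2``; the apex value
    is then ``H p1 / p2``.
    """
    if p1 <= 0 or p2 <= 0:
        raise ValueError(f"lorentzian parameters must be positive, got p1={p1}, p2={p2}")
    x = np.asarray(x, dtype=float)
    return H * p1 / ((x - mu) ** 2 + p2)


def pure_spectrum(
    grid: np.ndarray, peaks: Sequence[PeakSpec] = BENCHMARK_PEAKS
) -> np.ndarray:
    """Sum of all peaks of the pure-spectrum model on ``grid``."""
    grid = np.asarray(grid, dtype=float)
    total = np.zeros_like(grid)
    for peak in peaks:
        total += peak(grid)
    return total


def true_baseline(
    grid: np.ndarray, spec: BaselineSpec | None = None
) -> np.ndarray:
    """Ground-truth baseline evaluated on ``grid``."""
    if spec is None:
        spec = BaselineSpec.benchmark()
    return spec(np.asarray(grid, dtype=float))


def add_noise(
    signal: np.ndarray, snr_db: float, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """White Gaussian noise scaled so the achieved SNR equals ``snr_db``.

    The returned realization satisfies ``10 log10(Es / En) == snr_db``
    exactly (post-hoc scaling), where ``Es = sum(signal**2)`` and
    ``En = sum(noise**2)``.  Deterministic for a fixed integer seed.
    """
    signal = np.asarray(signal, dtype=float)
    es = float(np.sum(signal**2))
    if es == 0.0:
        raise ValueError("cannot set an SNR against a zero-energy signal")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = rng.standard_normal(signal.size)
    en_target = es / (10.0 ** (snr_db / 10.0))
    raw_energy = float(np.sum(raw**2))
    return raw * math.sqrt(en_target / raw_energy)


def default_grid(start: float = 0.0, stop: float = 1600.0, step: float = 1.0) -> np.ndarray:
    """Uniform wavenumber grid, by default 0..1600 cm^-1 at 1 cm^-1."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def simulate_dataset(
    snr_db: float,
    seed: int | None = None,
    grid: np.ndarray | None = None,
    peaks: Sequence[PeakSpec] = BENCHMARK_PEAKS,
    baseline_spec: BaselineSpec | None = None,
) -> SimulatedSpectrum:
    """Simulate one composite spectrum at the requested SNR.

    ``snr_db=inf`` disables noise.  Signal energy for the SNR is
    measured on the noiseless composite (pure + baseline).
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    pure = pure_spectrum(grid, peaks)
    baseline = true_baseline(grid, baseline_spec)
    if math.isinf(snr_db):
        noise = np.zeros_like(grid)
    else:
        noise = add_noise(pure + baseline, snr_db, seed)
    return SimulatedSpectrum(
        grid=grid, pure=pure, baseline=baseline, noise=noise, snr_db=snr_db, seed=seed
    )
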