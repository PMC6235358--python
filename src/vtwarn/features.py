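"""Scalar HRV features: mean N-N, Hjorth parameters, DFA exponents, Lomb band powers.

Each analysis window (a sequence of N-N intervals, in seconds) yields ten
scalar features:

* ``mean_nn`` — arithmetic mean interval (s);
* ``hjorth_mobility`` / ``hjorth_complexity`` — variance-ratio estimates of
  the mean frequency and bandwidth of the beat-indexed tachogram;
* ``alpha1`` / ``alpha2`` — short- and long-range detrended-fluctuation
  scaling exponents (boxes of 4-16 and 16-64 beats);
* ``bp1`` .. ``bp5`` — Lomb-periodogram power (s^2) in five log-spaced
  frequency bins spanning (1/T, 0.5] Hz, computed on the uneven time axis
  given by the cumulative interval sums.

All variances are population (1/N) variances. Hjorth differencing is per beat
index, so mobility/complexity are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .records import RRValidationError

__all__ = [
    "FeatureRow",
    "SpectralGrid",
    "SCALAR_FEATURES",
    "PREDICTOR_SCALAR_ORDER",
    "mean_nn_interval",
    "hjorth_parameters",
    "dfa_exponents",
    "build_spectral_grid",
    "lomb_periodogram",
    "log_band_powers",
    "extract_feature_row",
    "DegenerateSignalError",
]

#: Column order of the feature-table CSV.
SCALAR_FEATURES = [
    "mean_nn",
    "hjorth_mobility",
    "hjorth_complexity",
    "alpha1",
    "alpha2",
    "bp1",
    "bp2",
    "bp3",
    "bp4",
    "bp5",
]

#: Predictor order used after the PC coefficients when building classifier
#: inputs: alpha_1, alpha_2, mean N-N, five band powers (low to high
#: frequency), Hjorth complexity, Hjorth mobility.
PREDICTOR_SCALAR_ORDER = [
    "alpha1",
    "alpha2",
    "mean_nn",
    "bp1",
    "bp2",
    "bp3",
    "bp4",
    "bp5",
    "hjorth_complexity",
    "hjorth_mobility",
]

F_MAX_HZ = 0.5
N_BINS = 5
OVERSAMPLE = 4

ALPHA1_BOXES = (4, 16)
ALPHA2_BOXES = (16, 64)
MIN_DFA_LENGTH = 128


class DegenerateSignalError(RRValidationError):
    """The window has zero variance at some differencing level."""


@dataclass
class FeatureRow:
    """Ten scalar HRV features plus (optionally) k PCA coefficients for one window."""

    patient_id: str
    record_id: str
    label: str
    mean_nn: float
    hjorth_mobility: float
    hjorth_complexity: float
    alpha1: float
    alpha2: float
    band_powers: tuple[float, ...]
    pc_coeffs: tuple[float, ...] = ()

    def as_dict(self) -> dict:
        d = {
            "patient_id": self.patient_id,
            "record_id": self.record_id,
            "label": self.label,
            "mean_nn": self.mean_nn,
            "hjorth_mobility": self.hjorth_mobility,
            "hjorth_complexity": self.hjorth_complexity,
            "alpha1": self.alpha1,
            "alpha2": self.alpha2,
        }
        for i, bp in enumerate(self.band_powers, start=1):
            d[f"bp{i}"] = bp
        for i, c in enumerate(self.pc_coeffs, start=1):
            d[f"pc{i}"] = c
        return d


@dataclass
class SpectralGrid:
    """Evaluation frequencies (Hz) and the 6 log-equispaced bin edges over them."""

    frequencies: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.frequencies.size < 2 or np.any(np.diff(self.frequencies) <= 0):
            raise RRValidationError("grid frequencies must be strictly increasing")
        if self.frequencies[0] <= 0 or self.frequencies[-1] > F_MAX_HZ + 1e-12:
            raise RRValidationError("grid frequencies must lie in (0, 0.5] Hz")
        if self.bin_edges.size != N_BINS + 1:
            raise RRValidationError("expected 6 bin edges defining 5 bins")
        ratios = np.diff(np.log10(self.bin_edges))
        if not np.allclose(ratios, ratios[0], rtol=1e-6):
            raise RRValidationError("bin edges must be equally spaced in log10")

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def mean_nn_interval(window: np.ndarray) -> float:
    """Arithmetic mean of the window's intervals (s)."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise RRValidationError("mean_nn_interval: empty window")
    return float(window.mean())


def hjorth_parameters(window: np.ndarray) -> tuple[float, float, float]:
    """(activity, mobility, complexity) of the beat-indexed tachogram.

    activity = var(y); mobility = sqrt(var(dy)/var(y));
    complexity = mobility(dy)/mobility(y), with first differences over beat
    index and population variances.
    """
    y = np.asarray(window, dtype=float)
    if y.size < 3:
        raise RRValidationError("hjorth_parameters: window must have >= 3 samples")
    d1 = np.diff(y)
    d2 = np.diff(d1)
    v0, v1, v2 = y.var(), d1.var(), d2.var()
    if v0 <= 0.0 or v1 <= 0.0:
        raise DegenerateSignalError("hjorth_parameters: zero variance window")
    mobility = float(np.sqrt(v1 / v0))
    complexity = float(np.sqrt(v2 / v1) / mobility)
    return float(v0), mobility, complexity


def _fluctuation_function(profile: np.ndarray, box_sizes: np.ndarray) -> np.ndarray:
    """RMS residual of per-box linear detrending of the integrated profile."""
    N = profile.size
    out = np.empty(box_sizes.size)
    for j, n in enumerate(box_sizes):
        k = N // n
        seg = profile[: k * n].reshape(k, n)
        x = np.arange(n, dtype=float)
        x = x - x.mean()
        # per-box OLS line: slope and intercept via closed form
        slope = seg @ x / (x @ x)
        intercept = seg.mean(axis=1)
        resid = seg - (intercept[:, None] + slope[:, None] * x)
        out[j] = np.sqrt(np.mean(resid**2))
    return out


def dfa_exponents(window: np.ndarray) -> tuple[float, float]:
    """Short- and long-range DFA scaling exponents (alpha1, alpha2).

    The mean-centered series is integrated; for every integer box size n the
    profile is split into non-overlapping boxes, each box is detrended by a
    least-squares line, and F(n) is the RMS residual. alpha1 is the OLS slope
    of log F vs log n over n in [4, 16], alpha2 over n in [16, 64].
    """
    y = np.asarray(window, dtype=float)
    if y.size < MIN_DFA_LENGTH:
        raise RRValidationError(
            f"dfa_exponents: window of {y.size} < {MIN_DFA_LENGTH} intervals"
        )
    profile = np.cumsum(y - y.mean())
    sizes = np.arange(ALPHA1_BOXES[0], ALPHA2_BOXES[1] + 1)
    F = _fluctuation_function(profile, sizes)
    if np.any(F <= 0):
        raise DegenerateSignalError("dfa_exponents: zero fluctuation")
    logn, logF = np.log10(sizes), np.log10(F)

    def slope(lo: int, hi: int) -> float:
        sel = (sizes >= lo) & (sizes <= hi)
        return float(np.polyfit(logn[sel], logF[sel], 1)[0])

    return slope(*ALPHA1_BOXES), slope(*ALPHA2_BOXES)


def build_spectral_grid(
    duration: float, oversample: int = OVERSAMPLE, n_bins: int = N_BINS
) -> SpectralGrid:
    """Log-binned Lomb evaluation grid for a window of total duration *duration* s.

    The lowest resolvable frequency f_min = 1/T anchors the log scale (a log
    axis cannot start at 0 Hz); grid spacing is 1/(oversample*T) up to 0.5 Hz.
    """
    if duration <= 2.0 / F_MAX_HZ:
        raise RRValidationError("window too short for spectral analysis")
    f_min = 1.0 / duration
    df = f_min / oversample
    freqs = np.arange(oversample, int(np.floor(F_MAX_HZ / df)) + 1) * df
    edges = np.logspace(np.log10(f_min), np.log10(F_MAX_HZ), n_bins + 1)
    return SpectralGrid(frequencies=freqs, bin_edges=edges)


@njit(cache=True)
def _lomb_uniform_grid(t, y, f0, df, nf):  # pragma: no cover - exercised via wrapper
    """Classical Lomb ordinates on the uniform frequency grid f0 + k*df.

    Per-sample trig state is advanced by rotation between consecutive
    frequencies, avoiding the per-(sample, frequency) trig of direct
    evaluation; the rotation drift over a few thousand steps is far below
    the 1e-6 tolerance the even-grid DFT equivalence is tested at.
    """
    n = t.size
    c = np.cos(2.0 * np.pi * f0 * t)
    s = np.sin(2.0 * np.pi * f0 * t)
    cd = np.cos(2.0 * np.pi * df * t)
    sd = np.sin(2.0 * np.pi * df * t)
    out = np.empty(nf)
    for k in range(nf):
        cy = 0.0
        sy = 0.0
        cc = 0.0
        cs = 0.0
        for j in range(n):
            cj = c[j]
            sj = s[j]
            cy += y[j] * cj
            sy += y[j] * sj
            cc += cj * cj
            cs += cj * sj
            c[j] = cj * cd[j] - sj * sd[j]
            s[j] = sj * cd[j] + cj * sd[j]
        c2 = 2.0 * cc - n  # sum cos(2 w t)
        s2 = 2.0 * cs  # sum sin(2 w t)
        r = np.hypot(c2, s2)
        half = 0.5 * np.arctan2(s2, c2)  # w * tau
        ct = np.cos(half)
        st = np.sin(half)
        cy_r = cy * ct + sy * st
        sy_r = sy * ct - cy * st
        den_c = 0.5 * (n + r)
        den_s = 0.5 * (n - r)
        p = 0.0
        if den_c > 1e-12 * n:
            p += cy_r * cy_r / den_c
        if den_s > 1e-12 * n:
            p += sy_r * sy_r / den_s
        out[k] = 0.5 * p
    return out


def lomb_periodogram(
    times: np.ndarray, values: np.ndarray, grid: SpectralGrid
) -> np.ndarray:
    """Classical Lomb normalized-least-squares periodogram, in power-density units.

    The raw Lomb ordinate P(omega) (the 1/2-normalized form; for even sampling
    it equals the DFT periodogram |Y_k|^2 / N) is rescaled by twice the mean
    sampling interval so that summing P_density * df over a dense grid
    estimates the series variance (s^2 when values are in s).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape or times.size < 16:
        raise RRValidationError("lomb_periodogram: need >= 16 aligned samples")
    if np.any(np.diff(times) <= 0):
        raise RRValidationError("lomb_periodogram: times must be strictly increasing")
    y = values - values.mean()
    if np.allclose(y, 0.0):
        return np.zeros_like(grid.frequencies)
    f = grid.frequencies
    df = f[1] - f[0]
    steps = np.diff(f)
    if np.allclose(steps, df, rtol=1e-9, atol=0.0):
        p_raw = _lomb_uniform_grid(times, y, float(f[0]), float(df), f.size)
    else:  # non-uniform grids fall back to direct per-frequency evaluation
        from scipy.signal import lombscargle as _scipy_ls

        p_raw = _scipy_ls(times, y, 2.0 * np.pi * f, precenter=False, normalize=False)
    mean_dt = (times[-1] - times[0]) / (times.size - 1)
    return 2.0 * mean_dt * p_raw


def log_band_powers(
    window: np.ndarray, n_bins: int = N_BINS, oversample: int = OVERSAMPLE
) -> tuple[np.ndarray, SpectralGrid]:
    """Power (s^2) of the tachogram in five log-spaced frequency bins.

    The time axis is the cumulative interval sum; band power is the rectangle-
    rule sum of periodogram density over the grid points in each bin, so the
    five powers sum exactly to the total power over the grid.
    """
    window = np.asarray(window, dtype=float)
    times = np.cumsum(window)
    grid = build_spectral_grid(float(times[-1]), oversample=oversample, n_bins=n_bins)
    density = lomb_periodogram(times, window, grid)
    # right-open bins, last bin closed at 0.5 Hz
    idx = np.clip(
        np.searchsorted(grid.bin_edges, grid.frequencies, side="right") - 1,
        0,
        n_bins - 1,
    )
    powers = np.bincount(idx, weights=density * grid.df, minlength=n_bins)
    return powers, grid


def extract_feature_row(window: np.ndarray, meta: dict) -> FeatureRow:
    """All ten scalar features for one window; ``pc_coeffs`` left empty.

    *meta* carries ``patient_id``, ``record_id`` and ``label``; any failure in
    a sub-computation is re-raised with the record id as context.
    """
    window = np.asarray(window, dtype=float)
    try:
        _, mobility, complexity = hjorth_parameters(window)
        a1, a2 = dfa_exponents(window)
        powers, _ = log_band_powers(window)
    except RRValidationError as exc:
        raise type(exc)(f"record {meta.get('record_id', '?')}: {exc}") from exc
    return FeatureRow(
        patient_id=str(meta.get("patient_id", "")),
        record_id=str(meta.get("record_id", "")),
        label=str(meta.get("label", meta.get("rhythm_class", ""))),
        mean_nn=mean_nn_interval(window),
        hjorth_mobility=mobility,
        hjorth_complexity=complexity,
        alpha1=a1,
        alpha2=a2,
        band_powers=tuple(float(p) for p in powers),
    )
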