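"""The 38 component features.

Each source component is described by 13 features of its time course, 9 of
its power spectrum and 16 of its sensor-space pattern.  All raw statistics
are log-transformed in a final step; statistics that can be non-positive
(ranges, fit errors, filter responses) are floored at ``EPS`` before the log
and flagged with a warning.

The spatial block includes a physics-based feature: the pattern is explained
by distributed dipolar sources inside a three-shell spherical head model via
a depth-weighted, Tikhonov-regularized minimum-l2-norm inverse, and the norm
of the estimated current density is used as a feature (compact cortical
sources yield small norms; patterns that no brain source can explain yield
large ones).
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.interpolate import griddata
from scipy.optimize import brentq

from .core_io import (
    DegenerateInputError,
    Decomposition,
    IcacleanError,
    Montage,
    reference_cap,
)

EPS = 1e-8

#: Canonical feature order (13 temporal, 9 spectral, 16 spatial).
FEATURE_NAMES = [
    "Variance", "MaxAmplitude", "Range", "MaxFirstDerivative", "Kurtosis",
    "ShannonEntropy", "DeterministicEntropy",
    "VarLocalVar1s", "VarLocalVar15s", "MeanLocalVar1s", "MeanLocalVar15s",
    "MeanLocalSkew1s", "MeanLocalSkew15s",
    "k1", "lambda", "k2", "FitError",
    "BP_0_3", "BP_4_7", "BP_8_13", "BP_14_30", "BP_31_45",
    "RangeWithinPattern", "SpatialDistExtrema",
    "SM_Left", "SM_LeftFrontal", "SM_Frontal", "SM_RightFrontal", "SM_Right",
    "SM_Occipital", "SM_Central",
    "DFT2D", "LaplaceFilter", "BorderActivation", "CurrentDensityNorm",
    "x", "y", "z",
]

_GROUP_TO_FEATURE = {
    "left": "SM_Left", "left_frontal": "SM_LeftFrontal",
    "frontal": "SM_Frontal", "right_frontal": "SM_RightFrontal",
    "right": "SM_Right", "occipital": "SM_Occipital", "central": "SM_Central",
}

FREQ_BANDS = {
    "BP_0_3": (0.0, 3.0), "BP_4_7": (4.0, 7.0), "BP_8_13": (8.0, 13.0),
    "BP_14_30": (14.0, 30.0), "BP_31_45": (31.0, 45.0),
}


class DegenerateFeatureWarning(UserWarning):
    """A raw statistic was non-positive and floored before the log."""


def _safe_log(value: float, what: str = "") -> float:
    if not value > EPS:
        if what:
            warnings.warn(f"{what} = {value:g} floored at {EPS:g} before log",
                          DegenerateFeatureWarning, stacklevel=3)
        return float(np.log(EPS))
    return float(np.log(value))


# ---------------------------------------------------------------------------
# Temporal features
# ---------------------------------------------------------------------------

#: samples used for the Lempel-Ziv complexity; the parsing cost grows
#: super-linearly and the complexity estimate is stable well before this
LZ_MAX_SAMPLES = 8192


def lz76_complexity(bits: np.ndarray) -> int:
    """Number of distinct phrases in the Lempel-Ziv (1976) parsing."""
    s = np.asarray(bits).astype(np.uint8).tobytes()
    n = len(s)
    i, c = 0, 0
    while i < n:
        length = 1
        # longest substring starting at i already seen in s[:i + length - 1]
        while i + length <= n and s.find(s[i:i + length], 0, i + length - 1) >= 0:
            length += 1
        c += 1
        i += length
    return c


def compute_temporal_features(source: np.ndarray, pattern: np.ndarray,
                              fs: float) -> dict[str, float]:
    """13 time-course features.

    ``Variance`` estimates the component's impact on the recording,
    Var(std(pattern) * source), and is computed before standardization; every
    other statistic is computed on the source scaled to unit variance.  Local
    statistics use non-overlapping windows of 1 s and 15 s.
    """
    s = np.asarray(source, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    sd = s.std()
    if sd < 1e-300:
        raise DegenerateInputError("constant source cannot be standardized")
    out: dict[str, float] = {}
    out["Variance"] = _safe_log(float(np.std(pattern) ** 2 * s.var()), "Variance")
    s = s / sd
    out["MaxAmplitude"] = _safe_log(float(np.max(np.abs(s))))
    out["Range"] = _safe_log(float(s.max() - s.min()), "Range")
    out["MaxFirstDerivative"] = _safe_log(float(np.max(np.abs(np.diff(s)))),
                                          "MaxFirstDerivative")
    out["Kurtosis"] = _safe_log(float(stats.kurtosis(s, fisher=True) + 3.0),
                                "Kurtosis")
    out["ShannonEntropy"] = _safe_log(_histogram_entropy(s), "ShannonEntropy")
    n = len(s)
    head = s[:LZ_MAX_SAMPLES]
    lz = lz76_complexity(head > np.median(head))
    out["DeterministicEntropy"] = _safe_log(
        lz / (len(head) / np.log2(len(head))), "DeterministicEntropy")
    for seconds in (1, 15):
        win = int(round(seconds * fs))
        if win > n:
            warnings.warn(
                f"recording shorter than the {seconds} s window; using full length",
                UserWarning,
            )
            win = n
        n_win = n // win
        seg = s[: n_win * win].reshape(n_win, win)
        local_var = seg.var(axis=1)
        out[f"VarLocalVar{seconds}s"] = _safe_log(float(local_var.var()),
                                                  f"VarLocalVar{seconds}s")
        out[f"MeanLocalVar{seconds}s"] = _safe_log(float(local_var.mean()),
                                                   f"MeanLocalVar{seconds}s")
        sk = np.abs(stats.skew(seg, axis=1))
        out[f"MeanLocalSkew{seconds}s"] = _safe_log(float(sk.mean()),
                                                    f"MeanLocalSkew{seconds}s")
    return out


def _histogram_entropy(s: np.ndarray, n_bins: int = 100, span: float = 5.0) -> float:
    """Differential entropy from a histogram over +-span standard deviations."""
    counts, edges = np.histogram(s, bins=n_bins, range=(-span, span))
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    width = edges[1] - edges[0]
    return float(-(p * np.log(p)).sum() + np.log(width))


# ---------------------------------------------------------------------------
# Spectral features
# ---------------------------------------------------------------------------

def estimate_log_spectrum(source: np.ndarray, fs: float
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Welch log power spectrum: 1 s Hann windows, 50% overlap, 1 Hz bins.

    The source is standardized to unit variance first, so spectra of
    differently scaled components are comparable.
    """
    if fs < 90:
        raise ValueError(
            f"sampling rate {fs} Hz too low: the spectral features need 45 Hz"
        )
    s = np.asarray(source, dtype=float)
    if len(s) < 2 * fs:
        raise ValueError("need at least 2 s of signal for the spectrum")
    sd = s.std()
    if sd < 1e-300:
        raise DegenerateInputError("constant source has no spectrum")
    nperseg = int(round(fs))
    freqs, psd = signal.welch(s / sd, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=nperseg // 2, scaling="density")
    # drop the DC bin: per-segment detrending biases it and no feature needs it
    return freqs[1:], np.log(np.maximum(psd[1:], 1e-15))


@dataclass
class SpectralFit:
    """Fit of the prototypical spectrum shape P(f) = k1 * f**-lam + k2."""

    k1: float
    lam: float
    k2: float
    mse: float
    anchors: tuple[tuple[float, float], ...]
    flags: tuple[str, ...]

    @property
    def features(self) -> dict[str, float]:
        return {
            "k1": _safe_log(self.k1),
            "lambda": _safe_log(self.lam),
            "k2": _safe_log(self.k2),
            "FitError": _safe_log(self.mse),
        }


_LAM_LO, _LAM_HI = 1e-3, 50.0


def _band_anchor(freqs: np.ndarray, logp: np.ndarray, lo: float, hi: float,
                 flags: list[str]) -> tuple[float, float]:
    """Lowest interior local minimum of the log spectrum within [lo, hi]."""
    band = np.where((freqs >= lo) & (freqs <= hi))[0]
    if band.size == 0:
        raise ValueError(f"spectrum does not cover the {lo}-{hi} Hz band")
    candidates = [
        i for i in band
        if 0 < i < len(freqs) - 1 and logp[i] < logp[i - 1] and logp[i] < logp[i + 1]
    ]
    if not candidates:
        flags.append(f"no-local-min-{lo:g}-{hi:g}")
        i = band[np.argmin(logp[band])]
    else:
        i = candidates[int(np.argmin(logp[candidates]))]
    return float(freqs[i]), float(logp[i])


def fit_spectral_curve(freqs: np.ndarray, logp: np.ndarray) -> SpectralFit:
    """Fit P(f) = k1 * f**-lam + k2 through three anchor points.

    Anchors: the log-spectrum value at 2 Hz, its local minimum within
    5-13 Hz and its local minimum within 33-39 Hz.  The three positive
    parameters are determined exactly by the anchors where a positive
    decreasing curve through them exists; otherwise lam is clamped (high for
    spectra with a rising high-frequency tail, which deviate maximally from
    the 1/f prototype) and k1/k2 are clipped at the EPS floor, with flags.
    """
    freqs = np.asarray(freqs, dtype=float)
    logp = np.asarray(logp, dtype=float)
    if freqs[0] > 2.0 or freqs[-1] < 45.0:
        raise ValueError("spectrum must cover 2-45 Hz")
    flags: list[str] = []
    i1 = int(np.argmin(np.abs(freqs - 2.0)))
    f1, y1 = float(freqs[i1]), float(logp[i1])
    f2, y2 = _band_anchor(freqs, logp, 5.0, 13.0, flags)
    f3, y3 = _band_anchor(freqs, logp, 33.0, 39.0, flags)
    p1, p2, p3 = np.exp([y1, y2, y3])

    def ratio(lam: float) -> float:
        a, b, c = f1 ** -lam, f2 ** -lam, f3 ** -lam
        return (a - b) / (b - c)

    lam = None
    d12, d23 = p1 - p2, p2 - p3
    if d23 > 0 and d12 >= 0:
        t = d12 / d23
        g_lo, g_hi = ratio(_LAM_LO) - t, ratio(_LAM_HI) - t
        if g_lo <= 0 <= g_hi:
            lam = brentq(lambda L: ratio(L) - t, _LAM_LO, _LAM_HI, xtol=1e-12)
        elif g_lo > 0:
            lam = _LAM_LO
            flags.append("lambda-clamped-low")
        else:
            lam = _LAM_HI
            flags.append("lambda-clamped-high")
    elif d23 > 0 and d12 < 0:
        lam = _LAM_LO
        flags.append("lambda-clamped-low")
    else:
        # rising (or flat) high-frequency tail: maximally non-1/f
        lam = _LAM_HI
        flags.append("lambda-clamped-high")
    denom = f1 ** -lam - f2 ** -lam
    k1 = d12 / denom if abs(denom) > 1e-300 else np.inf
    if not np.isfinite(k1) or k1 <= 0:
        k1 = EPS
        flags.append("k1-clipped")
    k2 = p1 - k1 * f1 ** -lam
    if not np.isfinite(k2) or k2 <= 0:
        k2 = EPS
        flags.append("k2-clipped")
    fit_band = (freqs >= 2.0) & (freqs <= 45.0)
    fitted = np.log(k1 * freqs[fit_band] ** -lam + k2)
    mse = float(np.mean((fitted - logp[fit_band]) ** 2))
    return SpectralFit(k1=float(k1), lam=float(lam), k2=float(k2), mse=mse,
                       anchors=((f1, y1), (f2, y2), (f3, y3)),
                       flags=tuple(flags))


def compute_band_powers(freqs: np.ndarray, logp: np.ndarray) -> dict[str, float]:
    """Average log power in the delta/theta/alpha/beta/gamma bands."""
    out = {}
    for name, (lo, hi) in FREQ_BANDS.items():
        mask = (freqs >= lo) & (freqs <= hi)
        if not np.any(mask):
            raise ValueError(f"no spectral bins in the {lo}-{hi} Hz band ({name})")
        out[name] = float(np.mean(logp[mask]))
    return out


# ---------------------------------------------------------------------------
# Pattern features: geometry and spatial frequency
# ---------------------------------------------------------------------------

def _unit_pattern(pattern: np.ndarray, montage: Montage) -> np.ndarray:
    p = np.asarray(pattern, dtype=float).ravel()
    if len(p) != montage.n_channels:
        raise ValueError(
            f"pattern length {len(p)} != montage channel count {montage.n_channels}"
        )
    norm = np.linalg.norm(p)
    if norm < 1e-300:
        raise DegenerateInputError("zero pattern")
    return p / norm


def compute_pattern_geometry_features(pattern: np.ndarray, montage: Montage
                                      ) -> dict[str, float]:
    """Range of activation, extrema distance and the 7 group means.

    The pattern is normalized to unit Euclidean norm; group means use the
    absolute activation (source sign is indeterminate).
    """
    p = _unit_pattern(pattern, montage)
    out = {
        "RangeWithinPattern": _safe_log(float(p.max() - p.min()),
                                        "RangeWithinPattern"),
        "SpatialDistExtrema": _safe_log(
            float(np.linalg.norm(montage.pos2d[int(np.argmax(p))]
                                 - montage.pos2d[int(np.argmin(p))])),
            "SpatialDistExtrema"),
    }
    for group, feat in _GROUP_TO_FEATURE.items():
        members = montage.groups.get(group)
        if not members:
            raise ValueError(f"montage has no electrodes in group {group!r}")
        idx = [montage.index(m) for m in members]
        out[feat] = _safe_log(float(np.mean(np.abs(p[idx]))), feat)
    return out


def interpolate_pattern_grid(pattern: np.ndarray, montage: Montage,
                             size: int = 64) -> np.ndarray:
    """Linear interpolation of the pattern onto a size x size square grid.

    The grid spans the bounding square of the projected electrode positions;
    cells outside the convex hull are filled by nearest-neighbour.
    """
    p = np.asarray(pattern, dtype=float).ravel()
    pts = montage.pos2d
    lo = float(pts.min())
    hi = float(pts.max())
    axis = np.linspace(lo, hi, size)
    gx, gy = np.meshgrid(axis, axis)
    try:
        grid = griddata(pts, p, (gx, gy), method="linear")
    except Exception as exc:  # degenerate (collinear) electrode layout
        raise IcacleanError(f"pattern interpolation failed: {exc}") from exc
    nearest = griddata(pts, p, (gx, gy), method="nearest")
    mask = np.isnan(grid)
    grid[mask] = nearest[mask]
    return grid


LAPLACE_KERNEL = np.array([[0.0, -1.0, 0.0],
                           [-1.0, 4.0, -1.0],
                           [0.0, -1.0, 0.0]])


def compute_spatial_frequency_features(pattern: np.ndarray, montage: Montage
                                       ) -> dict[str, float]:
    """2D-DFT high-frequency content and Laplacian edge energy.

    The unit-norm pattern is interpolated to 64x64; ``DFT2D`` is the mean log
    squared magnitude over the high-frequency half (column index >= 32) of
    the 1st and 4th quadrants of the unshifted 2D spectrum; ``LaplaceFilter``
    is the log Frobenius norm after valid-mode convolution with the 3x3
    Laplacian kernel.
    """
    p = _unit_pattern(pattern, montage)
    grid = interpolate_pattern_grid(p, montage, size=64)
    spec = np.abs(np.fft.fft2(grid)) ** 2
    high = spec[:, 32:]
    dft2d = float(np.mean(np.log(np.maximum(high, EPS ** 2))))
    lap = signal.convolve2d(grid, LAPLACE_KERNEL, mode="valid")
    return {
        "DFT2D": dft2d,
        "LaplaceFilter": _safe_log(float(np.linalg.norm(lap)), "LaplaceFilter"),
    }


def compute_border_activation(pattern: np.ndarray, montage: Montage) -> float:
    """+1 if the pattern peaks at the scalp border, else -1.

    +1 iff the global extremum lies in the montage's border set, or some
    electrode group attains its extremum at its outermost electrode while
    deviating at least two group standard deviations from the group mean.
    Both the pattern and its negation are tested (source sign is
    indeterminate), so the feature is sign-invariant.
    """
    p = _unit_pattern(pattern, montage)

    def peaked_at_border(v: np.ndarray) -> bool:
        if montage.names[int(np.argmax(v))] in montage.border_set:
            return True
        for group, members in montage.groups.items():
            if len(members) < 3:
                warnings.warn(f"group {group!r} has fewer than 3 electrodes; skipped",
                              UserWarning)
                continue
            idx = [montage.index(m) for m in members]
            vals = v[idx]
            radii = np.linalg.norm(montage.pos2d[idx], axis=1)
            outmost = int(np.argmax(radii))
            sd = vals.std()
            if sd < 1e-300:
                continue
            if int(np.argmax(vals)) == outmost and \
                    vals.max() - vals.mean() >= 2.0 * sd:
                return True
        return False

    return 1.0 if peaked_at_border(p) or peaked_at_border(-p) else -1.0


# ---------------------------------------------------------------------------
# Leadfield and current density
# ---------------------------------------------------------------------------

HEAD_RADIUS_CM = 10.0
SHELL_RADII = (0.87, 0.92, 1.0)            # brain, skull, scalp (head units)
SHELL_CONDUCTIVITIES = (1.0, 1.0 / 80.0, 1.0)
N_GRID_SOURCES = 2142
DEFAULT_REG_LAMBDA = 100.0
REG_LAMBDA_CANDIDATES = (0.0, 1.0, 10.0, 100.0, 1000.0)
_N_HARMONICS = 60
#: Gain of a unit depth-equalized source triplet, i.e. the unit convention of
#: the forward field.  Chosen so the regularizer (lambda = 100) falls in the
#: transition region of the operator's spectrum: smooth cortical topographies
#: have gains above it and spatially rough ones below it, the regime in which
#: the regularized minimum-norm estimate separates compact brain sources from
#: patterns no brain source can explain.
FORWARD_GAIN = 20.0


@dataclass
class Leadfield:
    """Forward model and cached inverse operator on the reference cap.

    ``F`` maps 3*m current moments (grid of m sources, 1 cm spacing) to
    sensor potentials; ``gamma`` holds the per-location depth-equalization
    weights; ``operator`` is the depth-weighted regularized minimum-norm
    source estimator (Gamma * J_lambda) whose columns correspond to
    ``channel_names``.
    """

    F: np.ndarray                 # n_channels x 3m
    grid: np.ndarray              # m x 3, centimetres
    gamma: np.ndarray             # m depth weights
    operator: np.ndarray          # 3m x n_channels
    channel_names: list[str]
    reg_lambda: float


def source_grid() -> np.ndarray:
    """The m = 2142 source locations: a 1 cm lattice inside the inner shell.

    Integer-centimetre lattice points sorted by (radius, x, y, z); the 2142
    closest to the head centre are kept (all well inside the brain shell).
    """
    limit = int(np.floor(SHELL_RADII[0] * HEAD_RADIUS_CM))
    axis = np.arange(-limit, limit + 1)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]).astype(float)
    r2 = np.sum(pts**2, axis=1)
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], r2))
    return pts[order[:N_GRID_SOURCES]]


def _shell_transfer(n_max: int) -> np.ndarray:
    """Per-degree scalp response of the three-shell model.

    For each spherical-harmonic degree n the radial part of the potential in
    shell j is a_j (r/R_j)^n + b_j (R_j/r)^(n+1); matching potential and
    radial current at the interfaces and zero current at the scalp yields a
    5x5 linear system whose solution gives the scalp potential per unit
    outgoing source coefficient (evaluated at the brain-shell radius).
    """
    r1, r2, r3 = SHELL_RADII
    s1, s2, s3 = SHELL_CONDUCTIVITIES
    t = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        q12 = (r1 / r2) ** n
        q21 = (r2 / r1) ** (n + 1)
        q23 = (r2 / r3) ** n
        q32 = (r3 / r2) ** (n + 1)
        m = np.array([
            # unknowns: a1, a2, b2, a3, b3
            [1.0, -q12, -q21, 0.0, 0.0],
            [s1 * n, -s2 * n * q12, s2 * (n + 1) * q21, 0.0, 0.0],
            [0.0, 1.0, 1.0, -q23, -q32],
            [0.0, s2 * n, -s2 * (n + 1), -s3 * n * q23, s3 * (n + 1) * q32],
            [0.0, 0.0, 0.0, n, -(n + 1.0)],
        ])
        rhs = np.array([-1.0, s1 * (n + 1.0), 0.0, 0.0, 0.0])
        a1, a2, b2, a3, b3 = np.linalg.solve(m, rhs)
        t[n] = a3 + b3
    return t


@functools.lru_cache(maxsize=1)
def _reference_forward() -> tuple[np.ndarray, np.ndarray]:
    """Forward matrix (115 x 3m) of the reference cap and the grid (cm)."""
    cap = reference_cap()
    grid_cm = source_grid()
    elec = cap.pos3d                                   # 115 x 3 unit vectors
    q = grid_cm / HEAD_RADIUS_CM                       # m x 3, head units
    b = np.linalg.norm(q, axis=1)
    rhat = np.divide(q, b[:, None], out=np.zeros_like(q), where=b[:, None] > 1e-12)
    rhat[b <= 1e-12] = (0.0, 0.0, 1.0)                 # centre: direction is moot
    cosg = np.clip(elec @ rhat.T, -1.0, 1.0)           # n_e x m
    sing = np.sqrt(np.maximum(0.0, 1.0 - cosg**2))
    # tangent unit vector at the source pointing toward each electrode
    that = elec[:, None, :] - cosg[:, :, None] * rhat[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        that = np.where(sing[:, :, None] > 1e-12, that / sing[:, :, None], 0.0)

    t_n = _shell_transfer(_N_HARMONICS)
    r1 = SHELL_RADII[0]
    ratio = b / r1                                     # < 1 for all grid points
    # Legendre recurrences accumulated over degrees
    p_prev = np.ones_like(cosg)                        # P_0
    p_cur = cosg.copy()                                # P_1
    p1_prev = np.zeros_like(cosg)                      # P_0^1
    p1_cur = -sing                                     # P_1^1 (Condon-Shortley)
    radial = np.zeros_like(cosg)
    tangential = np.zeros_like(cosg)
    scale = 1.0 / (4.0 * np.pi * SHELL_CONDUCTIVITIES[0] * r1**2)
    coef = np.ones_like(b)                             # (b/r1)^(n-1), n = 1
    for n in range(1, _N_HARMONICS + 1):
        w = scale * t_n[n] * coef                       # m-vector
        radial += (n * w)[None, :] * p_cur
        tangential += -w[None, :] * p1_cur
        coef = coef * ratio
        p_next = ((2 * n + 1) * cosg * p_cur - n * p_prev) / (n + 1)
        p_prev, p_cur = p_cur, p_next
        if n == 1:
            p1_next = 3.0 * cosg * p1_cur
        else:
            p1_next = ((2 * n + 1) * cosg * p1_cur - (n + 1) * p1_prev) / n
        p1_prev, p1_cur = p1_cur, p1_next

    m = grid_cm.shape[0]
    f = np.empty((elec.shape[0], 3 * m))
    for a in range(3):
        f[:, a::3] = radial * rhat[None, :, a] + tangential * that[:, :, a]
    return f, grid_cm


@functools.lru_cache(maxsize=4)
def _reference_leadfield(reg_lambda: float = DEFAULT_REG_LAMBDA) -> Leadfield:
    f, grid_cm = _reference_forward()
    m = grid_cm.shape[0]
    blocks = f.reshape(f.shape[0], m, 3)
    gamma = np.sqrt(np.sum(blocks**2, axis=(0, 2)))    # per-location gain
    gamma = np.maximum(gamma, 1e-300) / FORWARD_GAIN
    b = f / np.repeat(gamma, 3)[None, :]               # F Gamma^-1
    gram = b @ b.T
    operator = b.T @ np.linalg.solve(gram + reg_lambda * np.eye(gram.shape[0]),
                                     np.eye(gram.shape[0]))
    return Leadfield(F=f, grid=grid_cm, gamma=gamma, operator=operator,
                     channel_names=reference_cap().names,
                     reg_lambda=reg_lambda)


def build_leadfield(montage: Montage | None = None,
                    reg_lambda: float = DEFAULT_REG_LAMBDA) -> Leadfield:
    """Leadfield restricted to ``montage`` (default: the full reference cap).

    The inverse operator is precomputed once on the 115-electrode reference
    cap and subselected by channel name, so current-density values are
    comparable across caps of different sizes.
    """
    ref = _reference_leadfield(reg_lambda)
    if montage is None:
        return ref
    unknown = [n for n in montage.names if n not in ref.channel_names]
    if unknown:
        raise ValueError(
            f"channels not in the reference cap: {unknown}; current-density "
            "features require reference-cap channel names"
        )
    idx = [ref.channel_names.index(n) for n in montage.names]
    return Leadfield(F=ref.F[idx], grid=ref.grid, gamma=ref.gamma,
                     operator=ref.operator[:, idx],
                     channel_names=list(montage.names),
                     reg_lambda=ref.reg_lambda)


def compute_current_density_features(pattern: np.ndarray, montage: Montage,
                                     leadfield: Leadfield | None = None
                                     ) -> dict[str, float]:
    """Current-density norm of the pattern and the strongest source location.

    The unit-norm pattern is explained by the depth-weighted regularized
    minimum-norm source estimate; the feature is the log norm of the
    depth-weighted estimate, and (x, y, z) are the grid coordinates (cm) of
    the location with maximal current-moment magnitude.
    """
    p = _unit_pattern(pattern, montage)
    lf = leadfield if leadfield is not None else build_leadfield(montage)
    if lf.channel_names != montage.names:
        lf = build_leadfield(montage, lf.reg_lambda)
    weighted = lf.operator @ p                      # Gamma * z_hat
    moments = weighted.reshape(-1, 3)
    # localize on the depth-equalized magnitude |Gamma z|: the unweighted
    # |z| over-boosts deep grid points (small gain) and biases the peak inward
    mags = np.linalg.norm(moments, axis=1)
    loc = lf.grid[int(np.argmax(mags))]
    return {
        "CurrentDensityNorm": _safe_log(float(np.linalg.norm(weighted)),
                                        "CurrentDensityNorm"),
        "x": float(loc[0]), "y": float(loc[1]), "z": float(loc[2]),
    }


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def compute_component_features(source: np.ndarray, pattern: np.ndarray,
                               fs: float, montage: Montage,
                               leadfield: Leadfield | None = None
                               ) -> dict[str, float]:
    """All 38 features of one component, keyed by canonical name."""
    out = compute_temporal_features(source, pattern, fs)
    freqs, logp = estimate_log_spectrum(source, fs)
    out.update(fit_spectral_curve(freqs, logp).features)
    out.update(compute_band_powers(freqs, logp))
    out.update(compute_pattern_geometry_features(pattern, montage))
    out.update(compute_spatial_frequency_features(pattern, montage))
    out["BorderActivation"] = compute_border_activation(pattern, montage)
    out.update(compute_current_density_features(pattern, montage, leadfield))
    return {name: out[name] for name in FEATURE_NAMES}


def assemble_features(decomp: Decomposition, montage: Montage,
                      leadfield: Leadfield | None = None) -> pd.DataFrame:
    """Feature matrix (components x 38) for a decomposition."""
    if decomp.channel_names != montage.names:
        raise ValueError("decomposition and montage channel names differ")
    if leadfield is None:
        leadfield = build_leadfield(montage)
    rows = []
    for i in range(decomp.n_components):
        try:
            rows.append(compute_component_features(
                decomp.sources[i], decomp.patterns[:, i], decomp.fs,
                montage, leadfield))
        except Exception as exc:
            raise IcacleanError(f"feature extraction failed for component {i}: {exc}"
                                ) from exc
    return pd.DataFrame(rows, columns=FEATURE_NAMES)
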