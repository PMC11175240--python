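"""Trunk-acceleration gait indexes.

Implements the indexes computed from a single lumbar IMU trial:

* **Harmonic ratio (HR)** — per-stride discrete Fourier amplitudes at the
  first 20 stride-frequency harmonics; HR_AP / HR_V = sum of the first 10
  even-harmonic amplitudes over the first 10 odd ones (inverted for ML),
  averaged across strides.  Higher HR means smoother, more symmetric gait.
* **Step-length CV** — 100 x SD / mean of the step-length series.
* **Recurrence quantification (RQArec, RQAdet)** — percentage of recurrent
  points and percentage of recurrent points on diagonal line structures of a
  delay-embedded recurrence plot.
* **Short-term largest Lyapunov exponent (sLLE)** — Rosenstein's
  nearest-neighbour divergence method on the time-normalised (100 samples per
  stride) acceleration series; reported per stride.

Embedding parameters follow the false-nearest-neighbour (dimension) and
average-mutual-information (delay) criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import interp1d
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

N_HARMONICS = 20
SAMPLES_PER_STRIDE = 100


class DegenerateInputError(ValueError):
    """Raised when an index is undefined for the given input."""


# ---------------------------------------------------------------------------
# embedding helpers
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingParams:
    """State-space reconstruction parameters.

    Defaults (m=5, tau=10 samples, Rtol=17, Atol=2) follow the false-neighbour
    and first-AMI-minimum analyses on trunk-acceleration data; the Theiler
    window defaults to tau * (m - 1) samples.
    """

    m: int = 5
    tau: int = 10
    rtol: float = 17.0
    atol: float = 2.0
    theiler: int | None = None

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("embedding dimension m must be >= 2")
        if self.tau < 1:
            raise ValueError("delay tau must be >= 1")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("FNN thresholds must be > 0")

    @property
    def theiler_window(self) -> int:
        return self.tau * (self.m - 1) if self.theiler is None else self.theiler


def delay_embed(series: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Delay-embed a 1-D series into an (N, m) matrix of state vectors."""
    x = np.asarray(series, dtype=float)
    n = len(x) - (m - 1) * tau
    if n < 1:
        raise DegenerateInputError("series too short for the requested embedding")
    return np.column_stack([x[i * tau: i * tau + n] for i in range(m)])


# ---------------------------------------------------------------------------
# harmonic ratio
# ---------------------------------------------------------------------------


@dataclass
class HarmonicSpectrum:
    """Per-stride amplitudes at harmonics 1..20 of the stride frequency."""

    amplitudes: np.ndarray  # A_1 .. A_20
    axis: str
    stride_index: int

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.shape != (N_HARMONICS,):
            raise ValueError(f"expected {N_HARMONICS} harmonic amplitudes")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be >= 0")

    @property
    def even_sum(self) -> float:
        return float(self.amplitudes[1::2].sum())  # A_2, A_4, ..., A_20

    @property
    def odd_sum(self) -> float:
        return float(self.amplitudes[0::2].sum())  # A_1, A_3, ..., A_19


def lowpass_filter(x: np.ndarray, fs: float, cutoff: float = 20.0,
                   order: int = 4, btype: str = "lowpass") -> np.ndarray:
    """Zero-phase Butterworth filter (4th order, 20 Hz low-pass by default)."""
    nyq = fs / 2.0
    if cutoff >= nyq:
        return np.asarray(x, dtype=float)
    b, a = sps.butter(order, cutoff / nyq, btype=btype)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float))


def _resample_stride(segment: np.ndarray, n_out: int) -> np.ndarray:
    """Cubic resampling of one stride segment to ``n_out`` samples per period."""
    L = len(segment) - 1
    f = interp1d(np.arange(L + 1), segment, kind="cubic")
    return f(np.linspace(0.0, L, n_out, endpoint=False))


def stride_harmonics(signal, axis: str, n_harm: int = N_HARMONICS,
                     filter_mode: str | None = "lowpass",
                     cutoff: float = 20.0) -> list[HarmonicSpectrum]:
    """Per-stride harmonic amplitudes of one acceleration axis.

    Each stride segment is cubically resampled to 100 samples (exactly one
    period) and its discrete Fourier amplitudes at harmonics 1..n_harm of the
    stride frequency are returned.  A zero-phase Butterworth filter (default
    20 Hz low-pass) removes out-of-band noise first; pass
    ``filter_mode=None`` to disable.
    """
    x = signal.axis(axis)
    if signal.n_strides < 1:
        raise DegenerateInputError("signal contains no complete stride")
    if filter_mode is not None:
        x = lowpass_filter(x, signal.fs, cutoff=cutoff,
                           btype="highpass" if filter_mode == "highpass" else "lowpass")
    spectra = []
    min_len = 2 * n_harm + 1
    for k in range(signal.n_strides):
        a, b = signal.stride_events[k], signal.stride_events[k + 1]
        seg = x[a: b + 1]
        if len(seg) < min_len:
            warnings.warn(f"stride {k} too short to resolve {n_harm} harmonics; skipped")
            continue
        rs = _resample_stride(seg, SAMPLES_PER_STRIDE)
        X = np.fft.rfft(rs)
        amps = 2.0 * np.abs(X[1: n_harm + 1]) / SAMPLES_PER_STRIDE
        full = np.zeros(N_HARMONICS)
        full[:n_harm] = amps
        spectra.append(HarmonicSpectrum(full, axis=axis, stride_index=k))
    if not spectra:
        raise DegenerateInputError("no stride long enough for harmonic analysis")
    return spectra


def harmonic_ratio(spectra: list[HarmonicSpectrum], axis: str | None = None) -> float:
    """Mean harmonic ratio across strides.

    AP / V axes: sum of the first 10 even harmonics over the first 10 odd
    harmonics; ML is the inverse ratio.  Strides with a zero denominator are
    excluded with a warning.
    """
    if not spectra:
        raise DegenerateInputError("no spectra provided")
    axis = axis or spectra[0].axis
    if any(s.axis != axis for s in spectra):
        raise ValueError("spectra axis tags are inconsistent")
    ratios = []
    for s in spectra:
        num, den = (s.odd_sum, s.even_sum) if axis == "ML" else (s.even_sum, s.odd_sum)
        if den == 0.0:
            warnings.warn(f"stride {s.stride_index}: zero HR denominator; excluded")
            continue
        ratios.append(num / den)
    if not ratios:
        raise DegenerateInputError("harmonic ratio undefined: all strides excluded")
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# step-length variability
# ---------------------------------------------------------------------------


def cv_step_length(step_lengths: np.ndarray) -> float:
    """Step-length coefficient of variation, 100 x SD / mean (sample SD, n-1)."""
    steps = np.asarray(step_lengths, dtype=float)
    if len(steps) < 2:
        raise DegenerateInputError("need at least 2 steps")
    mean = steps.mean()
    if mean <= 0:
        raise DegenerateInputError("mean step length must be > 0")
    return float(100.0 * steps.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# average mutual information (delay selection)
# ---------------------------------------------------------------------------


def average_mutual_information(series: np.ndarray, lags, bins: int = 16) -> np.ndarray:
    """Histogram-based AMI (nats) between x(t) and x(t + lag) for each lag.

    Equal-width bins span the global range of the series on both axes.
    """
    x = np.asarray(series, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise DegenerateInputError("constant series: AMI undefined")
    edges = np.linspace(lo, hi, bins + 1)
    edges[-1] += 1e-12  # include the maximum in the last bin
    out = np.empty(len(lags))
    for i, lag in enumerate(lags):
        a, b = x[: len(x) - lag] if lag else x, x[lag:]
        joint, _, _ = np.histogram2d(a, b, bins=[edges, edges])
        pj = joint / joint.sum()
        px = pj.sum(axis=1)
        py = pj.sum(axis=0)
        nz = pj > 0
        denom = np.outer(px, py)
        out[i] = float(np.sum(pj[nz] * np.log(pj[nz] / denom[nz])))
    return out


def ami_delay(series: np.ndarray, tau_min: int = 7, tau_max: int = 18,
              bins: int = 16) -> int:
    """Delay tau: first local minimum of the AMI in [tau_min, tau_max].

    AMI is also evaluated one lag either side of the range so boundary lags
    can qualify as local minima; if no local minimum exists the argmin over
    the range is returned.
    """
    lo = max(1, tau_min - 1)
    lags = list(range(lo, tau_max + 2))
    ami = average_mutual_information(series, lags, bins=bins)
    for tau in range(tau_min, tau_max + 1):
        i = lags.index(tau)
        if i == 0 or i == len(lags) - 1:
            continue
        if ami[i] < ami[i - 1] and ami[i] <= ami[i + 1]:
            return tau
    in_range = [lags.index(t) for t in range(tau_min, tau_max + 1)]
    return int(lags[in_range[int(np.argmin(ami[in_range]))]])


# ---------------------------------------------------------------------------
# false nearest neighbours (dimension selection)
# ---------------------------------------------------------------------------


def fnn_fraction(series: np.ndarray, m: int, tau: int,
                 rtol: float = 17.0, atol: float = 2.0) -> float:
    """Fraction of false nearest neighbours at embedding dimension ``m``.

    A neighbour pair is false if the extra-coordinate distance grows by more
    than ``rtol`` relative to the m-dimensional distance, or if the (m+1)-d
    distance exceeds ``atol`` times the attractor size (SD of the series).
    """
    x = np.asarray(series, dtype=float)
    n = len(x) - m * tau  # points embeddable at both m and m+1
    if n < 10:
        raise DegenerateInputError("series too short for FNN analysis")
    emb = delay_embed(x, m, tau)[:n]
    tree = cKDTree(emb)
    dist, idx = tree.query(emb, k=2)
    d_m, j = dist[:, 1], idx[:, 1]
    ra = x.std()
    extra = np.abs(x[np.arange(n) + m * tau] - x[j + m * tau])
    d_m1 = np.sqrt(d_m**2 + extra**2)
    # (near-)duplicate states are true neighbours iff the extra coordinate
    # also coincides, up to floating-point noise relative to attractor size
    tiny = 1e-10 * ra
    dup = d_m <= tiny
    ratio = np.where(dup,
                     np.where(extra > tiny, np.inf, 0.0),
                     extra / np.where(dup, 1.0, d_m))
    false = (ratio > rtol) | (d_m1 / ra > atol)
    return float(false.mean())


def fnn_dimension(series: np.ndarray, tau: int, m_min: int = 2, m_max: int = 10,
                  rtol: float = 17.0, atol: float = 2.0,
                  threshold: float = 0.01) -> int:
    """Smallest embedding dimension with an FNN fraction below ``threshold``.

    Falls back to the dimension with the smallest fraction if none drops
    below the threshold within the search range.
    """
    fracs = []
    for m in range(m_min, m_max + 1):
        f = fnn_fraction(series, m, tau, rtol=rtol, atol=atol)
        fracs.append(f)
        if f < threshold:
            return m
    return int(m_min + int(np.argmin(fracs)))


# ---------------------------------------------------------------------------
# recurrence quantification
# ---------------------------------------------------------------------------


@dataclass
class RecurrencePlot:
    """Binary recurrence matrix with its diagonal line-length distribution."""

    R: np.ndarray
    N: int
    radius: float
    line_hist: np.ndarray  # line_hist[l] = number of diagonal lines of length l
    l_min: int


def _diagonal_line_hist(R: np.ndarray, offsets) -> np.ndarray:
    """Histogram of maximal diagonal run lengths over the given offsets."""
    N = R.shape[0]
    hist = np.zeros(N + 1, dtype=int)
    for off in offsets:
        diag = np.diagonal(R, offset=off).astype(np.int8)
        # run lengths via edges of the padded indicator
        padded = np.concatenate(([0], diag, [0]))
        edges = np.diff(padded)
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for length in ends - starts:
            hist[length] += 1
    return hist


def recurrence_quantify(series: np.ndarray, params: EmbeddingParams | None = None,
                        radius: float | None = None,
                        recurrence_rate: float = 0.025,
                        radius_rule: str = "fixed_rate",
                        l_min: int = 2,
                        literal: bool = False):
    """Recurrence plot and the %recurrence / %determinism statistics.

    The recurrence matrix is R_ij = 1 iff the Euclidean state-space distance
    is <= radius.  By default the main diagonal and the Theiler band
    |i - j| <= tau*(m-1) are excluded (``literal=True`` keeps them, matching
    the textbook N^2 normalisation with self-recurrences).  If no radius is
    given it is set by ``radius_rule``: ``"fixed_rate"`` picks the distance
    quantile attaining ``recurrence_rate`` among considered pairs;
    ``"mean_fraction"`` uses ``recurrence_rate`` times the mean distance.

    Returns ``(RecurrencePlot, RQArec %, RQAdet %)``.
    """
    params = params or EmbeddingParams()
    emb = delay_embed(series, params.m, params.tau)
    N = len(emb)
    if N < 10:
        raise DegenerateInputError("need at least 10 embedded points")
    if radius is not None and radius <= 0:
        raise ValueError("radius must be > 0")

    D = cdist(emb, emb)
    w = 0 if literal else params.theiler_window
    lag = np.abs(np.arange(N)[:, None] - np.arange(N)[None, :])
    considered = np.ones_like(D, dtype=bool) if literal else lag > w

    if radius is None:
        dists = D[considered]
        if radius_rule == "mean_fraction":
            radius = float(recurrence_rate * dists.mean())
        else:
            radius = float(np.quantile(dists, recurrence_rate))

    R = (D <= radius) & considered
    rec = 100.0 * R.sum() / (N * N)

    offsets = range(-(N - 1), N) if literal else \
        [o for o in range(-(N - 1), N) if abs(o) > w]
    hist = _diagonal_line_hist(R, offsets)
    lengths = np.arange(len(hist))
    total = float(np.sum(lengths * hist))
    det = 0.0 if total == 0 else 100.0 * float(np.sum(lengths[l_min:] * hist[l_min:])) / total
    rp = RecurrencePlot(R=R.astype(np.uint8), N=N, radius=radius,
                        line_hist=hist, l_min=l_min)
    return rp, float(rec), float(det)


# ---------------------------------------------------------------------------
# short-term largest Lyapunov exponent (Rosenstein)
# ---------------------------------------------------------------------------


def _nearest_neighbors_theiler(emb: np.ndarray, theiler: int,
                               chunk: int = 256) -> np.ndarray:
    """Index of each point's nearest neighbour outside the Theiler window."""
    N = len(emb)
    nn = np.full(N, -1, dtype=int)
    idx = np.arange(N)
    for a in range(0, N, chunk):
        b = min(a + chunk, N)
        d = np.sqrt(((emb[a:b, None, :] - emb[None, :, :]) ** 2).sum(-1))
        mask = np.abs(idx[a:b, None] - idx[None, :]) <= theiler
        d[mask] = np.inf
        nn[a:b] = np.argmin(d, axis=1)
    return nn


def rosenstein_divergence(series: np.ndarray, m: int, tau: int,
                          theiler: int, n_steps: int) -> np.ndarray:
    """Mean log nearest-neighbour divergence curve <ln d_j(i)>, i = 0..n_steps.

    For each embedded point the nearest neighbour outside the Theiler window
    is found; pairs are followed forward and the log distances averaged over
    all pairs still inside the series.  Zero distances are floored at 1e-12.
    """
    emb = delay_embed(series, m, tau)
    N = len(emb)
    if N < theiler + 2:
        raise DegenerateInputError("series too short for neighbour search")
    nn = _nearest_neighbors_theiler(emb, theiler)
    curve = np.empty(n_steps + 1)
    i_idx = np.arange(N)
    for k in range(n_steps + 1):
        valid = (i_idx + k < N) & (nn + k < N)
        if not np.any(valid):
            curve[k:] = curve[k - 1] if k else np.nan
            break
        d = np.linalg.norm(emb[i_idx[valid] + k] - emb[nn[valid] + k], axis=1)
        curve[k] = float(np.mean(np.log(np.maximum(d, 1e-12))))
    return curve


def lyapunov_rosenstein(series: np.ndarray, m: int, tau: int, theiler: int,
                        fit_steps: tuple[int, int], dt: float = 1.0) -> float:
    """Largest Lyapunov exponent: least-squares slope of the divergence curve.

    ``fit_steps`` are (start, stop) indices into the curve; ``dt`` converts
    the slope from per-sample to the caller's time unit.
    """
    lo, hi = fit_steps
    curve = rosenstein_divergence(series, m, tau, theiler, hi)
    k = np.arange(lo, hi + 1)
    slope = np.polyfit(k * dt, curve[lo: hi + 1], 1)[0]
    return float(slope)


def time_normalize(signal, axis: str,
                   samples_per_stride: int = SAMPLES_PER_STRIDE) -> np.ndarray:
    """Concatenate all strides, each cubically resampled to a fixed length."""
    x = signal.axis(axis)
    parts = []
    for k in range(signal.n_strides):
        a, b = signal.stride_events[k], signal.stride_events[k + 1]
        parts.append(_resample_stride(x[a: b + 1], samples_per_stride))
    return np.concatenate(parts)


def slle_rosenstein(signal, axis: str, params: EmbeddingParams | None = None,
                    fit_window: tuple[float, float] = (0.0, 0.5),
                    min_strides: int = 20) -> float:
    """Short-term largest Lyapunov exponent of one acceleration axis (1/stride).

    The unfiltered series is time-normalised to 100 samples per stride,
    delay-embedded (defaults m=5, tau=10), and the mean log divergence from
    each point's nearest neighbour (Theiler window of one stride) is fitted
    over ``fit_window`` expressed in strides (default 0-0.5).
    """
    params = params or EmbeddingParams()
    if signal.n_strides < min_strides:
        raise DegenerateInputError(
            f"need at least {min_strides} strides, got {signal.n_strides}")
    series = time_normalize(signal, axis)
    lo = int(round(fit_window[0] * SAMPLES_PER_STRIDE))
    hi = int(round(fit_window[1] * SAMPLES_PER_STRIDE))
    return lyapunov_rosenstein(series, params.m, params.tau,
                               theiler=SAMPLES_PER_STRIDE,
                               fit_steps=(lo, hi),
                               dt=1.0 / SAMPLES_PER_STRIDE)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


@dataclass
class ExtractConfig:
    """Which indexes to compute and with what parameters."""

    embedding: EmbeddingParams = field(default_factory=EmbeddingParams)
    filter_mode: str | None = "lowpass"
    cutoff: float = 20.0
    rqa_axis: str = "AP"
    recurrence_rate: float = 0.025
    l_min: int = 2
    rqa_max_points: int | None = 1200
    fit_window: tuple[float, float] = (0.0, 0.5)
    min_strides: int = 20
    compute_hr: bool = True
    compute_cv: bool = True
    compute_rqa: bool = True
    compute_slle: bool = True


@dataclass
class GaitIndexes:
    """Full set of trunk-acceleration gait indexes for one trial.

    Indexes that could not be computed are None and listed in ``missing``.
    """

    HR_AP: float | None = None
    HR_ML: float | None = None
    HR_V: float | None = None
    CV_steplength: float | None = None
    RQArec: float | None = None
    RQAdet: float | None = None
    sLLE_AP: float | None = None
    sLLE_ML: float | None = None
    sLLE_V: float | None = None
    missing: tuple = ()

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("HR_AP", "HR_ML", "HR_V", "CV_steplength", "RQArec",
                 "RQAdet", "sLLE_AP", "sLLE_ML", "sLLE_V")}


def extract_all(signal, step_lengths=None,
                config: ExtractConfig | None = None) -> GaitIndexes:
    """Compute all enabled gait indexes from one trial.

    Deterministic given inputs and config.  Individual index failures are
    recorded in ``missing`` rather than aborting the whole extraction.
    """
    config = config or ExtractConfig()
    if signal.n_strides < 1:
        raise DegenerateInputError("signal has no stride events")
    out = GaitIndexes()
    missing = []

    if config.compute_hr:
        for ax in ("AP", "ML", "V"):
            try:
                spectra = stride_harmonics(signal, ax,
                                           filter_mode=config.filter_mode,
                                           cutoff=config.cutoff)
                setattr(out, f"HR_{ax}", harmonic_ratio(spectra, ax))
            except (DegenerateInputError, ValueError) as exc:
                warnings.warn(f"HR_{ax} failed: {exc}")
                missing.append(f"HR_{ax}")
    if config.compute_cv and step_lengths is not None:
        try:
            out.CV_steplength = cv_step_length(step_lengths)
        except DegenerateInputError as exc:
            warnings.warn(f"CV_steplength failed: {exc}")
            missing.append("CV_steplength")
    elif config.compute_cv:
        missing.append("CV_steplength")
    if config.compute_rqa:
        try:
            series = time_normalize(signal, config.rqa_axis)
            if config.rqa_max_points is not None:
                series = series[: config.rqa_max_points]
            _, rec, det = recurrence_quantify(
                series, config.embedding,
                recurrence_rate=config.recurrence_rate, l_min=config.l_min)
            out.RQArec, out.RQAdet = rec, det
        except (DegenerateInputError, ValueError) as exc:
            warnings.warn(f"RQA failed: {exc}")
            missing.extend(["RQArec", "RQAdet"])
    if config.compute_slle:
        for ax in ("AP", "ML", "V"):
            try:
                setattr(out, f"sLLE_{ax}",
                        slle_rosenstein(signal, ax, config.embedding,
                                        fit_window=config.fit_window,
                                        min_strides=config.min_strides))
            except (DegenerateInputError, ValueError) as exc:
                warnings.warn(f"sLLE_{ax} failed: {exc}")
                missing.append(f"sLLE_{ax}")
    out.missing = tuple(missing)
    return out
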