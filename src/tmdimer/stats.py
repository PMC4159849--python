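"""Sampling-completeness statistics for interface-cluster distributions.

To judge whether an ensemble of self-assembly runs has sampled the
interface space, cluster-frequency vectors from two subsamples are
compared with Pearson's correlation coefficient r.  For subsample size
n the procedure draws n simulations without replacement (two disjoint
draws from one pool for the autocorrelation; one draw from each of two
pools for the cross-condition correlation), repeats this ``n_permutations``
times (default 1000), and records mean and sd of r per n.

A double exponential

    r(n) = a (1 - exp(-b n)) + c (1 - exp(-d n)),      a, b, c, d >= 0

is then fitted by (weighted) least squares; the fast term reflects the
number of runs needed to find all important clusters, the slow term the
number needed to cover their frequency distribution.  The fitted
saturation value is ``limit = a + c``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


def frequency_vector(labels, cluster_space) -> np.ndarray:
    """Relative frequencies over a fixed, global cluster space.

    Unobserved clusters get frequency zero so that vectors from
    different samples are comparable.  Raises on labels outside the
    space.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    space = list(cluster_space)
    index = {c: i for i, c in enumerate(space)}
    counts = np.zeros(len(space))
    for lab in labels:
        if lab not in index:
            raise ValueError(f"label {lab!r} outside cluster space")
        counts[index[lab]] += 1
    return counts / counts.sum()


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson's correlation coefficient of two frequency vectors.

    Raises ``ValueError`` for length mismatch, length < 2, or zero
    variance in either vector (the coefficient is undefined there and
    is never silently reported as 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 entries")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float((xc * yc).sum() / (sx * sy))


@dataclass
class CorrelationCurve:
    """Subsampled correlation r as a function of subsample size n."""

    n_values: np.ndarray
    mean_r: np.ndarray
    sd_r: np.ndarray
    n_permutations: int = 1000
    mode: str = "cross"
    n_invalid: np.ndarray | None = None  # permutations with undefined r, per n

    def __post_init__(self):
        self.n_values = np.asarray(self.n_values, dtype=int)
        self.mean_r = np.asarray(self.mean_r, dtype=float)
        self.sd_r = np.asarray(self.sd_r, dtype=float)
        finite = np.isfinite(self.mean_r)
        if np.any(np.abs(self.mean_r[finite]) > 1 + 1e-12):
            raise ValueError("mean_r must lie in [-1, 1]")
        if np.any(self.sd_r[np.isfinite(self.sd_r)] < 0):
            raise ValueError("sd_r must be >= 0")


def subsampled_correlation(
    labels_a,
    labels_b=None,
    n_values=None,
    n_permutations: int = 1000,
    seed: int = 0,
    mode: str = "cross",
    cluster_space=None,
) -> CorrelationCurve:
    """Correlation between cluster-frequency vectors of random subsamples.

    Parameters
    ----------
    labels_a, labels_b : sequences of cluster labels
        One final-interface label per simulation.  ``labels_b`` is
        ignored in ``auto`` mode (the two subsamples are disjoint draws
        from ``labels_a``).
    n_values : iterable of int
        Subsample sizes.  ``auto`` mode requires ``2 n <= len(labels_a)``;
        ``cross`` mode requires ``n`` within each pool.
    mode : {"cross", "auto"}
    cluster_space : optional
        Global cluster space; defaults to the union of observed labels.

    Permutations in which either frequency vector has zero variance
    yield an undefined r and are excluded from mean/sd; their count is
    reported per n in ``n_invalid`` (all-invalid points give NaN).
    """
    if mode not in ("cross", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    labels_a = list(labels_a)
    labels_b = list(labels_b) if labels_b is not None else None
    if mode == "auto":
        pool_b = labels_a
    else:
        if labels_b is None:
            raise ValueError("cross mode needs labels_b")
        pool_b = labels_b
    if cluster_space is None:
        cluster_space = sorted(set(labels_a) | set(pool_b), key=str)
    cluster_space = list(cluster_space)
    if n_values is None:
        raise ValueError("n_values is required")
    n_values = np.asarray(list(n_values), dtype=int)

    rng = np.random.default_rng(seed)
    mean_r = np.empty(len(n_values))
    sd_r = np.empty(len(n_values))
    n_invalid = np.zeros(len(n_values), dtype=int)
    arr_a = np.array(labels_a, dtype=object)
    arr_b = np.array(pool_b, dtype=object)

    for k, n in enumerate(n_values):
        if mode == "auto":
            if 2 * n > len(arr_a):
                raise ValueError(f"auto mode needs 2n <= pool size (n={n})")
        else:
            if n > len(arr_a) or n > len(arr_b):
                raise ValueError(f"n={n} exceeds a pool size")
        rs = []
        for _ in range(n_permutations):
            if mode == "auto":
                perm = rng.permutation(len(arr_a))
                sample_x = arr_a[perm[:n]]
                sample_y = arr_a[perm[n : 2 * n]]
            else:
                sample_x = arr_a[rng.choice(len(arr_a), size=n, replace=False)]
                sample_y = arr_b[rng.choice(len(arr_b), size=n, replace=False)]
            fx = frequency_vector(sample_x, cluster_space)
            fy = frequency_vector(sample_y, cluster_space)
            try:
                rs.append(pearson_r(fx, fy))
            except ValueError:
                n_invalid[k] += 1
        if rs:
            mean_r[k] = float(np.mean(rs))
            sd_r[k] = float(np.std(rs))
        else:
            mean_r[k] = np.nan
            sd_r[k] = np.nan
    return CorrelationCurve(n_values, mean_r, sd_r, n_permutations, mode, n_invalid)


# -- double-exponential fit ------------------------------------------------


@dataclass
class DoubleExpFit:
    """Parameters of r(n) = a (1 - e^{-b n}) + c (1 - e^{-d n})."""

    a: float
    b: float
    c: float
    d: float
    covariance: np.ndarray | None = None
    residual: float = 0.0

    @property
    def limit(self) -> float:
        """Saturation value of the fitted curve: a + c."""
        return self.a + self.c

    def __call__(self, n):
        return double_exponential(np.asarray(n, dtype=float), self.a, self.b, self.c, self.d)


def double_exponential(n, a, b, c, d):
    return a * (1.0 - np.exp(-b * n)) + c * (1.0 - np.exp(-d * n))


class FitError(RuntimeError):
    """Raised when no start point of the least-squares fit converges."""


def fit_double_exponential(
    curve: CorrelationCurve,
    weighted: bool = True,
    seed: int = 0,
    n_random_starts: int = 8,
) -> DoubleExpFit:
    """Least-squares fit of the double exponential to a correlation curve.

    Points with NaN mean are dropped.  With ``weighted=True`` residuals
    are weighted by 1/sd (points with sd == 0 get the smallest positive
    sd, i.e. the largest finite weight).  All four parameters are
    constrained non-negative, and the amplitudes a and c are bounded by
    1 because a correlation coefficient cannot exceed 1 (this keeps the
    extrapolated limit meaningful for nearly flat curves, where an
    unbounded amplitude with a vanishing rate would otherwise fit just
    as well).  A deterministic multistart (fixed grid plus
    ``n_random_starts`` seeded perturbations) guards against local
    minima; the result is reported with the fast term first (b >= d).
    """
    mask = np.isfinite(curve.mean_r)
    n = curve.n_values[mask].astype(float)
    r = curve.mean_r[mask]
    if len(n) < 5:
        raise ValueError("need at least 5 valid points to fit")

    sigma = None
    if weighted:
        sd = curve.sd_r[mask].astype(float).copy()
        positive = sd[np.isfinite(sd) & (sd > 0)]
        floor = positive.min() if len(positive) else 1.0
        sd[~np.isfinite(sd) | (sd <= 0)] = floor
        sigma = sd

    amp = max(float(np.max(r)), 1e-6)
    starts = [
        (0.5 * amp, 0.1, 0.5 * amp, 0.01),
        (0.7 * amp, 0.2, 0.3 * amp, 0.02),
        (0.3 * amp, 0.05, 0.7 * amp, 0.005),
        (amp, 0.1, 1e-3, 0.01),
    ]
    rng = np.random.default_rng(seed)
    for _ in range(n_random_starts):
        starts.append(
            (
                amp * rng.uniform(0.2, 0.8),
                10 ** rng.uniform(-2, 0),
                amp * rng.uniform(0.1, 0.6),
                10 ** rng.uniform(-3, -1),
            )
        )

    best = None
    errors = []
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                double_exponential,
                n,
                r,
                p0=p0,
                sigma=sigma,
                bounds=([0.0, 0.0, 0.0, 0.0], [1.0, np.inf, 1.0, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            errors.append(f"{p0}: {exc}")
            continue
        resid = float(((double_exponential(n, *popt) - r) ** 2).sum())
        if best is None or resid < best[0]:
            best = (resid, popt, pcov)
    if best is None:
        raise FitError(
            "double-exponential fit failed from every start point:\n" + "\n".join(errors)
        )
    resid, (a, b, c, d), pcov = best
    if b < d:  # canonical order: fast term first
        a, b, c, d = c, d, a, b
    return DoubleExpFit(float(a), float(b), float(c), float(d), pcov, resid)
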