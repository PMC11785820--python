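"""Displacement-fluctuation motor counting via the phi = 2*mu/s^2 statistic.

For a cargo segment moving at roughly constant velocity, the displacements
Delta x(t, tau) = x(t + tau) - x(t) over a delay tau are near-Gaussian with
mean mu(tau) and variance s^2(tau).  For n motors stepping independently at
rate lam with per-step displacement mean d and variance v (cargo moves
step/n per motor step), compound-Poisson moments give

    mu(tau)  = lam * tau * d
    s^2(tau) = lam * tau * (d^2 + v) / n + 2 * sigma^2

so phi(tau) = 2 mu / s^2 relaxes toward the asymptote n * 2d / (d^2 + v):
an integer multiple of the single-motor quantum phi_1 = 2d/(d^2+v).
Pooled asymptotes therefore cluster at quantized values, and k-means
clustering plus a fitted quantum turns each segment's phi_infinity into a
motor count n.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.cluster import KMeans

from .segment import VelocitySegment

__all__ = [
    "DisplacementStats",
    "PhiCurve",
    "MotorCountResult",
    "displacement_stats",
    "phi_curve",
    "phi_asymptote",
    "cluster_quantized",
    "motor_count_summary",
    "default_tau_grid",
]

log = logging.getLogger(__name__)

MIN_PAIRS = 50  # displacement pairs required before an entry is reported


def default_tau_grid() -> np.ndarray:
    """10-ms steps from 10 to 200 ms (includes the 10/40/100 ms display delays)."""
    return np.round(np.arange(0.01, 0.2001, 0.01), 10)


@dataclass(frozen=True)
class DisplacementStats:
    """Gaussian summary of Delta x at one delay."""

    tau_s: float
    mu_nm: float
    s2_nm2: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.s2_nm2 <= 0:
            raise ValueError("displacement variance must be > 0")
        if self.n_pairs < MIN_PAIRS:
            raise ValueError(f"need >= {MIN_PAIRS} displacement pairs per entry")

    @property
    def phi_inv_nm(self) -> float:
        return 2.0 * self.mu_nm / self.s2_nm2


@dataclass
class PhiCurve:
    """phi(tau) relaxation curve for one segment."""

    segment_id: str
    tau_s: np.ndarray
    phi_inv_nm: np.ndarray
    stats: list[DisplacementStats]
    noise_sd_nm: float | None = None
    temperature_c: float | None = None
    phi_asymptote_inv_nm: float | None = None
    converged: bool = False

    def __post_init__(self) -> None:
        if np.any(np.diff(self.tau_s) <= 0):
            raise ValueError("tau grid must be strictly increasing")


@dataclass
class MotorCountResult:
    """Pooled quantization analysis of phi asymptotes."""

    values_inv_nm: np.ndarray
    centers_inv_nm: np.ndarray
    phi1_inv_nm: float
    motor_numbers: np.ndarray       # integer n per segment
    mean_n: float = field(init=False)
    se_n: float = field(init=False)

    def __post_init__(self) -> None:
        n = np.asarray(self.motor_numbers, dtype=int)
        if np.any(n < 1):
            raise ValueError("motor numbers must be >= 1 integers")
        self.mean_n = float(n.mean())
        self.se_n = float(n.std(ddof=1) / np.sqrt(len(n))) if len(n) > 1 else 0.0

    def histogram(self) -> dict[int, int]:
        vals, counts = np.unique(self.motor_numbers, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


# ---------------------------------------------------------------------------
# Per-delay displacement statistics
# ---------------------------------------------------------------------------

def _gaussian_hist_fit(dx: np.ndarray) -> tuple[float, float]:
    """Cross-check mode: fit a Gaussian to the binned displacement histogram."""
    counts, edges = np.histogram(dx, bins="auto", density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, mu, sd):
        return np.exp(-((x - mu) ** 2) / (2 * sd**2)) / (sd * np.sqrt(2 * np.pi))

    p, _ = curve_fit(gauss, centers, counts, p0=[dx.mean(), dx.std() + 1e-12])
    return float(p[0]), float(p[1]) ** 2


def displacement_stats(
    segment: "VelocitySegment | np.ndarray",
    tau_grid: np.ndarray | None = None,
    dt_s: float | None = None,
    method: str = "moments",
) -> list[DisplacementStats]:
    """Mean and variance of Delta x(tau) over all overlapping pairs.

    ``segment`` may be a :class:`VelocitySegment` or a raw 1-D position
    array (then ``dt_s`` is required).  Delays not on the frame grid are
    snapped to the nearest multiple of dt with a warning.  Sample moments
    are the Gaussian MLE; ``method="histogram"`` fits the binned histogram
    instead (comparison mode).
    """
    if isinstance(segment, VelocitySegment):
        pos, dt = segment.positions_nm, segment.dt_s
    else:
        if dt_s is None:
            raise ValueError("dt_s is required for raw position input")
        pos, dt = np.asarray(segment, dtype=float), float(dt_s)
    tau_grid = default_tau_grid() if tau_grid is None else np.asarray(tau_grid, float)
    out: list[DisplacementStats] = []
    for tau in tau_grid:
        lag = int(round(tau / dt))
        if abs(lag * dt - tau) > 1e-9:
            warnings.warn(
                f"tau={tau} s is not a multiple of dt={dt} s; snapped to {lag * dt} s",
                stacklevel=2,
            )
        if lag < 1 or lag >= len(pos):
            continue
        dx = pos[lag:] - pos[:-lag]
        if len(dx) < MIN_PAIRS:
            continue
        if method == "histogram":
            mu, s2 = _gaussian_hist_fit(dx)
        elif method == "moments":
            mu, s2 = float(dx.mean()), float(dx.var(ddof=1))
        else:
            raise ValueError(f"unknown method {method!r}")
        if s2 <= 0:
            continue
        out.append(DisplacementStats(tau_s=lag * dt, mu_nm=mu, s2_nm2=s2, n_pairs=len(dx)))
    return out


def phi_curve(
    stats: list[DisplacementStats],
    noise_sd_nm: float | None = None,
    segment_id: str = "segment",
    temperature_c: float | None = None,
) -> PhiCurve:
    """phi(tau) = 2 mu / (s^2 - 2 sigma^2) on the tau grid.

    When the localization noise SD sigma is known, its static contribution
    2 sigma^2 to the displacement variance is subtracted; entries whose
    corrected variance is nonpositive are dropped with a warning.
    """
    if not stats:
        raise ValueError("stats must be nonempty")
    taus, phis, kept = [], [], []
    n_dropped = 0
    for st in stats:
        s2 = st.s2_nm2 - (2.0 * noise_sd_nm**2 if noise_sd_nm else 0.0)
        if s2 <= 0:
            n_dropped += 1
            continue
        taus.append(st.tau_s)
        phis.append(2.0 * st.mu_nm / s2)
        kept.append(st)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} entries dropped: variance below the noise floor", stacklevel=2
        )
    return PhiCurve(
        segment_id=segment_id,
        tau_s=np.asarray(taus),
        phi_inv_nm=np.asarray(phis),
        stats=kept,
        noise_sd_nm=noise_sd_nm,
        temperature_c=temperature_c,
    )


def phi_asymptote(
    curve: PhiCurve,
    tau_min_s: float = 0.12,
    flatness_tol: float = 0.1,
) -> tuple[float | None, bool]:
    """Asymptote of phi(tau): tail mean over tau >= ``tau_min_s``.

    The tail is declared converged when the fitted linear trend changes phi
    by less than ``flatness_tol`` (relative) across the tail window; only
    converged curves carry an asymptote.  Updates ``curve`` in place and
    returns (phi_infinity or None, converged).
    """
    mask = curve.tau_s >= tau_min_s
    if mask.sum() < 3:
        curve.phi_asymptote_inv_nm, curve.converged = None, False
        return None, False
    tau, phi = curve.tau_s[mask], curve.phi_inv_nm[mask]
    mean_phi = float(phi.mean())
    slope = float(np.polyfit(tau, phi, 1)[0])
    rel_drift = abs(slope * (tau[-1] - tau[0]) / mean_phi) if mean_phi != 0 else np.inf
    converged = bool(rel_drift < flatness_tol)
    curve.converged = converged
    curve.phi_asymptote_inv_nm = mean_phi if converged else None
    return (mean_phi if converged else None), converged


def bootstrap_phi_se(
    segment: "VelocitySegment | np.ndarray",
    tau_grid: np.ndarray | None = None,
    dt_s: float | None = None,
    noise_sd_nm: float | None = None,
    block_s: float = 0.5,
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    """Block-bootstrap SE of the phi asymptote.

    Overlapping displacement pairs are serially correlated, so plain
    resampling understates the error; resampling contiguous time blocks of
    ``block_s`` preserves the short-range correlation structure.
    """
    if isinstance(segment, VelocitySegment):
        pos, dt = segment.positions_nm, segment.dt_s
    else:
        pos, dt = np.asarray(segment, float), float(dt_s)
    block = max(int(round(block_s / dt)), 2)
    n_blocks = len(pos) // block
    if n_blocks < 2:
        raise ValueError("segment too short for block bootstrap")
    dx_blocks = [np.diff(pos[i * block:(i + 1) * block + 1]) for i in range(n_blocks)]
    rng = np.random.default_rng(seed)
    est = []
    for _ in range(n_boot):
        idx = rng.integers(0, n_blocks, n_blocks)
        boot_pos = np.concatenate([[0.0], np.cumsum(np.concatenate([dx_blocks[i] for i in idx]))])
        stats = displacement_stats(boot_pos, tau_grid, dt_s=dt)
        if not stats:
            continue
        curve = phi_curve(stats, noise_sd_nm=noise_sd_nm)
        tail = curve.phi_inv_nm[curve.tau_s >= 0.12]
        if len(tail):
            est.append(tail.mean())
    return float(np.std(est, ddof=1))


# ---------------------------------------------------------------------------
# Quantized clustering and motor-number inference
# ---------------------------------------------------------------------------

def _fit_quantum(centers: np.ndarray, weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Regress cluster centers onto integer multiples {m * phi1}."""
    phi1 = float(centers.min())
    m = np.maximum(1, np.round(centers / phi1)).astype(int)
    for _ in range(20):
        phi1_new = float((weights * centers * m).sum() / (weights * m**2).sum())
        m_new = np.maximum(1, np.round(centers / phi1_new)).astype(int)
        if np.array_equal(m_new, m) and abs(phi1_new - phi1) < 1e-12:
            break
        phi1, m = phi1_new, m_new
    return phi1, m


def cluster_quantized(
    values: np.ndarray,
    k_range: range = range(1, 7),
    seed: int = 0,
    n_init: int = 50,
    min_rel_drop: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, float]:
    """k-means clustering of pooled phi asymptotes with quantum extraction.

    The cluster count is chosen by the elbow rule (largest relative drop in
    within-cluster sum of squares along k in ``k_range``; below
    ``min_rel_drop`` the data are treated as a single cluster).  Cluster
    centers are then regressed onto integer multiples of a quantum phi_1,
    and each value is assigned the integer n of its cluster.

    Returns ``(centers, assignments_n, phi1)``.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values to cluster")
    if np.ptp(values) < 1e-12:
        center = np.array([values.mean()])
        return center, np.ones(len(values), dtype=int), float(values.mean())
    ks = [k for k in k_range if k <= len(values) // 2]
    if len(values) < 2 * max(k_range):
        log.info("few values (%d): k range truncated at %d", len(values), max(ks))
    x = values.reshape(-1, 1)
    wcss: dict[int, float] = {}
    models: dict[int, KMeans] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
        wcss[k] = float(km.inertia_)
        models[k] = km
    # elbow: the largest k still preceded by a big relative WCSS drop;
    # splitting a true cluster only drops WCSS by ~(1 - 2/pi)/k, below the gate
    k_best = ks[0]
    for k_prev, k in zip(ks[:-1], ks[1:]):
        if wcss[k_prev] <= 0:
            break
        drop = (wcss[k_prev] - wcss[k]) / wcss[k_prev]
        if drop >= min_rel_drop:
            k_best = k
    km = models[k_best]
    order = np.argsort(km.cluster_centers_.ravel())
    centers = km.cluster_centers_.ravel()[order]
    sizes = np.array([(km.labels_ == lab).sum() for lab in order], dtype=float)
    phi1, multiples = _fit_quantum(centers, sizes)
    relabel = np.empty(k_best, dtype=int)
    relabel[order] = multiples
    assignments = relabel[km.labels_]
    return centers, assignments, phi1


def motor_count_summary(
    values_inv_nm: np.ndarray,
    seed: int = 0,
    k_range: range = range(1, 7),
) -> MotorCountResult:
    """Pooled motor-number summary of phi asymptotes: cluster, snap to the
    quantum, and report per-segment n with mean +/- SE (SD / sqrt(#segments))."""
    values_inv_nm = np.asarray(values_inv_nm, dtype=float)
    centers, assignments, phi1 = cluster_quantized(values_inv_nm, k_range=k_range, seed=seed)
    return MotorCountResult(
        values_inv_nm=values_inv_nm,
        centers_inv_nm=centers,
        phi1_inv_nm=phi1,
        motor_numbers=assignments,
    )


def phi_theory(tau: np.ndarray, step_mean_nm: float, step_variance_nm2: float,
               step_rate_s: float, n_motors: int = 1,
               noise_sd_nm: float = 0.0) -> np.ndarray:
    """Closed-form compound-Poisson relaxation curve
    phi(tau) = 2 lam tau d / (lam tau (d^2+v)/n + 2 sigma^2) (oracle/reference)."""
    tau = np.asarray(tau, dtype=float)
    num = 2.0 * step_rate_s * tau * step_mean_nm
    den = step_rate_s * tau * (step_mean_nm**2 + step_variance_nm2) / n_motors \
        + 2.0 * noise_sd_nm**2
    return num / den
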