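"""Motion-state annotation and constant-velocity segment extraction.

Cargo trajectories alternate between diffusive pauses and directed
(retrograde / anterograde) runs.  We model the projected per-frame
displacements as a Gaussian hidden Markov chain: a diffusive state has zero
mean and variance 2 D dt + 2 sigma^2, a transport state has mean v dt on
top.  The number of states K in {1, 2, 3} is chosen by BIC over EM fits
with multiple restarts, and frames are labeled by the Viterbi path.  This
is a deliberately simplified stand-in for full Bayesian model-evidence
selection: BIC is the large-sample limit of the evidence and behaves the
same way on the long trajectories this analysis needs.

Runs of a single directed state become :class:`VelocitySegment` objects for
the downstream displacement-fluctuation analysis, after trimming boundary
frames and gating on velocity stationarity (coefficient of variation of
block velocities).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .trajsim import Trajectory

__all__ = [
    "MotionAnnotation",
    "VelocitySegment",
    "annotate_motion",
    "extract_segments",
    "project_to_axis",
]

log = logging.getLogger(__name__)

#: Label constants: diffusive, directed positive (retrograde), directed negative.
LABEL_D, LABEL_DV_POS, LABEL_DV_NEG = "D", "DV+", "DV-"


@dataclass
class MotionAnnotation:
    """Per-frame motion-state labels and the selected HMM."""

    labels: np.ndarray            # str per frame: D / DV+ / DV-
    state_path: np.ndarray        # int state index per frame
    state_means_nm: np.ndarray    # per-state mean displacement per frame
    state_sds_nm: np.ndarray      # per-state displacement SD per frame
    n_states: int
    bic_per_k: dict[int, float]
    dt_s: float
    positions_nm: np.ndarray      # projected 1-D positions used for the fit
    trajectory: Trajectory | None = None
    converged: bool = True

    @property
    def state_velocities_nm_s(self) -> np.ndarray:
        return self.state_means_nm / self.dt_s


@dataclass
class VelocitySegment:
    """A contiguous run of one directed state, projected to 1-D."""

    traj_id: str
    start_frame: int
    end_frame: int               # inclusive
    positions_nm: np.ndarray     # retrograde-positive 1-D positions
    dt_s: float
    mean_velocity_nm_s: float = field(init=False)

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("segment frame range must be monotone")
        span = (len(self.positions_nm) - 1) * self.dt_s
        self.mean_velocity_nm_s = (
            (self.positions_nm[-1] - self.positions_nm[0]) / span if span > 0 else 0.0
        )

    @property
    def duration_s(self) -> float:
        return (len(self.positions_nm) - 1) * self.dt_s

    def __len__(self) -> int:
        return len(self.positions_nm)


def project_to_axis(traj: Trajectory, window: tuple[int, int] | None = None) -> np.ndarray:
    """Project (x, y) onto the first principal axis of the (windowed) track.

    The sign is chosen so the mean displacement is nonnegative
    (retrograde-positive convention).  A window spanning two parallel
    microtubule tracks projects both onto the common transport axis,
    removing the lateral offset.
    """
    lo, hi = window if window is not None else (0, len(traj))
    xy = np.column_stack([traj.x_nm[lo:hi], traj.y_nm[lo:hi]])
    if len(xy) < 2:
        raise ValueError("need at least 2 frames to define an axis")
    centered = xy - xy.mean(axis=0)
    cov = centered.T @ centered
    if np.allclose(cov, 0.0):
        raise ValueError("zero-variance window: no principal axis")
    _w, v = np.linalg.eigh(cov)
    axis = v[:, -1]
    proj = centered @ axis
    if proj[-1] - proj[0] < 0:
        proj = -proj
    return proj


def _fit_k(dx: np.ndarray, k: int, restarts: int, seed: int) -> tuple[GaussianHMM, float]:
    """Best-of-``restarts`` EM fit with velocity-quantile mean seeding."""
    x = dx.reshape(-1, 1)
    best, best_ll = None, -np.inf
    ss = np.random.SeedSequence(seed)
    for sub in ss.spawn(restarts):
        rs = int(sub.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(rs)
        hmm = GaussianHMM(
            n_components=k,
            covariance_type="diag",
            n_iter=200,
            tol=1e-4,
            random_state=rs,
            init_params="stc",  # means seeded by displacement quantiles
        )
        q = np.linspace(0.1, 0.9, k) + rng.uniform(-0.05, 0.05, k)
        hmm.means_ = np.quantile(x, np.clip(q, 0.0, 1.0)).reshape(-1, 1)
        try:
            hmm.fit(x)
            ll = float(hmm.score(x))
        except Exception:
            continue
        if ll > best_ll:
            best, best_ll = hmm, ll
    if best is None:
        raise RuntimeError("all EM restarts failed")
    return best, best_ll


def annotate_motion(
    traj: Trajectory,
    max_states: int = 3,
    restarts: int = 10,
    seed: int = 0,
    diffusive_gate: float = 0.5,
) -> MotionAnnotation:
    """Label every frame diffusive (D) or directed (DV+/DV-).

    Fits Gaussian-emission HMMs on the projected per-frame displacements
    for K = 1..``max_states`` (EM, ``restarts`` restarts each, distinct
    sub-seeds), selects K by minimum BIC, and labels frames by the Viterbi
    path.  A state is classified D when the magnitude of its mean
    displacement is below ``diffusive_gate`` of its emission SD; otherwise
    DV+/DV- by the sign of its velocity.  Frame 0 inherits the label of the
    first displacement.
    """
    if len(traj) < 100:
        raise ValueError("need >= 100 frames for motion annotation")
    pos = project_to_axis(traj)
    dx = np.diff(pos)
    n = len(dx)
    converged = True
    fits: dict[int, tuple[GaussianHMM, float]] = {}
    bic: dict[int, float] = {}
    for k in range(1, max_states + 1):
        try:
            hmm, ll = _fit_k(dx, k, restarts, seed + k)
        except RuntimeError:
            converged = False
            continue
        if not hmm.monitor_.converged:
            converged = False
        n_params = (k - 1) + k * (k - 1) + 2 * k  # startprob + transmat + means + vars
        bic[k] = n_params * np.log(n) - 2.0 * ll
        fits[k] = (hmm, ll)
    if not fits:
        raise RuntimeError("motion annotation failed for every state count")
    if not converged:
        warnings.warn("EM did not fully converge; returning best attempt", stacklevel=2)
    k_best = min(bic, key=bic.get)
    hmm, _ = fits[k_best]
    _, path = hmm.decode(dx.reshape(-1, 1), algorithm="viterbi")
    means = hmm.means_.ravel()
    sds = np.sqrt(hmm.covars_.ravel())

    state_labels = np.empty(k_best, dtype=object)
    for s in range(k_best):
        if abs(means[s]) < diffusive_gate * sds[s]:
            state_labels[s] = LABEL_D
        else:
            state_labels[s] = LABEL_DV_POS if means[s] > 0 else LABEL_DV_NEG
    frame_path = np.concatenate([[path[0]], path])  # frame 0 <- first displacement
    labels = state_labels[frame_path]
    return MotionAnnotation(
        labels=labels,
        state_path=frame_path,
        state_means_nm=means,
        state_sds_nm=sds,
        n_states=k_best,
        bic_per_k=bic,
        dt_s=traj.dt_s,
        positions_nm=pos,
        trajectory=traj,
        converged=converged,
    )


def _velocity_cv(pos: np.ndarray, dt: float, block_s: float = 0.5) -> float:
    """Coefficient of variation of block velocities (stationarity gate)."""
    block = max(int(round(block_s / dt)), 2)
    n_blocks = len(pos) // block
    if n_blocks < 2:
        return 0.0
    v = np.array([
        (pos[(i + 1) * block - 1] - pos[i * block]) / ((block - 1) * dt)
        for i in range(n_blocks)
    ])
    mean = v.mean()
    if mean == 0:
        return np.inf
    return float(np.std(v, ddof=1) / abs(mean))


def extract_segments(
    annotation: MotionAnnotation,
    min_duration_s: float = 1.0,
    max_velocity_cv: float = 0.3,
    trim_frames: int = 2,
    traj_id: str = "traj",
) -> list[VelocitySegment]:
    """Contiguous single-DV-state runs as retrograde-positive 1-D segments.

    Boundary frames are trimmed (state assignment is least reliable at
    switches), runs shorter than ``min_duration_s`` or failing the velocity
    coefficient-of-variation gate are discarded.  Runs are delimited by the
    directed *label* (DV+ or DV-), not the raw state index: on strongly
    non-Gaussian stepping noise BIC may split one transport direction into
    two emission components, and the CV gate already rejects runs whose
    velocity actually changes.
    """
    labels = annotation.labels
    dt = annotation.dt_s
    pos = annotation.positions_nm
    segments: list[VelocitySegment] = []
    n_gated = 0
    i = 0
    while i < len(labels):
        if labels[i] == LABEL_D:
            i += 1
            continue
        j = i
        while j + 1 < len(labels) and labels[j + 1] == labels[i]:
            j += 1
        lo, hi = i + trim_frames, j - trim_frames  # inclusive frame range
        i = j + 1
        if hi <= lo:
            continue
        if (hi - lo) * dt < min_duration_s:
            continue
        seg_pos = pos[lo:hi + 1].copy()
        if labels[j] == LABEL_DV_NEG:
            seg_pos = -seg_pos  # retrograde-positive sign convention
        seg_pos -= seg_pos[0]
        if _velocity_cv(seg_pos, dt) > max_velocity_cv:
            n_gated += 1
            continue
        segments.append(
            VelocitySegment(
                traj_id=traj_id,
                start_frame=lo,
                end_frame=hi,
                positions_nm=seg_pos,
                dt_s=dt,
            )
        )
    if n_gated:
        log.info("%d segments discarded by the velocity-CV gate", n_gated)
    return segments
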