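"""Synthetic daily-diary generator with known time-varying VAR(1) ground truth.

Emulates the regime of single-patient depression diaries: around 6 continuous
variables observed daily for 150-540 days, lag-1 dependence whose coefficients
stay constant, drift linearly, change smoothly (sigmoid) or jump (step), a few
percent item-wise missingness including multi-day gaps, and bounded
visual-analog-type scales with possible floor/ceiling pileup. Because the
ground-truth coefficient trajectories are retained, recovery, coverage and
test-calibration studies can score estimators exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import DiaryDataset

__all__ = [
    "EdgeTrajectory",
    "TrajectorySpec",
    "SyntheticDataset",
    "build_trajectories",
    "generate_tvvar_series",
    "inject_missingness",
    "to_bounded_scale",
    "scenario_bank",
]

_TAGS = ("constant", "linear_ramp", "step", "sigmoid")


@dataclass
class EdgeTrajectory:
    """One coefficient's path over normalized time [0, 1].

    tag:
      constant     — ``start`` throughout
      linear_ramp  — linear from ``start`` to ``end``
      step         — ``start`` before ``loc``, ``end`` at and after
      sigmoid      — logistic transition from ``start`` to ``end`` centred at
                     ``loc`` with slope ``steepness``
    """

    tag: str
    start: float
    end: float = 0.0
    loc: float = 0.5
    steepness: float = 20.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        if self.tag == "constant":
            return np.full_like(t, self.start)
        if self.tag == "linear_ramp":
            return self.start + (self.end - self.start) * t
        if self.tag == "step":
            return np.where(t < self.loc, self.start, self.end)
        if self.tag == "sigmoid":
            s = 1.0 / (1.0 + np.exp(-self.steepness * (t - self.loc)))
            return self.start + (self.end - self.start) * s
        raise ValueError(f"unknown trajectory tag {self.tag!r}; valid: {_TAGS}")


@dataclass
class TrajectorySpec:
    """Ground-truth generative model: per-entry trajectories, intercepts, noise."""

    p: int
    edges: dict[tuple[int, int], EdgeTrajectory] = field(default_factory=dict)
    intercepts: dict[int, EdgeTrajectory] = field(default_factory=dict)
    innovation_sd: np.ndarray | float = 1.0

    def sd_vector(self) -> np.ndarray:
        sd = np.broadcast_to(np.asarray(self.innovation_sd, float), (self.p,))
        if np.any(sd < 0):
            raise ValueError("innovation SDs must be nonnegative")
        return np.array(sd)


@dataclass
class SyntheticDataset:
    """A diary dataset plus its generative ground truth."""

    ds: DiaryDataset
    truth_B: np.ndarray  # (T, p, p)
    truth_intercepts: np.ndarray  # (T, p)
    innovation_sd: np.ndarray
    injected_mask: np.ndarray | None = None  # True where an entry was deleted


def build_trajectories(spec: TrajectorySpec, T: int) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the tagged trajectories on the daily grid; enforce stability.

    Returns (B_t of shape (T, p, p), intercepts of shape (T, p)). Raises if
    the instantaneous coefficient matrix has spectral radius >= 1 at any day.
    """
    t = np.arange(T) / max(T - 1, 1)
    B = np.zeros((T, spec.p, spec.p))
    for (i, j), traj in spec.edges.items():
        B[:, i, j] = traj(t)
    c = np.zeros((T, spec.p))
    for i, traj in spec.intercepts.items():
        c[:, i] = traj(t)
    rho = np.array([np.max(np.abs(np.linalg.eigvals(B[s]))) for s in range(T)])
    if np.any(rho >= 1.0):
        day = int(np.argmax(rho >= 1.0))
        raise ValueError(
            f"unstable coefficient matrix at day {day + 1} (spectral radius {rho[day]:.3f})"
        )
    return B, c


def generate_tvvar_series(
    spec: TrajectorySpec, T: int, seed: int = 0, participant_id: str = "synthetic"
) -> SyntheticDataset:
    """Simulate x_t = c(t) + B(t) x_{t-1} + eps_t on a daily calendar grid.

    Gaussian diagonal innovations; a 100-step burn-in under the day-1
    parameters is discarded; the returned mask is complete.
    """
    B, c = build_trajectories(spec, T)
    sd = spec.sd_vector()
    rng = np.random.default_rng(seed)
    burn = 100
    x = np.zeros(spec.p)
    out = np.empty((T, spec.p))
    for t in range(-burn, T):
        idx = max(t, 0)
        x = c[idx] + B[idx] @ x + rng.standard_normal(spec.p) * sd
        if t >= 0:
            out[t] = x
    dates = pd.date_range("2020-01-01", periods=T, freq="D")
    ds = DiaryDataset(
        participant_id,
        dates,
        out,
        np.ones((T, spec.p), dtype=bool),
        [f"V{j + 1}" for j in range(spec.p)],
    )
    return SyntheticDataset(ds, B, c, sd)


def inject_missingness(
    sds: SyntheticDataset,
    frac: float = 0.055,
    max_block: int = 7,
    seed: int = 0,
    block_share: float = 0.5,
    block_lengths: tuple[int, ...] | None = None,
) -> SyntheticDataset:
    """Delete ~``frac`` of entries as a mixture of isolated holes and gaps.

    Roughly ``block_share`` of the deleted entries come in per-variable blocks
    of consecutive days (lengths drawn from ``block_lengths``, default
    2..max_block), the rest are isolated missing-completely-at-random holes.
    The deleted values are retained in the ground truth.
    """
    if not 0 <= frac < 0.3:
        raise ValueError("frac must be in [0, 0.3)")
    if block_lengths is None:
        block_lengths = tuple(range(2, max_block + 1))
    if any(L > max_block for L in block_lengths):
        raise ValueError(f"block length exceeds max_block={max_block}")
    ds = sds.ds
    T, p = ds.T, ds.p
    target = int(round(frac * T * p))
    rng = np.random.default_rng(seed)
    mask = ds.mask.copy()
    deleted = np.zeros_like(mask)
    n_deleted = 0
    if target > 0 and block_lengths:
        attempts = 0
        while n_deleted < block_share * target and attempts < 50 * target:
            attempts += 1
            L = int(rng.choice(block_lengths))
            if n_deleted + L > target:
                L = target - n_deleted
                if L < 1:
                    break
            j = int(rng.integers(p))
            start = int(rng.integers(0, T - L + 1))
            if not mask[start : start + L, j].all():
                continue
            mask[start : start + L, j] = False
            deleted[start : start + L, j] = True
            n_deleted += L
    while n_deleted < target:
        t = int(rng.integers(T))
        j = int(rng.integers(p))
        if mask[t, j]:
            mask[t, j] = False
            deleted[t, j] = True
            n_deleted += 1
    new_ds = replace(ds, values=ds.values.copy(), mask=mask)
    return SyntheticDataset(
        new_ds, sds.truth_B, sds.truth_intercepts, sds.innovation_sd, deleted
    )


def to_bounded_scale(
    sds: SyntheticDataset,
    bounds: tuple[float, float] = (0.0, 100.0),
    squash: str = "logistic",
    shift: float = 0.0,
    scale: float = 1.0,
) -> SyntheticDataset:
    """Map the latent series monotonically into a bounded visual-analog scale.

    squash:
      identity — values pass through unchanged (must already lie in bounds)
      logistic — lo + (hi-lo) * expit(scale * x + shift); strictly monotone
      clip     — hard clipping of scale * x + shift to the bounds; a large
                 ``shift`` manufactures floor/ceiling pileup on purpose

    Day-wise rank order is preserved (weakly, for "clip").
    """
    lo, hi = bounds
    if hi <= lo:
        raise ValueError("invalid bounds")
    x = sds.ds.values * scale + shift
    if squash == "identity":
        y = sds.ds.values
        obs = y[sds.ds.mask]
        if obs.size and (obs.min() < lo or obs.max() > hi):
            raise ValueError("identity squash requires data already within bounds")
    elif squash == "logistic":
        y = lo + (hi - lo) / (1.0 + np.exp(-x))
    elif squash == "clip":
        y = np.clip(x, lo, hi)
    else:
        raise ValueError(f"unknown squash tag {squash!r}")
    new_ds = replace(sds.ds, values=y, mask=sds.ds.mask.copy(), standardized=False)
    return SyntheticDataset(
        new_ds, sds.truth_B, sds.truth_intercepts, sds.innovation_sd, sds.injected_mask
    )


def scenario_bank() -> dict[str, dict]:
    """Named scenarios mirroring the study regime (p=6; T and missingness from
    the reported ranges; constant, drifting and abruptly changing dynamics)."""
    ar = {(i, i): EdgeTrajectory("constant", 0.3) for i in range(6)}
    return {
        "stationary_T300": {
            "spec": TrajectorySpec(6, {**ar, (0, 1): EdgeTrajectory("constant", 0.4)}),
            "T": 300,
            "missing_frac": 0.055,
        },
        "ramp_T300": {
            "spec": TrajectorySpec(
                6, {**ar, (0, 1): EdgeTrajectory("linear_ramp", 0.0, 0.4)}
            ),
            "T": 300,
            "missing_frac": 0.055,
        },
        "step_T204": {
            "spec": TrajectorySpec(
                6, {**ar, (0, 1): EdgeTrajectory("step", 0.5, -0.5, loc=0.5)}
            ),
            "T": 204,
            "missing_frac": 0.014,
        },
        "sigmoid_T539": {
            "spec": TrajectorySpec(
                6, {**ar, (1, 0): EdgeTrajectory("sigmoid", 0.4, -0.2, loc=0.5)}
            ),
            "T": 539,
            "missing_frac": 0.055,
        },
        "short_T154": {
            "spec": TrajectorySpec(6, ar),
            "T": 154,
            "missing_frac": 0.196,
        },
    }
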