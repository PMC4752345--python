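"""Stochastic nuclear trajectories for interkinetic nuclear migration.

A trajectory is one out-and-back episode of the nuclear centroid along the
dimensionless cell axis: persistent basalward drift from the apical resting
position, a pause at a sampled turning position, and persistent apicalward
return, ending on first return to the apical resting position (where mitosis
would occur).  The position follows the Euler-Maruyama discretization of

    d(xi_n) = v_nd dt + sqrt(2 D_n,nd dt) dW

with the drift set per phase (+v_basal, 0, -v_apical in dimensionless form)
and the Wiener term active in *all* phases — only the drift is zeroed during
the pause, since the positional diffusivity was fitted to observed
fluctuations.  Turning is detected by first passage of the centroid across
the sampled turning position; the pause lasts exactly its sampled duration.
Positions are confined to the admissible centroid range (nucleus fully
inside the cell) by a reflecting clamp; clamping events are counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .params import H_TO_S, CellGeometry, DimensionlessGroups
from .distributions import PauseDistribution, TurningDistribution, sample_pause, sample_turning

__all__ = [
    "Phase",
    "PhaseRules",
    "NuclearTrajectory",
    "simulate_trajectory",
    "resample_trajectory",
]

_BLOCK = 8192
_MAX_STEPS = 5_000_000


class Phase(IntEnum):
    BASALWARD = 0
    PAUSED = 1
    APICALWARD = 2


@dataclass(frozen=True)
class PhaseRules:
    """Samplers for the stochastic phase structure plus the native step."""

    turning: TurningDistribution
    pause: PauseDistribution  # hours
    dt: float = 1e-3  # dimensionless; ~0.9 s for the default geometry
    max_resample: int = 10_000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class NuclearTrajectory:
    """Uniformly sampled centroid time series with per-sample phase labels.

    ``times`` and ``pause_duration`` are dimensionless (units of t_d);
    ``turning_position`` is the sampled pause location as a fraction of cell
    length; ``n_clamped`` counts boundary-clamp events (diagnostic).
    """

    times: np.ndarray
    xi: np.ndarray
    phase: np.ndarray
    turning_position: float
    pause_duration: float
    seed: int
    dt: float
    n_clamped: int = 0

    def __post_init__(self) -> None:
        if len(self.times) != len(self.xi) or len(self.xi) != len(self.phase):
            raise ValueError("times, xi and phase must have equal length")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def phase_duration(self, phase: Phase) -> float:
        return float(np.count_nonzero(self.phase == phase) * self.dt)


def _em_leg(
    xi0: float,
    drift: float,
    sigma: float,
    dt: float,
    rng: np.random.Generator,
    lo: float,
    hi: float,
    stop,
    max_steps: int,
):
    """One trajectory leg: Euler-Maruyama steps until ``stop(xi)`` is True.

    Steps are drawn in blocks; the common case (no boundary contact) uses a
    vectorized cumulative sum, falling back to a stepwise reflecting clamp —
    reusing the identical noise — only when the block leaves [lo, hi].
    """
    out = []
    xi = xi0
    n_clamped = 0
    taken = 0
    step_drift = drift * dt
    while True:
        noise = sigma * rng.standard_normal(_BLOCK)
        path = xi + np.cumsum(step_drift + noise)
        if path.min() < lo or path.max() > hi:
            # rare: replay the same increments with reflection at the walls
            path = np.empty(_BLOCK)
            x = xi
            for j in range(_BLOCK):
                x = x + step_drift + noise[j]
                if x < lo:
                    x = min(2.0 * lo - x, hi)
                    n_clamped += 1
                elif x > hi:
                    x = max(2.0 * hi - x, lo)
                    n_clamped += 1
                path[j] = x
        hit = stop(path)
        if hit is not None:
            out.append(path[: hit + 1])
            break
        out.append(path)
        xi = float(path[-1])
        taken += _BLOCK
        if taken > max_steps:
            raise RuntimeError("trajectory leg exceeded the step budget")
    leg = np.concatenate(out) if out else np.empty(0)
    if not np.all(np.isfinite(leg)):
        raise RuntimeError("non-finite position in trajectory simulation")
    return leg, n_clamped


def simulate_trajectory(
    geometry: CellGeometry,
    groups: DimensionlessGroups,
    rules: PhaseRules,
    seed: int,
    turning_position: float | None = None,
    pause_hours: float | None = None,
) -> NuclearTrajectory:
    """Simulate one seeded out-and-back nuclear trajectory.

    Turning position and pause duration are sampled from ``rules`` unless
    given explicitly (ensemble replay).  Sampled turning positions outside
    the admissible centroid range are rejected and resampled, up to
    ``rules.max_resample`` attempts.
    """
    xi_min, xi_max = geometry.xi_min, geometry.xi_max
    rng = np.random.default_rng(seed)

    if turning_position is None:
        turning_position = float(sample_turning(rules.turning, rng))
        tries = 0
        while not xi_min <= turning_position <= xi_max:
            turning_position = float(sample_turning(rules.turning, rng))
            tries += 1
            if tries > rules.max_resample:
                raise RuntimeError(
                    f"turning sampler produced no admissible position in "
                    f"[{xi_min:.3f}, {xi_max:.3f}] after {rules.max_resample} tries"
                )
    elif not xi_min <= turning_position <= xi_max:
        raise ValueError(
            f"turning position {turning_position:.4f} outside admissible "
            f"range [{xi_min:.3f}, {xi_max:.3f}]"
        )
    if pause_hours is None:
        pause_hours = float(sample_pause(rules.pause, rng))
    if pause_hours < 0:
        raise ValueError("pause duration must be non-negative")
    pause_nd = pause_hours * H_TO_S / groups.t_d

    dt = rules.dt
    sigma = np.sqrt(2.0 * groups.dn_nd * dt)
    n_clamped = 0

    # basalward: first passage across the turning position
    def hit_turn(path):
        idx = np.nonzero(path >= turning_position)[0]
        return int(idx[0]) if idx.size else None

    # no upper clamp here: any excursion past xi_max would have crossed the
    # turning position first and terminated the leg
    if turning_position > xi_min:
        leg_b, c = _em_leg(xi_min, groups.v_basal_nd, sigma, dt, rng,
                           xi_min, np.inf, hit_turn, _MAX_STEPS)
        n_clamped += c
    else:
        leg_b = np.empty(0)

    # pause: drift zeroed, fluctuations retained, fixed sampled duration
    n_pause = int(round(pause_nd / dt))
    xi_at_turn = float(leg_b[-1]) if leg_b.size else xi_min
    if n_pause > 0:
        def never(path):
            return None

        leg_p = np.empty(0)
        remaining = n_pause
        x = xi_at_turn
        parts = []
        while remaining > 0:
            take = min(remaining, _BLOCK)
            noise = sigma * rng.standard_normal(take)
            path = x + np.cumsum(noise)
            if path.min() < xi_min or path.max() > xi_max:
                pathr = np.empty(take)
                xx = x
                for j in range(take):
                    xx = xx + noise[j]
                    if xx < xi_min:
                        xx = min(2.0 * xi_min - xx, xi_max)
                        n_clamped += 1
                    elif xx > xi_max:
                        xx = max(2.0 * xi_max - xx, xi_min)
                        n_clamped += 1
                    pathr[j] = xx
                path = pathr
            parts.append(path)
            x = float(path[-1])
            remaining -= take
        leg_p = np.concatenate(parts)
    else:
        leg_p = np.empty(0)

    # apicalward: first return to the apical resting position
    def hit_apex(path):
        idx = np.nonzero(path <= xi_min)[0]
        return int(idx[0]) if idx.size else None

    # no lower clamp here: crossing xi_min terminates the leg
    x_start = float(leg_p[-1]) if leg_p.size else xi_at_turn
    if x_start > xi_min:
        leg_a, c = _em_leg(x_start, -groups.v_apical_nd, sigma, dt, rng,
                           -np.inf, xi_max, hit_apex, _MAX_STEPS)
        n_clamped += c
    else:
        leg_a = np.empty(0)

    xi = np.concatenate([[xi_min], leg_b, leg_p, leg_a])
    # first-passage / first-return samples may overshoot the admissible range
    # by one Euler step; project them back (part of the reflecting clamp)
    outside = (xi < xi_min) | (xi > xi_max)
    # the terminal first-return sample is a termination artifact, not a
    # boundary collision; project it back without counting it as a clamp
    n_clamped += int(np.count_nonzero(outside[:-1]))
    np.clip(xi, xi_min, xi_max, out=xi)
    phase = np.concatenate([
        np.zeros(1 + len(leg_b), dtype=np.int8),
        np.full(len(leg_p), Phase.PAUSED, dtype=np.int8),
        np.full(len(leg_a), Phase.APICALWARD, dtype=np.int8),
    ])
    times = np.arange(len(xi)) * dt
    return NuclearTrajectory(
        times=times,
        xi=xi,
        phase=phase,
        turning_position=float(turning_position),
        pause_duration=float(n_pause * dt),
        seed=int(seed),
        dt=dt,
        n_clamped=int(n_clamped),
    )


def resample_trajectory(traj: NuclearTrajectory, dt_out: float) -> NuclearTrajectory:
    """Coarsen a trajectory to step ``dt_out`` by linear interpolation of the
    position; phase labels are carried by the nearest predecessor.

    Refuses ``dt_out`` below the native step: upsampling would fabricate
    fluctuations that were never simulated.
    """
    if dt_out < traj.dt * (1.0 - 1e-12):
        raise ValueError(
            f"dt_out={dt_out:g} is finer than the native step {traj.dt:g}; "
            "refusing to fabricate unobserved fluctuations"
        )
    if abs(dt_out - traj.dt) <= 1e-12 * traj.dt:
        return traj
    t_end = traj.times[-1]
    # keep uniform sampling: round the horizon up and hold the final value
    n_out = int(np.ceil(t_end / dt_out - 1e-9))
    times = np.arange(n_out + 1) * dt_out
    xi = np.interp(times, traj.times, traj.xi)
    idx = np.searchsorted(traj.times, times + 1e-15, side="right") - 1
    phase = traj.phase[np.clip(idx, 0, len(traj.phase) - 1)]
    return NuclearTrajectory(
        times=times,
        xi=xi,
        phase=phase,
        turning_position=traj.turning_position,
        pause_duration=traj.pause_duration,
        seed=traj.seed,
        dt=dt_out,
        n_clamped=traj.n_clamped,
    )
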