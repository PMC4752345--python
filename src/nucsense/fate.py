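"""Depletion-time statistics and trajectory-dependent differentiation
probabilities.

The biological hypothesis: nuclear Notch (NICD) represses differentiation,
so the probability that a progenitor divides neurogenically grows with the
total time its nucleus spends with NICD below a threshold during one
apex-base-apex migration episode.  The "depletion time" tau of a trajectory
is the total time the nuclear concentration theta_n sits below a threshold
(a fraction f of the maximum cytoplasmic concentration), accrued over all
phases of the trajectory.  Trajectories are binned by their basal turning
position; the per-bin mean depletion times <tau>_i, normalized by the
largest bin mean, give the differentiation probability per bin:

    p_i = <tau>_i / max_j <tau>_j

so the bin whose nuclei translate farthest (largest mean depletion time)
gets probability one by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .params import CellGeometry, DimensionlessGroups, MotionParameters, TransportParameters, derive_dimensionless
from .distributions import EnsembleManifest, make_fixture_ensemble
from .solver import (
    ConcentrationState,
    ExchangeGeometry,
    Grid1D,
    steady_state_with_nucleus,
    transient_solve,
)
from .trajectories import PhaseRules, simulate_trajectory

__all__ = [
    "DepletionRecord",
    "ThresholdSpec",
    "BinnedFateResult",
    "depletion_time",
    "resolve_threshold",
    "bin_probabilities",
    "simulate_fate_ensemble",
    "run_scenario_sweep",
    "default_bin_edges",
]

logger = logging.getLogger(__name__)

THRESHOLD_REFERENCES = ("max_cytoplasmic", "max_nuclear_apical")


@dataclass(frozen=True)
class DepletionRecord:
    """Per-trajectory outcome: depletion time tau and its covariates
    (dimensionless times)."""

    trajectory_id: int
    turning_position: float
    tau: float
    total_time: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= self.total_time + 1e-9:
            raise ValueError("depletion time must lie in [0, total_time]")


@dataclass(frozen=True)
class ThresholdSpec:
    """Threshold as a fraction ``f`` of a reference concentration.

    ``reference``: ``max_cytoplasmic`` (default; maximum of the steady
    cytoplasmic profile) or ``max_nuclear_apical`` (steady nuclear level at
    the apical starting position — offered because nuclear levels exceed
    cytoplasmic ones by alpha_i/alpha_e, so a cytoplasmic-referenced
    threshold can sit far below the nuclear operating range for some phi).
    """

    fraction: float = 0.6
    reference: str = "max_cytoplasmic"

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("threshold fraction must lie in (0, 1)")
        if self.reference not in THRESHOLD_REFERENCES:
            raise ValueError(f"unknown threshold reference {self.reference!r}")


@dataclass(frozen=True)
class BinnedFateResult:
    """Binned mean depletion times and normalized probabilities.

    Empty bins are reported as missing (NaN mean_tau/p, n=0), never imputed.
    ``degenerate`` flags the all-zero-tau outcome (e.g. small phi: NICD never
    falls below threshold), where the probability curve is undefined.
    """

    bin_edges: np.ndarray
    mean_tau: np.ndarray
    p: np.ndarray
    n_per_bin: np.ndarray
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "mean_tau": self.mean_tau,
                "p": self.p,
                "n": self.n_per_bin,
            }
        )


def default_bin_edges() -> np.ndarray:
    """Turning-position bins: 10%-of-cell-length bins from 30% to 100%."""
    return np.round(np.arange(0.3, 1.0001, 0.1), 10)


def depletion_time(theta_n: np.ndarray, threshold: float, dt: float) -> float:
    """Total time a uniformly sampled series spends below ``threshold``.

    Piecewise-linear reconstruction between samples: an interval with both
    endpoints below the threshold contributes dt, a crossing interval
    contributes the linearly interpolated sub-step fraction.
    """
    y = np.asarray(theta_n, dtype=float)
    if y.size == 0:
        raise ValueError("empty concentration series")
    if not threshold > 0.0:
        raise ValueError("threshold must be positive")
    if y.size == 1:
        return 0.0
    y0, y1 = y[:-1], y[1:]
    below0, below1 = y0 < threshold, y1 < threshold
    frac = np.zeros(y0.shape)
    frac[below0 & below1] = 1.0
    cross = below0 != below1
    if np.any(cross):
        s = (threshold - y0[cross]) / (y1[cross] - y0[cross])
        # entering from below: below for s*dt; entering from above: (1-s)*dt
        frac[cross] = np.where(below0[cross], s, 1.0 - s)
    return float(frac.sum() * dt)


def resolve_threshold(spec: ThresholdSpec, reference_state: ConcentrationState) -> float:
    """Threshold value = fraction x reference maximum, from the phi-matched
    steady state at the trajectory starting position."""
    if spec.reference == "max_cytoplasmic":
        ref = float(np.max(reference_state.theta_c))
    else:
        ref = float(reference_state.theta_n)
    if ref <= 0.0:
        raise ValueError("reference concentration maximum is zero")
    return spec.fraction * ref


def bin_probabilities(
    records: Sequence[DepletionRecord], bin_edges: np.ndarray
) -> BinnedFateResult:
    """Average tau per turning-position bin and normalize to the largest bin
    mean.  The final bin is closed on the right."""
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2:
        raise ValueError("need at least one bin")
    if not records:
        raise ValueError("no depletion records")
    pos = np.array([r.turning_position for r in records])
    tau = np.array([r.tau for r in records])
    idx = np.digitize(pos, edges) - 1
    idx[np.isclose(pos, edges[-1])] = len(edges) - 2

    n_bins = len(edges) - 1
    mean_tau = np.full(n_bins, np.nan)
    n_per_bin = np.zeros(n_bins, dtype=int)
    for i in range(n_bins):
        mask = idx == i
        n_per_bin[i] = mask.sum()
        if n_per_bin[i]:
            mean_tau[i] = tau[mask].mean()
    if not np.any(n_per_bin):
        raise ValueError("all turning-position bins are empty")
    max_tau = np.nanmax(mean_tau)
    if max_tau > 0.0:
        p = mean_tau / max_tau
        degenerate = False
    else:
        p = np.full(n_bins, np.nan)
        degenerate = True
        logger.warning("all mean depletion times are zero; probability undefined")
    empty = np.nonzero(n_per_bin == 0)[0]
    if empty.size:
        logger.warning("empty turning-position bins: %s", empty.tolist())
    return BinnedFateResult(
        bin_edges=edges, mean_tau=mean_tau, p=p, n_per_bin=n_per_bin, degenerate=degenerate
    )


def simulate_fate_ensemble(
    geometry: CellGeometry,
    transport: TransportParameters,
    motion: MotionParameters,
    manifest: EnsembleManifest,
    threshold: ThresholdSpec,
    grid: Grid1D | None = None,
    dt_solver: float = 5e-3,
    dt_trajectory: float = 1e-3,
    keep_series: bool = False,
    progress: bool = False,
):
    """Run the full pipeline for every trajectory in the manifest.

    Returns ``(records, series)``; ``series`` is a list of (times, theta_n)
    pairs when ``keep_series`` is True, else None.  The threshold is resolved
    once from the steady state at the apical starting position.
    """
    if grid is None:
        grid = Grid1D.make()
    groups = derive_dimensionless(geometry, transport, motion)
    exch = ExchangeGeometry.from_geometry(geometry)
    rules = PhaseRules(turning=manifest.turning, pause=manifest.pause, dt=dt_trajectory)
    ref_state = steady_state_with_nucleus(groups, exch, geometry.xi_min, grid)
    thr = resolve_threshold(threshold, ref_state)

    records = []
    series = [] if keep_series else None
    for spec in manifest.specs:
        traj = simulate_trajectory(
            geometry,
            groups,
            rules,
            seed=spec.seed,
            turning_position=spec.turning_position,
            pause_hours=spec.pause_hours,
        )
        result = transient_solve(groups, exch, traj, grid, dt=dt_solver)
        tau = depletion_time(result.theta_n, thr, dt_solver)
        records.append(
            DepletionRecord(
                trajectory_id=spec.trajectory_id,
                turning_position=spec.turning_position,
                tau=tau,
                total_time=float(result.times[-1]),
            )
        )
        if keep_series:
            series.append((result.times, result.theta_n))
        if progress and spec.trajectory_id % 100 == 0:
            logger.info("trajectory %d/%d done", spec.trajectory_id + 1, manifest.n)
    return records, series


def run_scenario_sweep(
    phis: Sequence[float],
    thresholds: Sequence[float],
    geometry: CellGeometry,
    transport: TransportParameters,
    motion: MotionParameters,
    manifest: EnsembleManifest,
    bin_edges: np.ndarray | None = None,
    grid: Grid1D | None = None,
    dt_solver: float = 5e-3,
    dt_trajectory: float = 1e-3,
    threshold_reference: str = "max_cytoplasmic",
) -> pd.DataFrame:
    """Sensitivity sweep over (phi, threshold fraction) pairs.

    The same trajectory ensemble (common random numbers) is reused for every
    pair — trajectories do not depend on phi — and, per phi, the nuclear
    concentration series is solved once and re-thresholded for every
    fraction.  Returns a long-format table (phi, threshold, bin columns).
    """
    if grid is None:
        grid = Grid1D.make()
    if bin_edges is None:
        bin_edges = default_bin_edges()
    exch = ExchangeGeometry.from_geometry(geometry)
    rules = PhaseRules(turning=manifest.turning, pause=manifest.pause, dt=dt_trajectory)

    # trajectories are phi-independent: simulate once
    groups0 = derive_dimensionless(geometry, transport, motion)
    trajectories = [
        simulate_trajectory(
            geometry,
            groups0,
            rules,
            seed=s.seed,
            turning_position=s.turning_position,
            pause_hours=s.pause_hours,
        )
        for s in manifest.specs
    ]

    rows = []
    for phi in phis:
        transport_phi = transport.with_phi(phi, geometry.length)
        groups = derive_dimensionless(geometry, transport_phi, motion)
        ref_state = steady_state_with_nucleus(groups, exch, geometry.xi_min, grid)
        solved = [transient_solve(groups, exch, traj, grid, dt=dt_solver) for traj in trajectories]
        for f in thresholds:
            thr = resolve_threshold(ThresholdSpec(f, threshold_reference), ref_state)
            records = [
                DepletionRecord(
                    trajectory_id=spec.trajectory_id,
                    turning_position=spec.turning_position,
                    tau=depletion_time(res.theta_n, thr, dt_solver),
                    total_time=float(res.times[-1]),
                )
                for spec, res in zip(manifest.specs, solved)
            ]
            binned = bin_probabilities(records, bin_edges)
            frame = binned.to_frame()
            frame.insert(0, "phi", phi)
            frame.insert(1, "threshold", f)
            frame["degenerate"] = binned.degenerate
            rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def make_default_manifest(
    geometry: CellGeometry,
    turning,
    pause,
    n: int,
    seed: int,
) -> EnsembleManifest:
    """Ensemble manifest with turning positions restricted to the admissible
    centroid range of ``geometry``."""
    return make_fixture_ensemble(
        turning, pause, n=n, seed=seed, xi_min=geometry.xi_min, xi_max=geometry.xi_max
    )
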