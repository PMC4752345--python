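"""Parametric stand-ins for the measured turning-position and pause-time
distributions of interkinetic nuclear migration.

The empirical distributions (basal turning position along the apico-basal
axis, and waiting time at the turning point) come from live imaging of the
zebrafish retina and are not available in tabulated form, so the ensemble
generator accepts configurable parametric families instead; an
EMPIRICAL_HISTOGRAM kind accepts digitized data (two-column CSV:
bin_edge_left, weight) so measured distributions can be dropped in later.

Defaults (see docs/methods.md for rationale): turning position uniform over
the admissible 30-90% span of the cell length, so every probability bin
receives trajectories — the depletion-probability normalization makes the
result independent of how turning positions are weighted across bins; pause
duration exponential with mean 1 h, the minimal waiting-time model.  Both
defaults are modeling assumptions, not measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "TurningDistribution",
    "PauseDistribution",
    "sample_turning",
    "sample_pause",
    "TrajectorySpec",
    "EnsembleManifest",
    "make_fixture_ensemble",
]

_TURNING_KINDS = ("uniform", "truncated_normal", "empirical_histogram")
_PAUSE_KINDS = ("exponential", "lognormal", "empirical_histogram", "fixed")


def _validate_histogram(edges: np.ndarray, weights: np.ndarray) -> None:
    if len(edges) != len(weights) + 1:
        raise ValueError("histogram needs len(edges) == len(weights) + 1")
    if np.any(np.diff(edges) < 0):
        raise ValueError("histogram bin edges must be non-decreasing")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("histogram weights must be non-negative with positive sum")


def _sample_histogram(edges: np.ndarray, weights: np.ndarray, rng: np.random.Generator, size):
    p = weights / weights.sum()
    idx = rng.choice(len(weights), size=size, p=p)
    left, right = edges[idx], edges[idx + 1]
    # zero-width (degenerate) bins return their midpoint
    return left + rng.uniform(0.0, 1.0, size=np.shape(idx)) * (right - left)


@dataclass(frozen=True)
class TurningDistribution:
    """Distribution of the basal turning position (fraction of cell length).

    kinds: ``uniform`` (low, high); ``truncated_normal`` (mean, sd, low,
    high); ``empirical_histogram`` (edges, weights).  The support must lie
    within the admissible centroid range of the geometry in use.
    """

    kind: str
    low: float = 0.0
    high: float = 1.0
    mean: float = 0.5
    sd: float = 0.1
    edges: Optional[tuple] = None
    weights: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.kind not in _TURNING_KINDS:
            raise ValueError(f"unknown turning distribution kind {self.kind!r}")
        if self.kind in ("uniform", "truncated_normal") and not self.low < self.high:
            raise ValueError("turning support is empty (low >= high)")
        if self.kind == "truncated_normal" and self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.kind == "empirical_histogram":
            if self.edges is None or self.weights is None:
                raise ValueError("empirical_histogram needs edges and weights")
            _validate_histogram(np.asarray(self.edges, float), np.asarray(self.weights, float))

    @property
    def support(self) -> tuple[float, float]:
        if self.kind == "empirical_histogram":
            return float(self.edges[0]), float(self.edges[-1])
        return self.low, self.high

    def sample(self, rng: np.random.Generator, size=None):
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, size=size)
        if self.kind == "truncated_normal":
            a = (self.low - self.mean) / self.sd
            b = (self.high - self.mean) / self.sd
            return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                       size=size, random_state=rng)
        return _sample_histogram(np.asarray(self.edges, float),
                                 np.asarray(self.weights, float), rng, size)

    @classmethod
    def from_config(cls, cfg: dict) -> "TurningDistribution":
        cfg = dict(cfg)
        kind = cfg.pop("kind")
        if "csv" in cfg:
            edges, weights = _read_histogram_csv(cfg.pop("csv"))
            return cls(kind=kind, edges=edges, weights=weights, **cfg)
        for key in ("edges", "weights"):
            if cfg.get(key) is not None:
                cfg[key] = tuple(cfg[key])
            else:
                cfg.pop(key, None)
        return cls(kind=kind, **cfg)


@dataclass(frozen=True)
class PauseDistribution:
    """Distribution of the pause (waiting) duration at the turning position,
    in hours.

    kinds: ``exponential`` (mean); ``lognormal`` (log_mean, log_sd, i.e. the
    mean and sd of log duration); ``empirical_histogram`` (edges, weights);
    ``fixed`` (value).
    """

    kind: str
    mean: float = 1.0
    log_mean: float = 0.0
    log_sd: float = 0.5
    value: float = 1.0
    edges: Optional[tuple] = None
    weights: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.kind not in _PAUSE_KINDS:
            raise ValueError(f"unknown pause distribution kind {self.kind!r}")
        if self.kind == "exponential" and self.mean <= 0:
            raise ValueError("exponential mean must be positive")
        if self.kind == "lognormal" and self.log_sd <= 0:
            raise ValueError("log_sd must be positive")
        if self.kind == "fixed" and self.value < 0:
            raise ValueError("fixed pause must be non-negative")
        if self.kind == "empirical_histogram":
            if self.edges is None or self.weights is None:
                raise ValueError("empirical_histogram needs edges and weights")
            edges = np.asarray(self.edges, float)
            _validate_histogram(edges, np.asarray(self.weights, float))
            if edges[0] < 0:
                raise ValueError("pause durations must be non-negative")

    def sample(self, rng: np.random.Generator, size=None):
        if self.kind == "exponential":
            return rng.exponential(self.mean, size=size)
        if self.kind == "lognormal":
            return rng.lognormal(self.log_mean, self.log_sd, size=size)
        if self.kind == "fixed":
            return self.value if size is None else np.full(size, self.value)
        return _sample_histogram(np.asarray(self.edges, float),
                                 np.asarray(self.weights, float), rng, size)

    @classmethod
    def from_config(cls, cfg: dict) -> "PauseDistribution":
        cfg = dict(cfg)
        kind = cfg.pop("kind")
        if "csv" in cfg:
            edges, weights = _read_histogram_csv(cfg.pop("csv"))
            return cls(kind=kind, edges=edges, weights=weights, **cfg)
        for key in ("edges", "weights"):
            if cfg.get(key) is not None:
                cfg[key] = tuple(cfg[key])
            else:
                cfg.pop(key, None)
        return cls(kind=kind, **cfg)


def _read_histogram_csv(path) -> tuple[tuple, tuple]:
    """Two-column CSV (bin_edge_left, weight); the last row's weight may be
    empty/zero and its edge closes the final bin."""
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    edges = tuple(data[:, 0])
    weights = tuple(data[:-1, 1])
    return edges, weights


def sample_turning(dist: TurningDistribution, rng: np.random.Generator, size=None):
    """Draw turning position(s) from ``dist``."""
    return dist.sample(rng, size=size)


def sample_pause(dist: PauseDistribution, rng: np.random.Generator, size=None):
    """Draw pause duration(s) in hours from ``dist``."""
    return dist.sample(rng, size=size)


@dataclass(frozen=True)
class TrajectorySpec:
    """Pre-sampled inputs of one trajectory: enough to replay it exactly."""

    trajectory_id: int
    turning_position: float
    pause_hours: float
    seed: int


@dataclass(frozen=True)
class EnsembleManifest:
    """Deterministic recipe for a trajectory ensemble (exact replay)."""

    seed: int
    n: int
    turning: TurningDistribution
    pause: PauseDistribution
    specs: tuple[TrajectorySpec, ...]

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "n": self.n,
            "turning": asdict(self.turning),
            "pause": asdict(self.pause),
            "specs": [asdict(s) for s in self.specs],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "EnsembleManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            seed=payload["seed"],
            n=payload["n"],
            turning=TurningDistribution.from_config(payload["turning"]),
            pause=PauseDistribution.from_config(payload["pause"]),
            specs=tuple(TrajectorySpec(**s) for s in payload["specs"]),
        )


def make_fixture_ensemble(
    turning: TurningDistribution,
    pause: PauseDistribution,
    n: int,
    seed: int,
    xi_min: float,
    xi_max: float,
    max_resample: int = 10_000,
) -> EnsembleManifest:
    """Sample ``n`` trajectory specifications (turning position, pause
    duration, child seed), deterministically from ``seed``.

    Turning positions outside the admissible centroid range
    ``[xi_min, xi_max]`` are resampled (rejection); a distribution whose
    support misses the admissible range entirely raises.
    """
    if n < 1:
        raise ValueError("ensemble size must be at least 1")
    lo, hi = turning.support
    if hi < xi_min or lo > xi_max:
        raise ValueError(
            f"turning support [{lo:.3f}, {hi:.3f}] lies outside the "
            f"admissible centroid range [{xi_min:.3f}, {xi_max:.3f}]"
        )
    # child 0 feeds the distribution sampler; children 1..n seed the
    # per-trajectory noise, so growing n never reshuffles earlier trajectories
    children = np.random.SeedSequence(seed).spawn(n + 1)
    sampler_rng = np.random.default_rng(children[0])
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children[1:]]

    specs = []
    for i in range(n):
        xi_turn = float(sample_turning(turning, sampler_rng))
        tries = 0
        while not xi_min <= xi_turn <= xi_max:
            xi_turn = float(sample_turning(turning, sampler_rng))
            tries += 1
            if tries > max_resample:
                raise RuntimeError("could not sample an admissible turning position")
        tau = float(sample_pause(pause, sampler_rng))
        specs.append(TrajectorySpec(trajectory_id=i, turning_position=xi_turn,
                                    pause_hours=tau, seed=child_seeds[i]))
    return EnsembleManifest(seed=seed, n=n, turning=turning, pause=pause,
                            specs=tuple(specs))
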