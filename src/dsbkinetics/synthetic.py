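"""Synthetic replica trajectories with the statistics the analysis assumes.

The downstream pipeline consumes three observables per replica of a DSB
scenario: the internal energy of the residual contact-interface
nucleotides, the minimum distance between the broken moieties, and (for
time mapping) the centre-of-mass track of a freely diffusing molecule.
This module generates ensembles of such traces from a known ground truth
so the whole detection + fitting chain can be validated by parameter
recovery:

* rupture is a two-state, thermally activated event: waiting times are
  exponential with mean ``tau0 * exp(k1 * b_d)`` (Arrhenius in the DSB
  distance b_d);
* the energy trace switches between a bound plateau ``E_min`` and a broken
  plateau ``E_max`` through a base-10 logistic of steepness ``m`` centred
  at the rupture time, plus stationary AR(1) (discretised
  Ornstein-Uhlenbeck) noise;
* the plateau separation grows linearly with b_d, ``E_max - E_min =
  2 * (alpha * b_d + sigma_c)``, so the energy read at the flex of the
  transition is ``alpha * b_d + sigma_c`` above the bound plateau;
* the minimum inter-moiety distance fluctuates about a bound value until
  rupture, then drifts away linearly in the mean;
* diffusion tracks are ideal 3-D Brownian motion of known coefficient.

Replicas whose sampled rupture time exceeds the trace duration are
generated honestly as censored (no transition), not resampled.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .mechanics import ScenarioConfig


@dataclass
class GeneratorParams:
    """Ground-truth parameters of the synthetic-trajectory generator.

    Energy is in units of kB*T, time in ns, distance in nm.  Defaults
    follow the blunt-break study conditions: mean blunt rupture time
    1.0 ns, Arrhenius increment 1.7 per base pair, energy law
    ``deltaU = 7.1 * b_d + 7.8`` kT, plateau noise s.d. 2 kT.
    """

    E_min: float = 0.0
    E_max: Optional[float] = None      # None -> from the alpha/sigma_c law
    alpha_true: float = 7.1            # kT per bp, plateau-gap law
    sigmac_true: float = 7.8           # kT, plateau-gap offset
    m_true: float = 5.0                # sigmoid steepness, decades / ns
    tau0_true: float = 1.0             # ns, blunt-DSB mean rupture time
    k1_true: float = 1.7               # dimensionless, per bp
    noise_sigma: float = 2.0           # kT
    noise_corr_time: float = 0.5       # ns
    d_bound: float = 1.0               # nm, bound-state interface distance
    d_noise_sigma: float = 0.15        # nm
    drift_rate: float = 2.0            # nm / ns after rupture
    dt: float = 0.1759                 # ns  (103 LJ time units)
    duration: Optional[float] = None   # ns; None -> duration_factor * mean
    duration_factor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_true", "sigmac_true", "m_true", "tau0_true",
                     "noise_corr_time", "d_bound", "drift_rate", "dt",
                     "duration_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.noise_sigma < 0 or self.d_noise_sigma < 0:
            raise ValueError("noise s.d. must be non-negative")
        if self.E_max is not None and self.E_max <= self.E_min:
            raise ValueError("E_max must exceed E_min")
        if self.duration is not None and self.duration <= self.dt:
            raise ValueError("duration must exceed dt")

    def plateau_gap(self, b_d: int) -> float:
        """E_max - E_min for DSB distance ``b_d`` (kT)."""
        if self.E_max is not None:
            return self.E_max - self.E_min
        return 2.0 * (self.alpha_true * b_d + self.sigmac_true)

    def trace_duration(self, b_d: int) -> float:
        if self.duration is not None:
            return self.duration
        return self.duration_factor * mean_rupture_time(
            b_d, self.tau0_true, self.k1_true)

    def frame_interval(self, b_d: int) -> float:
        """Sampling interval for scenario ``b_d`` (ns).

        The saved-frame interval must resolve the shortest expected
        dwell time, so it is refined below ``dt`` whenever the scenario
        mean rupture time is short: dt_eff = min(dt, mean/50).
        """
        if self.duration is not None:
            return self.dt
        mean = mean_rupture_time(b_d, self.tau0_true, self.k1_true)
        return min(self.dt, mean / 50.0)


@dataclass
class EnergyTrace:
    """Internal energy of the contact-interface nucleotides vs time."""

    times: np.ndarray          # ns, uniform, strictly increasing
    energies: np.ndarray       # kT
    scenario: Optional[ScenarioConfig] = None
    replica_id: Optional[str] = None
    true_rupture_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.times.shape != self.energies.shape:
            raise ValueError("times and energies must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class DistanceTrace:
    """Minimum inter-moiety distance vs time."""

    times: np.ndarray          # ns
    min_distance: np.ndarray   # nm, >= 0
    scenario: Optional[ScenarioConfig] = None
    replica_id: Optional[str] = None
    true_rupture_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.min_distance = np.asarray(self.min_distance, dtype=float)
        if self.times.shape != self.min_distance.shape:
            raise ValueError("times and min_distance must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.min_distance < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class BrownianTrack:
    """Centre-of-mass track of a freely diffusing molecule (um)."""

    times: np.ndarray          # LJ time units
    positions: np.ndarray      # (n, 3) um
    true_D: Optional[float] = None   # um^2 per LJ time unit

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if self.positions.shape[0] != self.times.size:
            raise ValueError("times and positions must have equal length")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")


def mean_rupture_time(b_d: int, tau0: float, k1: float) -> float:
    """Arrhenius mean rupture time tau0 * exp(k1 * b_d) in ns."""
    if b_d < 0:
        raise ValueError("b_d must be non-negative")
    if tau0 <= 0:
        raise ValueError("tau0 must be strictly positive")
    return tau0 * np.exp(k1 * b_d)


def sample_rupture_time(b_d: int, params: GeneratorParams,
                        rng: np.random.Generator) -> float:
    """One exponential waiting-time draw with the Arrhenius mean (ns)."""
    return float(rng.exponential(
        mean_rupture_time(b_d, params.tau0_true, params.k1_true)))


def sigmoid_mean_path(t: np.ndarray, E_min: float, E_max: float,
                      m: float, t50: float) -> np.ndarray:
    """Base-10 logistic between the bound and broken plateaus.

    Evaluated through the numerically stable logistic function:
    1 / (1 + 10^(m (t50 - t))) = expit(ln10 * m * (t - t50)).
    """
    from scipy.special import expit
    t = np.asarray(t, dtype=float)
    return E_min + (E_max - E_min) * expit(
        np.log(10.0) * m * (t - t50))


def _ar1_noise(n: int, sigma: float, corr_time: float, dt: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise of s.d. ``sigma``, correlation time in ns."""
    if sigma == 0 or n == 0:
        return np.zeros(n)
    from scipy.signal import lfilter
    phi = np.exp(-dt / corr_time)
    innov = rng.normal(0.0, sigma * np.sqrt(1.0 - phi ** 2), size=n)
    innov[0] = rng.normal(0.0, sigma)   # start in the stationary law
    return lfilter([1.0], [1.0, -phi], innov)


def _time_grid(duration: float, dt: float) -> np.ndarray:
    n = max(int(np.floor(duration / dt)) + 1, 2)
    return np.arange(n) * dt


def generate_energy_trace(scenario: ScenarioConfig, rupture_time: float,
                          params: GeneratorParams,
                          rng: np.random.Generator) -> EnergyTrace:
    """Two-plateau energy trace with a logistic transition at rupture.

    If the rupture time falls beyond the trace duration the transition is
    (mostly or wholly) outside the window and the replica is censored.
    """
    duration = params.trace_duration(scenario.b_d)
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt = params.frame_interval(scenario.b_d)
    t = _time_grid(duration, dt)
    gap = params.plateau_gap(scenario.b_d)
    mean = sigmoid_mean_path(t, params.E_min, params.E_min + gap,
                             params.m_true, rupture_time)
    noise = _ar1_noise(t.size, params.noise_sigma, params.noise_corr_time,
                       dt, rng)
    return EnergyTrace(times=t, energies=mean + noise, scenario=scenario,
                       true_rupture_time=rupture_time)


def generate_distance_trace(scenario: ScenarioConfig, rupture_time: float,
                            params: GeneratorParams,
                            rng: np.random.Generator) -> DistanceTrace:
    """Bound-then-drifting minimum inter-moiety distance trace."""
    duration = params.trace_duration(scenario.b_d)
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt = params.frame_interval(scenario.b_d)
    t = _time_grid(duration, dt)
    mean = np.where(t < rupture_time, params.d_bound,
                    params.d_bound + params.drift_rate * (t - rupture_time))
    noise = _ar1_noise(t.size, params.d_noise_sigma, params.noise_corr_time,
                       dt, rng)
    return DistanceTrace(times=t, min_distance=np.clip(mean + noise, 0, None),
                         scenario=scenario, true_rupture_time=rupture_time)


def generate_replica(scenario: ScenarioConfig, params: GeneratorParams,
                     rng: np.random.Generator,
                     replica_id: Optional[str] = None
                     ) -> Tuple[EnergyTrace, DistanceTrace]:
    """One paired (energy, distance) replica sharing a single rupture time."""
    tau = sample_rupture_time(scenario.b_d, params, rng)
    e = generate_energy_trace(scenario, tau, params, rng)
    d = generate_distance_trace(scenario, tau, params, rng)
    e.replica_id = d.replica_id = replica_id
    return e, d


def generate_brownian_track(D: float, n_steps: int, dt: float,
                            rng: np.random.Generator) -> BrownianTrack:
    """3-D random walk with per-step per-coordinate s.d. sqrt(2 D dt).

    ``D`` in um^2 per LJ time unit, ``dt`` in LJ time units.
    """
    if D <= 0:
        raise ValueError("D must be strictly positive")
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_steps, 3))
    pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return BrownianTrack(times=np.arange(n_steps + 1) * dt,
                         positions=pos, true_D=D)


def _replica_rng(seed: int, scenario_index: int,
                 replica_index: int) -> np.random.Generator:
    """Counter-based seed fan-out: each replica gets its own stream."""
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(scenario_index, replica_index))
    return np.random.default_rng(ss)


@dataclass
class EnsembleManifest:
    """Inventory of a generated ensemble, JSON-serializable."""

    seed: int
    params: dict
    entries: List[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EnsembleManifest":
        d = json.loads(text)
        return cls(seed=d["seed"], params=d["params"], entries=d["entries"])


def generate_ensemble(scenarios: Sequence[ScenarioConfig], n_replicas: int,
                      params: GeneratorParams, seed: int,
                      outdir: Optional[str] = None
                      ) -> Tuple[EnsembleManifest,
                                 List[Tuple[EnergyTrace, DistanceTrace]]]:
    """Paired trace ensemble over a scenario grid, deterministic under seed.

    When ``outdir`` is given, traces are written as TSV and the manifest
    records their paths; otherwise paths are None and traces live in
    memory only.
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be at least 1")
    from . import io as _io   # local import to avoid a cycle

    manifest = EnsembleManifest(seed=seed, params=asdict(params))
    traces: List[Tuple[EnergyTrace, DistanceTrace]] = []
    for si, scenario in enumerate(scenarios):
        for ri in range(n_replicas):
            rid = f"bd{scenario.b_d}_F{scenario.F_z:.2f}_r{ri:04d}"
            rng = _replica_rng(seed, si, ri)
            e, d = generate_replica(scenario, params, rng, replica_id=rid)
            epath = dpath = None
            if outdir is not None:
                os.makedirs(outdir, exist_ok=True)
                epath = os.path.join(outdir, f"{rid}_energy.tsv")
                dpath = os.path.join(outdir, f"{rid}_distance.tsv")
                _io.write_trace(epath, e)
                _io.write_trace(dpath, d)
            manifest.entries.append({
                "scenario": scenario.to_dict(), "replica_id": rid,
                "scenario_index": si, "replica_index": ri,
                "energy_path": epath, "distance_path": dpath,
                "true_rupture_time": e.true_rupture_time,
            })
            traces.append((e, d))
    if outdir is not None:
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            fh.write(manifest.to_json())
    return manifest, traces
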