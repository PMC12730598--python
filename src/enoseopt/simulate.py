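"""Synthetic electronic-nose data generator.

Emulates a cold-chain spoilage experiment: a sealed chamber of shellfish
releases volatile compounds whose concentrations evolve with storage time
and temperature; a ten-sensor array samples the headspace at 1 Hz for
5 minutes per measurement cycle.

Each simulated sensor trace follows the rise-to-plateau target-curve form

    x(t) = a * f(c*t - b) + d + e * Noise(t),

where ``f(u) = 1 - exp(-u)`` for ``u >= 0`` (0 otherwise) is the canonical
metal-oxide-sensor response morphology, ``a`` aggregates per-class affinity
times concentration (mapped into the sensor's detection span), ``b``/``c``
set onset delay and rise rate, ``d`` is the baseline offset and ``e`` the
noise amplitude.

Spoilage-marker concentrations (amines, sulfides, ammonia, H2S) follow
logistic growth on a temperature-compressed "effective time" axis: rates
double per 10 degC (Q10 = 2), so spoilage stages occur proportionally
earlier at higher storage temperature.  Freshness classes are storage-time
bins (early / middle / advanced spoilage) defined on the same effective
axis.  Background volatiles (ethanol, hydrogen, alkanes, CO, solvents)
carry no class signal; their cycle-to-cycle variation is shared across
sensors, which is what makes the planted redundant groups mutually
correlated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .panel import (
    COMPOUND_CLASSES,
    SENSOR_IDS,
    SPOILAGE_MARKERS,
    SensorProfile,
    default_panel,
)

__all__ = [
    "VocTrajectory",
    "SpoilageScenario",
    "ResponseCycle",
    "rise_plateau",
    "simulate_response",
    "generate_dataset",
    "DEFAULT_TEMPERATURES",
]

DEFAULT_TEMPERATURES = (4.0, 12.0, 20.0, 28.0)

#: Effective-time horizon of the modelled spoilage process (hours at 4 degC).
_EFFECTIVE_HORIZON_H = 72.0

#: Cycle length: 5 min at 1 Hz.
N_SAMPLES = 300
SAMPLE_HZ = 1.0


def rise_plateau(u):
    """Reference response-curve shape ``f(u) = 1 - exp(-u)`` for u >= 0, else 0."""
    u = np.asarray(u, dtype=float)
    return np.where(u > 0.0, -np.expm1(-np.minimum(u, 700.0) * (u > 0.0)), 0.0)


def q10_factor(temperature_c: float, reference_c: float = 4.0, q10: float = 2.0) -> float:
    """Rate multiplier: doubles every 10 degC above the reference temperature."""
    return float(q10 ** ((temperature_c - reference_c) / 10.0))


@dataclass(frozen=True)
class VocTrajectory:
    """Concentration-versus-storage-time model for one compound class.

    ``conc(t) = baseline + amplitude * sigmoid(rate * (t_eff - midpoint))``
    where ``t_eff`` is storage time scaled by the Q10 temperature factor.
    ``amplitude = 0`` gives a time-constant background compound.
    ``jitter_group`` names the shared cycle-level multiplicative
    disturbance this compound belongs to (compounds in one group scale
    together within a cycle); ``jitter_sd`` is the log-sd of that factor.
    """

    baseline: float
    amplitude: float = 0.0
    midpoint_h: float = 36.0
    rate_per_h: float = 0.12
    jitter_group: str = "markers"
    jitter_sd: float = 0.05

    def concentration(self, storage_h: float, temperature_c: float,
                      class_signal_scale: float = 1.0) -> float:
        """Noise-free concentration at a clock storage time and temperature."""
        if storage_h < 0:
            raise ValueError(f"negative storage_time {storage_h}")
        t_eff = storage_h * q10_factor(temperature_c)
        z = self.rate_per_h * (t_eff - self.midpoint_h)
        sig = 1.0 / (1.0 + math.exp(-max(min(z, 60.0), -60.0)))
        return self.baseline + class_signal_scale * self.amplitude * sig


def _default_trajectories() -> dict:
    """Trajectory family for the bundled spoilage scenario.

    Markers rise in two logistic waves aligned with the spoilage-stage
    boundaries: amines/ammonia switch on at the early->middle boundary
    (24 effective hours), sulfides/H2S at the middle->advanced boundary
    (48 effective hours) — the amine wave marks mid-spoilage, the sulfur
    wave advanced putrefaction.  Background volatiles are constant in
    time but carry large shared cycle-to-cycle jitter ("fuel" group for
    ethanol/hydrogen/alkanes driving S3/S7/S8, "burn" group for
    CO/solvents driving S9/S10).
    """
    return {
        "amines": VocTrajectory(2.0, 300.0, midpoint_h=24.0, rate_per_h=0.35),
        "ammonia": VocTrajectory(2.0, 100.0, midpoint_h=26.0, rate_per_h=0.30),
        "sulfides": VocTrajectory(1.0, 60.0, midpoint_h=48.0, rate_per_h=0.35),
        "hydrogen_sulfide": VocTrajectory(0.5, 40.0, midpoint_h=50.0, rate_per_h=0.30),
        "ethanol": VocTrajectory(50.0, jitter_group="fuel", jitter_sd=0.35),
        "hydrogen": VocTrajectory(20.0, jitter_group="h2", jitter_sd=0.35),
        "alkanes": VocTrajectory(15.0, jitter_group="fuel", jitter_sd=0.35),
        "co": VocTrajectory(40.0, jitter_group="burn", jitter_sd=0.35),
        "organic_solvents": VocTrajectory(25.0, jitter_group="burn", jitter_sd=0.35),
        "toluene": VocTrajectory(3.0, jitter_group="trace", jitter_sd=0.20),
        "benzene": VocTrajectory(2.0, jitter_group="trace", jitter_sd=0.20),
        "refrigerant": VocTrajectory(0.0),
    }


@dataclass(frozen=True)
class SpoilageScenario:
    """One temperature condition of the simulated storage experiment.

    ``class_boundaries`` are clock-time cut points (hours) splitting the
    modelled horizon into ``n_classes`` freshness classes; by default they
    are placed uniformly on the effective-time axis, so every temperature
    exhibits the same spoilage stages, reached earlier when warm.
    """

    temperature: float
    n_classes: int = 3
    voc_trajectories: dict = field(default_factory=_default_trajectories)
    class_boundaries: tuple = None
    horizon_h: float = None
    class_signal_scale: float = 1.0
    env_jitter_scale: float = 1.0

    def __post_init__(self):
        q = q10_factor(self.temperature)
        if self.horizon_h is None:
            object.__setattr__(self, "horizon_h", _EFFECTIVE_HORIZON_H / q)
        if self.class_boundaries is None:
            edges = np.linspace(0.0, _EFFECTIVE_HORIZON_H, self.n_classes + 1)[1:-1] / q
            object.__setattr__(self, "class_boundaries", tuple(float(x) for x in edges))
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if len(self.class_boundaries) != self.n_classes - 1:
            raise ValueError("class_boundaries must have n_classes - 1 cut points")
        # Spoilage markers must be non-decreasing in storage time.
        for name, traj in self.voc_trajectories.items():
            if name in SPOILAGE_MARKERS and traj.amplitude < 0:
                raise ValueError(f"marker {name} must have non-negative amplitude")

    def label_for(self, storage_h: float) -> int:
        """Freshness class index of a storage time (0 = freshest)."""
        return int(np.searchsorted(self.class_boundaries, storage_h, side="right"))

    def class_interval(self, label: int) -> tuple:
        edges = (0.0, *self.class_boundaries, self.horizon_h)
        if not 0 <= label < self.n_classes:
            raise ValueError(f"label {label} out of range")
        return edges[label], edges[label + 1]

    def concentration(self, compound: str, storage_h: float) -> float:
        traj = self.voc_trajectories.get(compound)
        if traj is None:
            return 0.0
        return traj.concentration(storage_h, self.temperature, self.class_signal_scale)

    def draw_jitter(self, rng: np.random.Generator) -> dict:
        """Cycle-level multiplicative disturbance per compound class.

        Compounds sharing a jitter group scale together (the gas mixture
        varies, not the individual sensors); marker compounds get small
        independent factors.
        """
        group_factor = {}
        factors = {}
        for name in sorted(self.voc_trajectories):
            traj = self.voc_trajectories[name]
            sd = traj.jitter_sd * self.env_jitter_scale
            if sd <= 0:
                factors[name] = 1.0
                continue
            if traj.jitter_group == "markers":
                factors[name] = float(rng.lognormal(0.0, sd))
            else:
                if traj.jitter_group not in group_factor:
                    group_factor[traj.jitter_group] = float(rng.lognormal(0.0, sd))
                factors[name] = group_factor[traj.jitter_group]
        return factors


@dataclass
class ResponseCycle:
    """One measurement cycle: a 10-channel, 1 Hz, 5-minute raw trace."""

    cycle_id: str
    temperature: float
    label: int
    t: np.ndarray
    readings: np.ndarray
    sensor_ids: tuple = SENSOR_IDS
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if self.readings.shape != (len(self.sensor_ids), self.t.size):
            raise ValueError(
                f"readings shape {self.readings.shape} does not match "
                f"({len(self.sensor_ids)}, {self.t.size})"
            )
        dt = np.diff(self.t)
        if self.t.size > 1 and not np.allclose(dt, dt[0]):
            raise ValueError("time grid must be uniform")

    def __eq__(self, other):
        if not isinstance(other, ResponseCycle):
            return NotImplemented
        return (
            self.cycle_id == other.cycle_id
            and self.temperature == other.temperature
            and self.label == other.label
            and self.sensor_ids == tuple(other.sensor_ids)
            and np.array_equal(self.t, other.t)
            and np.allclose(self.readings, other.readings, rtol=0, atol=1e-9)
        )


def _steady_amplitude(profile: SensorProfile, scenario: SpoilageScenario,
                      storage_h: float, jitter: dict | None = None) -> float:
    """Steady-state response amplitude above baseline, in sensor units.

    Aggregates affinity x concentration over the compound classes the
    sensor targets, then maps it into the sensor's detection span through
    a saturating law so the plateau stays inside [range_low, range_high].
    """
    total = 0.0
    for cls, gain in profile.affinity.items():
        conc = scenario.concentration(cls, storage_h)
        if jitter is not None:
            conc *= jitter.get(cls, 1.0)
        total += gain * conc
    frac = -math.expm1(-total / profile.conc_scale)
    return profile.span * frac


def simulate_response(
    profile: SensorProfile,
    scenario: SpoilageScenario,
    storage_time: float,
    seed: int | np.random.Generator,
    jitter: dict | None = None,
    gain: float = 1.0,
    noise_sd: float | None = None,
    ar1: float = 0.0,
    n_samples: int = N_SAMPLES,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one sensor's raw trace for one measurement cycle.

    Returns ``(t, x)`` with ``t`` the 1 Hz grid and ``x`` the trace
    ``a*f(c*t - b) + d + e*Noise(t)``.  Identical inputs and seed produce
    bitwise-identical traces.

    Parameters
    ----------
    storage_time : float
        Elapsed storage in hours; must lie in the scenario's horizon.
    jitter : dict, optional
        Cycle-level concentration factors from ``scenario.draw_jitter``.
    gain : float
        Extra multiplicative sensor-state factor (redundancy jitter).
    noise_sd : float, optional
        Override of the profile's noise level (fraction of span).
    ar1 : float
        AR(1) coefficient for optional correlated drift noise; 0 = i.i.d.
    """
    if storage_time < 0:
        raise ValueError(f"negative storage_time {storage_time}")
    if storage_time > scenario.horizon_h * (1 + 1e-9):
        raise ValueError(
            f"storage_time {storage_time} outside scenario horizon {scenario.horizon_h:.2f} h"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(n_samples, dtype=float) / SAMPLE_HZ

    a = gain * _steady_amplitude(profile, scenario, storage_time, jitter)
    c = profile.rise_rate
    b = profile.rise_rate * profile.delay  # onset at t = delay
    d = profile.range_low
    sd = profile.noise_sd if noise_sd is None else noise_sd
    e = sd * profile.span

    x = a * rise_plateau(c * t - b) + d
    if e > 0:
        eps = rng.standard_normal(n_samples)
        if ar1:
            drift = np.empty(n_samples)
            drift[0] = eps[0]
            for i in range(1, n_samples):
                drift[i] = ar1 * drift[i - 1] + math.sqrt(1 - ar1**2) * eps[i]
            eps = drift
        x = x + e * eps
    return t, x


def generate_dataset(
    scenarios,
    n_cycles_per_class: int,
    seed: int,
    panel: list[SensorProfile] | None = None,
    redundancy: float = 0.95,
    n_replicates: int = 1,
    noise_sd: float | None = None,
    stage_guard_frac: float = 0.15,
) -> list[ResponseCycle]:
    """Generate a balanced, labelled synthetic dataset.

    For every (scenario, class) pair, ``n_cycles_per_class`` samples are
    drawn with storage times uniform within the class's storage-time bin,
    excluding a guard band of ``stage_guard_frac`` of the bin width at
    each boundary (stage labels are assigned away from transitions).
    ``redundancy`` in [0, 1) controls how tightly redundant-group sensors
    co-vary: the per-cycle per-sensor gain jitter has log-sd
    ``0.5 * (1 - redundancy)``.  With ``n_replicates > 1``, each sample
    yields several replicate cycles sharing the gas mixture (jitter) but
    with independent measurement noise, mirroring repeated sampling
    sessions to be averaged during preprocessing.

    The whole dataset is a pure function of (arguments, seed).
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("empty scenario set")
    if n_cycles_per_class < 1:
        raise ValueError("n_cycles_per_class must be >= 1")
    if not 0.0 <= redundancy < 1.0:
        raise ValueError("redundancy must be in [0, 1)")
    panel = default_panel() if panel is None else list(panel)
    rng = np.random.default_rng(seed)
    gain_sd = 0.5 * (1.0 - redundancy)

    cycles: list[ResponseCycle] = []
    for scenario in scenarios:
        for label in range(scenario.n_classes):
            lo, hi = scenario.class_interval(label)
            for i in range(n_cycles_per_class):
                margin = stage_guard_frac * (hi - lo)
                storage = float(rng.uniform(lo + margin, hi - margin))
                jitter = scenario.draw_jitter(rng)
                gains = np.exp(rng.normal(0.0, gain_sd, size=len(panel))) if gain_sd > 0 else np.ones(len(panel))
                sample_id = f"T{scenario.temperature:g}_c{label}_{i:03d}"
                for rep in range(n_replicates):
                    rows = []
                    t = None
                    for j, profile in enumerate(panel):
                        t, x = simulate_response(
                            profile, scenario, storage, rng,
                            jitter=jitter, gain=float(gains[j]), noise_sd=noise_sd,
                        )
                        rows.append(x)
                    cid = sample_id if n_replicates == 1 else f"{sample_id}_r{rep}"
                    cycles.append(
                        ResponseCycle(
                            cycle_id=cid,
                            temperature=scenario.temperature,
                            label=label,
                            t=t,
                            readings=np.vstack(rows),
                            sensor_ids=tuple(p.sensor_id for p in panel),
                            meta={
                                "storage_h": storage,
                                "sample_id": sample_id,
                                "replicate": rep,
                            },
                        )
                    )
    return cycles


def default_scenarios(
    temperatures=DEFAULT_TEMPERATURES,
    n_classes: int = 3,
    class_signal_scale: float = 1.0,
    env_jitter_scale: float = 1.0,
) -> list[SpoilageScenario]:
    """One bundled scenario per storage temperature."""
    return [
        SpoilageScenario(
            temperature=float(T),
            n_classes=n_classes,
            class_signal_scale=class_signal_scale,
            env_jitter_scale=env_jitter_scale,
        )
        for T in temperatures
    ]
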