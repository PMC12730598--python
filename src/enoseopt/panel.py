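"""Sensor panel definitions for the ten-channel electronic nose.

The bundled panel mirrors a typical oyster cold-chain array built from
Figaro TGS and Winsen MQ metal-oxide sensors.  Each profile records which
volatile-compound classes the sensor responds to, its nominal detection
range, and the simulator-facing response parameters (per-class gains,
rise kinetics, baseline noise).

Cross-sensitivity is the point of such an array: single sensors respond to
several compound classes, and several sensors overlap.  Two deliberately
redundant groups are present — S3/S7/S8 (ethanol/hydrogen/alkanes, same
TGS261x family) and S9/S10 (ethanol/CO/alkanes) — which the selection and
clustering machinery is expected to rediscover and prune.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "COMPOUND_CLASSES",
    "SPOILAGE_MARKERS",
    "SENSOR_IDS",
    "SensorProfile",
    "default_panel",
]

#: Volatile-compound classes modelled by the simulator.
COMPOUND_CLASSES = (
    "ethanol",
    "hydrogen",
    "ammonia",
    "hydrogen_sulfide",
    "toluene",
    "amines",
    "sulfides",
    "alkanes",
    "refrigerant",
    "benzene",
    "organic_solvents",
    "co",
)

#: Classes whose concentration rises monotonically as spoilage advances.
SPOILAGE_MARKERS = frozenset({"amines", "sulfides", "ammonia", "hydrogen_sulfide"})

SENSOR_IDS = tuple(f"S{i}" for i in range(1, 11))


@dataclass(frozen=True)
class SensorProfile:
    """Static description of one gas sensor channel.

    Parameters
    ----------
    sensor_id : str
        One of ``S1``..``S10``.
    model : str
        Manufacturer part name (informational).
    target_classes : frozenset of str
        Compound classes the sensor responds to.
    range_low, range_high : float
        Detection bounds in the sensor's own units (ppm or %LEL); the
        simulated steady-state response lies inside this interval.
    unit : str
        Unit of the detection bounds.
    affinity : dict
        Dimensionless gain per compound class; zero (absent) outside
        ``target_classes``.
    noise_sd : float
        Baseline noise level as a fraction of the response span.
    rise_rate : float
        First-order rise-rate constant of the response curve, 1/s.
    delay : float
        Response onset delay, s.
    conc_scale : float
        Concentration (in the shared simulator units) producing
        ``1 - 1/e`` of the full-span steady response.
    """

    sensor_id: str
    model: str
    target_classes: frozenset
    range_low: float
    range_high: float
    unit: str
    affinity: dict = field(default_factory=dict)
    noise_sd: float = 0.01
    rise_rate: float = 0.03
    delay: float = 15.0
    conc_scale: float = 50.0

    def __post_init__(self):
        if self.sensor_id not in SENSOR_IDS:
            raise ValueError(f"unknown sensor_id {self.sensor_id!r}; expected one of {SENSOR_IDS}")
        if not self.range_low < self.range_high:
            raise ValueError(
                f"{self.sensor_id}: range_low ({self.range_low}) must be < range_high ({self.range_high})"
            )
        unknown = set(self.target_classes) - set(COMPOUND_CLASSES)
        if unknown:
            raise ValueError(f"{self.sensor_id}: unknown compound classes {sorted(unknown)}")
        for cls, gain in self.affinity.items():
            if cls not in self.target_classes:
                raise ValueError(
                    f"{self.sensor_id}: affinity for {cls!r} outside target_classes"
                )
            if gain < 0:
                raise ValueError(f"{self.sensor_id}: negative affinity for {cls!r}")
        if self.noise_sd < 0:
            raise ValueError(f"{self.sensor_id}: noise_sd must be >= 0")
        if self.rise_rate <= 0:
            raise ValueError(f"{self.sensor_id}: rise_rate must be > 0")

    @property
    def span(self) -> float:
        return self.range_high - self.range_low


def _profile(sensor_id, model, classes, low, high, unit, affinity, **kw):
    return SensorProfile(
        sensor_id=sensor_id,
        model=model,
        target_classes=frozenset(classes),
        range_low=low,
        range_high=high,
        unit=unit,
        affinity=affinity,
        **kw,
    )


def default_panel() -> list[SensorProfile]:
    """The ten bundled sensor profiles.

    Class memberships follow the standard datasheet groupings for this
    array: S5 is the amine specialist; S3/S7/S8 share the
    ethanol/hydrogen/alkane set (high-similarity group); S9/S10 add CO and
    organic solvents on top of that set (second similarity group); S1, S2
    and S6 carry the sulfide/ammonia spoilage markers.

    Affinities weight the spoilage markers onto S1/S2/S5/S6 so the
    class-separating signal is carried predominantly by amine- and
    sulfide-responsive channels, while the redundant groups are driven by
    shared background volatiles.  Rise kinetics differ per sensor family,
    giving each channel a distinct response-curve shape; redundant-group
    members share nearly identical kinetics.
    """
    return [
        _profile(
            "S1", "TGS2602",
            {"ethanol", "hydrogen", "ammonia", "hydrogen_sulfide", "toluene"},
            1.0, 30.0, "ppm",
            {"hydrogen_sulfide": 1.0, "ammonia": 0.05, "ethanol": 0.05,
             "hydrogen": 0.05, "toluene": 0.05},
            rise_rate=0.050, delay=12.0, conc_scale=40.0,
        ),
        _profile(
            "S2", "TGS2603",
            {"ethanol", "hydrogen", "amines", "sulfides"},
            1.0, 10.0, "ppm",
            {"amines": 0.80, "sulfides": 0.60, "ethanol": 0.05, "hydrogen": 0.05},
            rise_rate=0.045, delay=14.0, conc_scale=60.0,
        ),
        _profile(
            "S3", "TGS2612",
            {"ethanol", "hydrogen", "alkanes"},
            1.0, 25.0, "%LEL",
            {"ethanol": 0.50, "hydrogen": 0.30, "alkanes": 0.40},
            rise_rate=0.030, delay=18.0, conc_scale=55.0,
        ),
        _profile(
            "S4", "TGS2630",
            {"hydrogen", "refrigerant"},
            1000.0, 10000.0, "ppm",
            {"hydrogen": 1.0, "refrigerant": 0.5},
            rise_rate=0.080, delay=10.0, conc_scale=120.0,
        ),
        _profile(
            "S5", "MQ137",
            {"amines"},
            5.0, 500.0, "ppm",
            {"amines": 1.0},
            rise_rate=0.020, delay=22.0, conc_scale=120.0,
        ),
        _profile(
            "S6", "MQ135",
            {"ammonia", "sulfides", "benzene"},
            10.0, 1000.0, "ppm",
            {"ammonia": 0.80, "sulfides": 0.15, "benzene": 0.10},
            rise_rate=0.060, delay=11.0, conc_scale=70.0,
        ),
        _profile(
            "S7", "TGS2611",
            {"ethanol", "hydrogen", "alkanes"},
            1.0, 25.0, "%LEL",
            {"ethanol": 0.55, "hydrogen": 0.28, "alkanes": 0.38},
            rise_rate=0.031, delay=17.5, conc_scale=55.0,
        ),
        _profile(
            "S8", "TGS2610",
            {"ethanol", "hydrogen", "alkanes"},
            1.0, 25.0, "%LEL",
            {"ethanol": 0.45, "hydrogen": 0.33, "alkanes": 0.42},
            rise_rate=0.029, delay=18.5, conc_scale=55.0,
        ),
        _profile(
            "S9", "TGS2620",
            {"ethanol", "hydrogen", "organic_solvents", "co", "alkanes"},
            50.0, 5000.0, "ppm",
            {"ethanol": 0.20, "hydrogen": 0.10, "organic_solvents": 0.70,
             "co": 0.80, "alkanes": 0.15},
            rise_rate=0.012, delay=25.0, conc_scale=80.0,
        ),
        _profile(
            "S10", "TGS2600",
            {"ethanol", "hydrogen", "co", "alkanes"},
            1.0, 30.0, "ppm",
            {"ethanol": 0.22, "hydrogen": 0.12, "co": 0.85, "alkanes": 0.18},
            rise_rate=0.013, delay=24.0, conc_scale=80.0,
        ),
    ]


#: Planted high-similarity groups the optimization pipeline should rediscover.
REDUNDANT_GROUPS = (("S3", "S7", "S8"), ("S9", "S10"))
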