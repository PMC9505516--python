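"""Electrode arrays and pulse-delivery protocols.

Three applicator geometries are supported:

``hex6``
    Six rod electrodes on a regular hexagon, no central electrode
    (opposite-center distance 9 mm, adjacent edge-to-edge gap 2.5 mm).
``hex7``
    The same hexagon plus a central electrode (the classical applicator).
``mea6``
    Six spring-loaded pins on a regular hexagon at 3.5 mm center-to-center
    spacing (the noninvasive multi-electrode array used with low-voltage,
    long pulses).

A protocol is an ordered list of anode/cathode activation steps sharing one
pulse-train parameter set.  Every electrode pair a protocol uses appears
twice, once per polarity ("first in one direction and then with reversed
polarity").  The ``classical`` protocol pulses between all adjacent pairs
including the center; the ``alternative`` protocol pulses around the rim and
then across the three diagonals, compensating for the missing central pin;
``mea_lv`` pulses around the rim only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

from .units import MM

__all__ = [
    "Electrode",
    "ElectrodeArray",
    "ProtocolStep",
    "PulseTrain",
    "Protocol",
    "DeviceEnvelope",
    "Violation",
    "build_array",
    "generate_protocol",
    "default_train",
    "validate_against_device",
    "classify_contact_impedance",
]

Arrangement = Literal["hex6", "hex7", "mea6"]
ProtocolName = Literal["classical", "alternative", "mea_lv"]

#: hex applicator: distance between the centers of opposite electrodes (m)
HEX_OPPOSITE_DISTANCE = 9.0 * MM
#: hex applicator: rod contact radius (m) — the value for which the adjacent
#: edge-to-edge gap equals 2.5 mm on a 4.5 mm-circumradius hexagon
HEX_CONTACT_RADIUS = 1.0 * MM
#: MEA: center-to-center pin spacing (m)
MEA_SPACING = 3.5 * MM
#: MEA: default pin contact radius (m)
MEA_CONTACT_RADIUS = 0.35 * MM

CENTER_ID = 0
RIM_IDS = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class Electrode:
    id: int
    center: tuple[float, float]
    contact_radius: float

    def __post_init__(self) -> None:
        if self.contact_radius <= 0:
            raise ValueError("contact_radius must be > 0")


@dataclass(frozen=True)
class ElectrodeArray:
    electrodes: tuple[Electrode, ...]
    arrangement: Arrangement
    adjacency: tuple[tuple[int, int], ...]
    opposite_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        ids = [e.id for e in self.electrodes]
        if len(set(ids)) != len(ids):
            raise ValueError("electrode ids must be unique")
        for (i, j) in self.adjacency:
            if i == j or i not in ids or j not in ids:
                raise ValueError(f"bad adjacency pair ({i}, {j})")
        by_id = {e.id: e for e in self.electrodes}
        for a in self.electrodes:
            for b in self.electrodes:
                if a.id < b.id:
                    d = math.dist(a.center, b.center)
                    if d < a.contact_radius + b.contact_radius:
                        raise ValueError(
                            f"contact discs of electrodes {a.id} and {b.id} overlap"
                        )

    def __getitem__(self, eid: int) -> Electrode:
        for e in self.electrodes:
            if e.id == eid:
                return e
        raise KeyError(eid)

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(e.id for e in self.electrodes)

    def footprint_radius(self) -> float:
        """Radius of the smallest origin-centred circle containing all
        contact discs."""
        return max(
            math.hypot(*e.center) + e.contact_radius for e in self.electrodes
        )


@dataclass(frozen=True)
class ProtocolStep:
    """One activation: ``amplitude`` volts on the anodes, 0 V on the cathodes."""

    anodes: frozenset[int]
    cathodes: frozenset[int]
    amplitude: float

    def __post_init__(self) -> None:
        if not self.anodes or not self.cathodes:
            raise ValueError("anodes and cathodes must both be non-empty")
        if self.anodes & self.cathodes:
            raise ValueError("anodes and cathodes must be disjoint")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def reversed(self) -> "ProtocolStep":
        return ProtocolStep(self.cathodes, self.anodes, self.amplitude)

    def is_reversal_of(self, other: "ProtocolStep") -> bool:
        return (
            self.anodes == other.cathodes
            and self.cathodes == other.anodes
            and self.amplitude == other.amplitude
        )


@dataclass(frozen=True)
class PulseTrain:
    """Pulse-train parameters of one activation step.

    Ap: pulse amplitude (V); Tp: single-pulse duration (s); NrP: pulses per
    burst; NrB: bursts; PRR: pulse repetition rate within a burst (Hz);
    BRR: burst repetition rate (Hz).
    """

    Ap: float
    Tp: float
    NrP: int
    PRR: float
    NrB: int = 1
    BRR: float | None = None

    def __post_init__(self) -> None:
        if self.NrP < 1 or self.NrB < 1:
            raise ValueError("NrP and NrB must be ≥ 1")
        if self.Tp > 1.0 / self.PRR:
            raise ValueError("pulse duration exceeds the pulse period 1/PRR")
        if self.NrB > 1:
            if self.BRR is None:
                raise ValueError("BRR required when NrB > 1")
            if self.NrP / self.PRR > 1.0 / self.BRR:
                raise ValueError("burst longer than the burst period 1/BRR")


@dataclass(frozen=True)
class Protocol:
    steps: tuple[ProtocolStep, ...]
    train: PulseTrain
    name: str

    def __post_init__(self) -> None:
        # every anode/cathode assignment must appear once with each polarity
        seen = {}
        for s in self.steps:
            key = (s.anodes, s.cathodes, s.amplitude)
            seen[key] = seen.get(key, 0) + 1
        for (an, ca, amp), n in seen.items():
            rev = (ca, an, amp)
            if n != 1 or seen.get(rev, 0) != 1:
                raise ValueError(
                    "each anode/cathode assignment must appear exactly once "
                    "per polarity"
                )

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def electrode_ids(self) -> frozenset[int]:
        out: frozenset[int] = frozenset()
        for s in self.steps:
            out |= s.anodes | s.cathodes
        return out

    def total_pulses(self) -> int:
        return len(self.steps) * self.train.NrP * self.train.NrB

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "train": {
                    "Ap": self.train.Ap,
                    "Tp": self.train.Tp,
                    "NrP": self.train.NrP,
                    "PRR": self.train.PRR,
                    "NrB": self.train.NrB,
                    "BRR": self.train.BRR,
                },
                "steps": [
                    {
                        "anodes": sorted(s.anodes),
                        "cathodes": sorted(s.cathodes),
                        "amplitude": s.amplitude,
                    }
                    for s in self.steps
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Protocol":
        d = json.loads(text)
        t = d["train"]
        train = PulseTrain(
            Ap=t["Ap"], Tp=t["Tp"], NrP=t["NrP"], PRR=t["PRR"],
            NrB=t.get("NrB", 1), BRR=t.get("BRR"),
        )
        steps = tuple(
            ProtocolStep(
                frozenset(s["anodes"]), frozenset(s["cathodes"]), s["amplitude"]
            )
            for s in d["steps"]
        )
        return cls(steps=steps, train=train, name=d["name"])


def _hex_positions(circumradius: float) -> list[tuple[float, float]]:
    """Rim positions 1..6, clockwise starting from the top vertex."""
    out = []
    for k in range(6):
        theta = math.pi / 2 - k * math.pi / 3
        out.append((circumradius * math.cos(theta), circumradius * math.sin(theta)))
    return out


def build_array(
    arrangement: Arrangement,
    *,
    circumradius: float | None = None,
    contact_radius: float | None = None,
) -> ElectrodeArray:
    """Build an electrode array of the given arrangement.

    Defaults: hex6/hex7 circumradius 4.5 mm (half the 9 mm opposite-center
    distance) with 1.0 mm rod contact radius, so the adjacent edge-to-edge
    gap is 4.5 − 2 × 1.0 = 2.5 mm; mea6 center-to-center 3.5 mm with 0.35 mm
    pin radius.  Overrides that make neighbouring contact discs overlap
    raise a ``ValueError``.
    """
    if arrangement not in ("hex6", "hex7", "mea6"):
        raise ValueError(f"unknown arrangement {arrangement!r}")
    if arrangement == "mea6":
        R = MEA_SPACING if circumradius is None else circumradius
        r = MEA_CONTACT_RADIUS if contact_radius is None else contact_radius
    else:
        R = HEX_OPPOSITE_DISTANCE / 2 if circumradius is None else circumradius
        r = HEX_CONTACT_RADIUS if contact_radius is None else contact_radius
    electrodes = [
        Electrode(i + 1, pos, r) for i, pos in enumerate(_hex_positions(R))
    ]
    adjacency = [(1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 1)]
    opposite = [(1, 4), (2, 5), (3, 6)]
    if arrangement == "hex7":
        electrodes.append(Electrode(CENTER_ID, (0.0, 0.0), r))
        adjacency += [(i, CENTER_ID) for i in RIM_IDS]
    return ElectrodeArray(
        electrodes=tuple(electrodes),
        arrangement=arrangement,
        adjacency=tuple(adjacency),
        opposite_pairs=tuple(opposite) if arrangement != "mea6" else (),
    )


def default_train(name: ProtocolName) -> PulseTrain:
    """Default pulse-train parameters per protocol.

    The hex protocols deliver, per activation step, a burst of 4 × 100 µs
    pulses at 5 kHz, 560 V, with successive bursts at 50 Hz; the MEA
    low-voltage protocol delivers one 150 ms, 60 V pulse per step at a
    2.82 Hz repetition rate.
    """
    if name in ("classical", "alternative"):
        return PulseTrain(Ap=560.0, Tp=100e-6, NrP=4, PRR=5000.0, NrB=1, BRR=50.0)
    if name == "mea_lv":
        return PulseTrain(Ap=60.0, Tp=150e-3, NrP=1, PRR=2.82)
    raise ValueError(f"unknown protocol name {name!r}")


def generate_protocol(
    array: ElectrodeArray,
    name: ProtocolName,
    amplitude: float | None = None,
    *,
    diagonal_mode: Literal["single", "paired"] = "paired",
    train: PulseTrain | None = None,
) -> Protocol:
    """Generate a pulse-delivery protocol on ``array``.

    classical (hex7): every adjacent pair — six rim-rim then six rim-center —
    each immediately followed by its polarity reversal (24 steps).
    alternative (hex6): the six rim pairs with polarity reversal, then six
    cross-array steps with polarity reversal (18 steps): pulses between two
    opposite pairs of electrodes, i.e. a pair of adjacent rim electrodes
    energised against the diametrically opposite pair (``paired``, the
    default).  ``diagonal_mode="single"`` instead pulses across the three
    single-electrode diagonals; both readings give 6 steps, but only the
    paired one compensates for the missing central pin strongly enough to
    enlarge the reversibly electroporated volume.
    mea_lv (mea6): the six rim pairs with polarity reversal (12 steps).
    """
    required = {"classical": "hex7", "alternative": "hex6", "mea_lv": "mea6"}
    if name not in required:
        raise ValueError(f"unknown protocol name {name!r}")
    if array.arrangement != required[name]:
        raise ValueError(
            f"protocol {name!r} requires a {required[name]} array, "
            f"got {array.arrangement!r}"
        )
    if train is None:
        train = default_train(name)
    amp = train.Ap if amplitude is None else float(amplitude)

    rim_pairs = [(1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 1)]
    steps: list[ProtocolStep] = []

    def add(anodes: Sequence[int], cathodes: Sequence[int]) -> None:
        s = ProtocolStep(frozenset(anodes), frozenset(cathodes), amp)
        steps.append(s)
        steps.append(s.reversed())

    for (a, b) in rim_pairs:
        add([a], [b])
    if name == "classical":
        for i in RIM_IDS:
            add([i], [CENTER_ID])
    elif name == "alternative":
        if diagonal_mode == "single":
            for (a, b) in [(1, 4), (2, 5), (3, 6)]:
                add([a], [b])
        elif diagonal_mode == "paired":
            for (an, ca) in [((1, 2), (4, 5)), ((2, 3), (5, 6)), ((3, 4), (6, 1))]:
                add(an, ca)
        else:
            raise ValueError(f"unknown diagonal_mode {diagonal_mode!r}")
    if amplitude is not None and amplitude != train.Ap:
        train = replace(train, Ap=amp)
    return Protocol(steps=tuple(steps), train=train, name=name)


@dataclass(frozen=True)
class DeviceEnvelope:
    """Operating envelope of the pulse generator (inclusive bounds)."""

    amplitude_v: tuple[float, float] = (80.0, 600.0)
    duration_s: tuple[float, float] = (10e-6, 1000e-6)
    prr_hz: tuple[float, float] = (0.1, 5000.0)


@dataclass(frozen=True)
class Violation:
    parameter: str
    value: float
    low: float
    high: float

    def __str__(self) -> str:
        return (
            f"{self.parameter} = {self.value:g} outside "
            f"[{self.low:g}, {self.high:g}]"
        )


def validate_against_device(
    train: PulseTrain, envelope: DeviceEnvelope = DeviceEnvelope()
) -> list[Violation]:
    """Check a pulse train against the generator's operating envelope.

    Returns one violation record per breached bound; an empty list means
    the train is deliverable.  Boundary values pass (bounds inclusive).
    """
    checks = [
        ("amplitude", train.Ap, envelope.amplitude_v),
        ("pulse_duration", train.Tp, envelope.duration_s),
        ("pulse_repetition_rate", train.PRR, envelope.prr_hz),
    ]
    return [
        Violation(name, value, lo, hi)
        for name, value, (lo, hi) in checks
        if not (lo <= value <= hi)
    ]


def classify_contact_impedance(
    z: float, bounds: tuple[float, float] = (100.0, 10_000.0)
) -> Literal["too_low", "contact", "too_high"]:
    """Classify an inter-electrode impedance into the three ranges the
    skin-contact detector distinguishes: below ``bounds[0]`` (short, no skin
    contact), within the bounds (electrodes in contact with skin), above
    ``bounds[1]`` (open / poor contact)."""
    low, high = bounds
    if z < 0:
        raise ValueError("impedance must be non-negative")
    if not low < high:
        raise ValueError("bounds must satisfy low < high")
    if z < low:
        return "too_low"
    if z <= high:
        return "contact"
    return "too_high"
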