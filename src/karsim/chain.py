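"""Data model for a chain of membrane compartments under kiss-and-run dynamics.

The secretory pathway is represented as an ordered chain of compartments
(ER at the proximal end, a post-Golgi compartment at the distal end), each
holding a nonnegative amount of a protein in arbitrary "conditional units".
Transport proceeds in discrete rounds: in every round a fixed set of
disjoint adjacent pairs transiently fuses, the joint content of each pair is
redistributed in an uneven ratio (the distal member of an anterograde pair
ends up with twice the proximal one), and the pair separates again. Two
alternating pairings tile the chain so that every junction is visited every
other round.

This module defines the configuration objects (chain, pairing schedule,
redistribution and direction rules, source clamp, departure rule), the
:class:`Trajectory` result container, validation, and the two canonical
worked scenarios: a soluble-cargo wave entering an empty Golgi, and a
resident-enzyme chain with an inverted gradient beyond the fourth medial
cisterna.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Mode",
    "Orientation",
    "CompartmentChain",
    "PairingSchedule",
    "RedistributionRule",
    "DirectionProfile",
    "SourceClamp",
    "DepartureRule",
    "DepartureEvent",
    "SimulationConfig",
    "Trajectory",
    "build_table1_config",
    "build_table2_config",
    "validate_config",
]

Mode = Literal["integer", "real"]
Orientation = Literal["anterograde", "retrograde"]


@dataclass
class CompartmentChain:
    """Ordered compartments with nonnegative contents in conditional units.

    ``baseline`` is the reference amount used for fold-enrichment
    computations (the ER steady-state content, 10 conditional units in the
    canonical scenarios).
    """

    labels: tuple[str, ...]
    contents: np.ndarray
    baseline: float = 10.0

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.contents = np.asarray(self.contents, dtype=float).copy()

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __getitem__(self, label: str) -> float:
        return float(self.contents[self.index(label)])

    def copy(self) -> "CompartmentChain":
        return CompartmentChain(self.labels, self.contents.copy(), self.baseline)


@dataclass(frozen=True)
class PairingSchedule:
    """Cyclic phases, each a set of disjoint pairs of adjacent chain positions.

    Round ``k`` (1-based) uses phase ``(k - 1) mod period``.
    """

    phases: tuple[tuple[tuple[int, int], ...], ...]

    @property
    def period(self) -> int:
        return len(self.phases)

    def phase_for_round(self, round_number: int) -> tuple[tuple[int, int], ...]:
        if round_number < 1:
            raise ValueError("rounds are 1-based")
        return self.phases[(round_number - 1) % self.period]


@dataclass(frozen=True)
class RedistributionRule:
    """The uneven split applied to a fused pair.

    ``ratio`` is the enriched-to-depleted ratio r: a pair holding total T
    separates into T/(1+r) on the depleted side and r·T/(1+r) on the
    enriched side. With ``rounding='nearest'`` (integer mode) the depleted
    side is rounded to the nearest integer, half away from zero, and the
    enriched side takes the remainder so the pair total is conserved
    exactly.
    """

    ratio: float = 2.0
    rounding: Literal["nearest", "none"] = "nearest"

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")


@dataclass(frozen=True)
class DirectionProfile:
    """Which member of each fused pair ends up enriched.

    A pair whose distal member sits at or before ``inversion_index`` is
    anterograde (distal member enriched); any pair beyond is retrograde
    (proximal member enriched). ``inversion_index=None`` makes the whole
    chain anterograde. The inversion models a reversal of the ionic-pump
    gradient in the distal Golgi.
    """

    inversion_index: int | None = None

    def orientation(self, pair: tuple[int, int]) -> Orientation:
        distal = max(pair)
        if self.inversion_index is None or distal <= self.inversion_index:
            return "anterograde"
        return "retrograde"


@dataclass(frozen=True)
class SourceClamp:
    """Constant-synthesis boundary condition.

    The source compartment (the ER) is held at ``clamp_value`` conditional
    units; whenever it fuses with a partner the partner is set to
    r × clamp_value, as if the source were an infinite reservoir.
    """

    source_index: int
    clamp_value: float = 10.0

    def __post_init__(self) -> None:
        if self.clamp_value < 0:
            raise ValueError("clamp_value must be nonnegative")


@dataclass(frozen=True)
class DepartureRule:
    """Threshold-triggered emptying of the terminal compartment.

    Checked once after each completed round: if the terminal content is
    strictly greater than ``threshold_fold`` times the baseline, the
    compartment departs. ``remove_all`` empties it; ``remove_half`` halves
    it (nearest integer in integer mode). Every departure is logged.
    """

    terminal_index: int
    threshold_fold: float = 5.0
    action: Literal["remove_all", "remove_half"] = "remove_all"

    def __post_init__(self) -> None:
        if self.threshold_fold <= 0:
            raise ValueError("threshold_fold must be positive")


@dataclass(frozen=True)
class DepartureEvent:
    round: int
    amount: float


@dataclass
class SimulationConfig:
    """Complete description of one deterministic simulation."""

    labels: tuple[str, ...]
    initial: np.ndarray
    schedule: PairingSchedule
    rule: RedistributionRule = field(default_factory=RedistributionRule)
    direction: DirectionProfile = field(default_factory=DirectionProfile)
    clamps: tuple[SourceClamp, ...] = ()
    departure: DepartureRule | None = None
    n_rounds: int = 0
    mode: Mode = "integer"
    baseline: float = 10.0

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.initial = np.asarray(self.initial, dtype=float).copy()

    # -- convenience -------------------------------------------------------

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def initial_chain(self) -> CompartmentChain:
        return CompartmentChain(self.labels, self.initial, self.baseline)

    def with_rounds(self, n_rounds: int) -> "SimulationConfig":
        return replace(self, n_rounds=n_rounds)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "compartments": list(self.labels),
            "initial": [float(x) for x in self.initial],
            "phases": [
                [[self.labels[i], self.labels[j]] for i, j in phase]
                for phase in self.schedule.phases
            ],
            "ratio": self.rule.ratio,
            "inversion_after": (
                None
                if self.direction.inversion_index is None
                else self.labels[self.direction.inversion_index]
            ),
            "clamps": [
                {"compartment": self.labels[c.source_index], "value": c.clamp_value}
                for c in self.clamps
            ],
            "departure": (
                None
                if self.departure is None
                else {
                    "compartment": self.labels[self.departure.terminal_index],
                    "threshold_fold": self.departure.threshold_fold,
                    "action": self.departure.action,
                }
            ),
            "rounds": self.n_rounds,
            "mode": self.mode,
            "baseline": self.baseline,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        labels = tuple(d["compartments"])
        idx = {lab: i for i, lab in enumerate(labels)}

        def _resolve(name) -> int:
            if name not in idx:
                raise KeyError(f"unknown compartment {name!r}")
            return idx[name]

        phases = tuple(
            tuple((_resolve(a), _resolve(b)) for a, b in phase)
            for phase in d["phases"]
        )
        dep = d.get("departure")
        departure = (
            None
            if dep is None
            else DepartureRule(
                terminal_index=_resolve(dep["compartment"]),
                threshold_fold=float(dep.get("threshold_fold", 5.0)),
                action=dep.get("action", "remove_all"),
            )
        )
        inv = d.get("inversion_after")
        return cls(
            labels=labels,
            initial=np.asarray(d["initial"], dtype=float),
            schedule=PairingSchedule(phases),
            rule=RedistributionRule(
                ratio=float(d.get("ratio", 2.0)),
                rounding="nearest" if d.get("mode", "integer") == "integer" else "none",
            ),
            direction=DirectionProfile(None if inv is None else _resolve(inv)),
            clamps=tuple(
                SourceClamp(_resolve(c["compartment"]), float(c["value"]))
                for c in d.get("clamps", [])
            ),
            departure=departure,
            n_rounds=int(d.get("rounds", 0)),
            mode=d.get("mode", "integer"),
            baseline=float(d.get("baseline", 10.0)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class Trajectory:
    """Per-round state matrix plus departure-event and influx logs.

    ``states`` has shape (n_rounds + 1, n_compartments); row 0 is the
    initial state and row k the state after round k. ``influx[k]`` is the
    net amount injected into the non-source system by source clamps during
    round k (index 0 is always 0).
    """

    labels: tuple[str, ...]
    states: np.ndarray
    events: list[DepartureEvent] = field(default_factory=list)
    influx: np.ndarray | None = None
    baseline: float = 10.0
    mode: Mode = "integer"
    clamped: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.states = np.asarray(self.states, dtype=float)
        if self.influx is None:
            self.influx = np.zeros(self.n_rounds + 1)
        else:
            self.influx = np.asarray(self.influx, dtype=float)

    @property
    def n_rounds(self) -> int:
        return self.states.shape[0] - 1

    def state(self, round_number: int) -> CompartmentChain:
        """Chain state after ``round_number`` completed rounds (0 = initial)."""
        return CompartmentChain(self.labels, self.states[round_number], self.baseline)

    def final_state(self) -> CompartmentChain:
        return self.state(self.n_rounds)

    def cell(self, round_number: int, label: str) -> float:
        return float(self.states[round_number, self.labels.index(label)])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(self.labels))
        df.insert(0, "round", np.arange(self.states.shape[0]))
        if self.mode == "integer":
            for lab in self.labels:
                df[lab] = df[lab].astype(int)
        return df


# ---------------------------------------------------------------------------
# Canonical worked scenarios
# ---------------------------------------------------------------------------

#: Compartments of the soluble-cargo scenario (worked table 1).
TABLE1_LABELS = ("ER", "IC", "cis", "med1", "med2", "med3", "med4", "TGN", "PGC")
#: Compartments of the resident-enzyme scenario (worked table 2).
TABLE2_LABELS = ("ER", "cis", "med1", "med2", "med3", "med4", "med5", "TGN", "PGC")


def build_table1_config(n_rounds: int = 48) -> SimulationConfig:
    """Canonical soluble-cargo configuration.

    Nine compartments ER → PGC with the ER clamped at 10 conditional units
    and everything else initially empty. Phase 1 fuses ER–IC, cis–med1,
    med2–med3 and med4–TGN; phase 2 fuses IC–cis, med1–med2, med3–med4 and
    TGN–PGC. All pairs are anterograde with a 1:2 split, integer rounding,
    and the PGC departs (is emptied) whenever its content exceeds 5-fold
    the 10-unit baseline.
    """
    labels = TABLE1_LABELS
    initial = np.zeros(9)
    initial[0] = 10.0
    schedule = PairingSchedule(
        (
            ((0, 1), (2, 3), (4, 5), (6, 7)),
            ((1, 2), (3, 4), (5, 6), (7, 8)),
        )
    )
    return SimulationConfig(
        labels=labels,
        initial=initial,
        schedule=schedule,
        rule=RedistributionRule(ratio=2.0, rounding="nearest"),
        direction=DirectionProfile(None),
        clamps=(SourceClamp(source_index=0, clamp_value=10.0),),
        departure=DepartureRule(terminal_index=8, threshold_fold=5.0, action="remove_all"),
        n_rounds=n_rounds,
        mode="integer",
        baseline=10.0,
    )


def build_table2_config(n_rounds: int = 23) -> SimulationConfig:
    """Canonical resident-enzyme configuration.

    Nine compartments ER, cis, med1–med5, TGN, PGC, all starting at 10
    conditional units (a Golgi pre-loaded with its glycosylation enzymes).
    Phase 1 fuses ER–cis, med1–med2, med3–med4 and med5–TGN; phase 2 fuses
    cis–med1, med2–med3, med4–med5 and TGN–PGC. Pairs whose distal member
    is med4 or proximal to it are anterograde; beyond med4 the pump
    gradient is inverted, so med4–med5, med5–TGN and TGN–PGC enrich their
    proximal member. ER clamped at 10; no departure rule.
    """
    labels = TABLE2_LABELS
    schedule = PairingSchedule(
        (
            ((0, 1), (2, 3), (4, 5), (6, 7)),
            ((1, 2), (3, 4), (5, 6), (7, 8)),
        )
    )
    return SimulationConfig(
        labels=labels,
        initial=np.full(9, 10.0),
        schedule=schedule,
        rule=RedistributionRule(ratio=2.0, rounding="nearest"),
        direction=DirectionProfile(inversion_index=labels.index("med4")),
        clamps=(SourceClamp(source_index=0, clamp_value=10.0),),
        departure=None,
        n_rounds=n_rounds,
        mode="integer",
        baseline=10.0,
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_config(config: SimulationConfig) -> list[str]:
    """Check every structural invariant; return a list of violations.

    An empty list means the configuration can be simulated. Violations are
    human-readable strings naming the offending field and rule; nothing is
    raised.
    """
    v: list[str] = []
    n = len(config.labels)

    if len(set(config.labels)) != n:
        v.append("labels: compartment labels must be unique")
    if len(config.initial) != n:
        v.append("initial: length must equal number of compartments")
    if np.any(config.initial < 0):
        v.append("initial: contents must be nonnegative")
    if config.mode == "integer" and not np.allclose(config.initial, np.round(config.initial)):
        v.append("initial: integer mode requires integer contents")
    if config.baseline <= 0:
        v.append("baseline: must be positive")
    if config.rule.ratio <= 0:
        v.append("rule.ratio: must be positive")
    if config.n_rounds < 0:
        v.append("n_rounds: must be nonnegative")

    if config.schedule.period == 0:
        v.append("schedule: at least one phase required")
    for p, phase in enumerate(config.schedule.phases, start=1):
        seen: set[int] = set()
        for i, j in phase:
            if not (0 <= i < n and 0 <= j < n):
                v.append(f"schedule phase {p}: pair ({i}, {j}) out of range")
                continue
            if abs(i - j) != 1:
                v.append(
                    f"schedule phase {p}: pair ({config.labels[i]}, {config.labels[j]})"
                    " is not adjacent in the chain"
                )
            overlap = seen & {i, j}
            if overlap:
                labs = ", ".join(config.labels[k] for k in sorted(overlap))
                v.append(
                    f"schedule phase {p}: pairs are not disjoint"
                    f" (compartment {labs} appears in two pairs)"
                )
            seen |= {i, j}

    inv = config.direction.inversion_index
    if inv is not None and not (0 <= inv < n):
        v.append("direction.inversion_index: not a valid chain position")

    for c in config.clamps:
        if not (0 <= c.source_index < n):
            v.append("clamp.source_index: not a valid chain position")
        if c.clamp_value < 0:
            v.append("clamp.clamp_value: must be nonnegative")

    if config.departure is not None:
        if not (0 <= config.departure.terminal_index < n):
            v.append("departure.terminal_index: not a valid chain position")
        if config.departure.threshold_fold <= 0:
            v.append("departure.threshold_fold: must be positive")

    return v
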