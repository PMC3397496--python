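"""Deterministic kiss-and-run update dynamics.

One simulation round applies one phase of the pairing schedule: every fused
pair pools its content and separates it again unevenly, with the enriched
member taking r times the depleted member's share (r = 2 by default). In
integer mode the depleted side is rounded to the nearest integer and the
enriched side takes the remainder, so each pair's total is conserved
exactly. A clamped source compartment (the ER) is the one exception to
conservation: it is an infinite reservoir held at its clamp value, and its
fusion partner is set to r times that value. After each round an optional
departure rule may empty the terminal compartment once its content exceeds
a fold threshold.

There is no randomness anywhere: trajectories are fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .chain import (
    CompartmentChain,
    DepartureEvent,
    DepartureRule,
    DirectionProfile,
    Mode,
    Orientation,
    RedistributionRule,
    SimulationConfig,
    SourceClamp,
    Trajectory,
    validate_config,
)

__all__ = [
    "PairOutcome",
    "ConfigError",
    "redistribute_pair",
    "apply_source_clamp",
    "apply_phase",
    "check_departure",
    "run",
]


class ConfigError(ValueError):
    """Raised by :func:`run` when a configuration fails validation."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n" + "\n".join(f"- {v}" for v in violations))


@dataclass(frozen=True)
class PairOutcome:
    """Result of redistributing one fused pair."""

    proximal_amount: float
    distal_amount: float
    orientation: Orientation

    @property
    def total(self) -> float:
        return self.proximal_amount + self.distal_amount


def _round_half_away(x: float) -> float:
    # half away from zero; x >= 0 throughout the model
    return math.floor(x + 0.5)


def redistribute_pair(
    total: float,
    orientation: Orientation,
    rule: RedistributionRule,
    mode: Mode = "integer",
) -> PairOutcome:
    """Split a fused pair's pooled content ``total`` in the ratio 1 : r.

    The depleted side receives total / (1 + r); in integer mode it is
    rounded to the nearest integer (half away from zero — for r = 2 the
    fraction of total/3 is never exactly one half, so no ties arise) and
    the enriched side takes the exact remainder. An anterograde pair
    enriches its distal member, a retrograde pair its proximal member.
    """
    if total < 0:
        raise ValueError(f"pair total must be nonnegative, got {total}")
    r = rule.ratio
    depleted = total / (1.0 + r)
    if mode == "integer" and rule.rounding == "nearest":
        depleted = _round_half_away(depleted)
    enriched = total - depleted
    if orientation == "anterograde":
        return PairOutcome(proximal_amount=depleted, distal_amount=enriched, orientation=orientation)
    return PairOutcome(proximal_amount=enriched, distal_amount=depleted, orientation=orientation)


def apply_source_clamp(
    clamp: SourceClamp,
    pair: tuple[int, int],
    rule: RedistributionRule,
    mode: Mode = "integer",
) -> tuple[float, float]:
    """Resolve a fusion involving a clamped source compartment.

    The source is an infinite reservoir: it is reset to its clamp value and
    the partner is set to r × clamp_value regardless of the partner's prior
    content (the pair is deliberately non-conserving). Returns the new
    (source, partner) contents.
    """
    if clamp.source_index not in pair:
        raise ValueError("pair does not contain the clamped source compartment")
    partner_amount = rule.ratio * clamp.clamp_value
    if mode == "integer" and rule.rounding == "nearest":
        partner_amount = _round_half_away(partner_amount)
    return clamp.clamp_value, partner_amount


def apply_phase(
    state: CompartmentChain,
    phase: Sequence[tuple[int, int]],
    rule: RedistributionRule,
    direction: DirectionProfile,
    clamps: Iterable[SourceClamp] = (),
    mode: Mode = "integer",
) -> CompartmentChain:
    """Apply one phase of pairwise fusion/fission to a chain state.

    Pairs are disjoint, so each is redistributed independently and the
    result does not depend on iteration order. Unpaired compartments are
    untouched. Pairs containing a clamped source use the clamp rule instead
    of conserving redistribution.
    """
    new = state.copy()
    clamp_by_index = {c.source_index: c for c in clamps}
    for i, j in phase:
        prox, dist = (i, j) if i < j else (j, i)
        clamp = clamp_by_index.get(prox) or clamp_by_index.get(dist)
        if clamp is not None:
            source = clamp.source_index
            partner = dist if source == prox else prox
            src_val, partner_val = apply_source_clamp(clamp, (prox, dist), rule, mode)
            new.contents[source] = src_val
            new.contents[partner] = partner_val
        else:
            total = float(state.contents[prox] + state.contents[dist])
            out = redistribute_pair(total, direction.orientation((prox, dist)), rule, mode)
            new.contents[prox] = out.proximal_amount
            new.contents[dist] = out.distal_amount
    return new


def check_departure(
    state: CompartmentChain,
    rule: DepartureRule | None,
    round_number: int,
    mode: Mode = "integer",
) -> tuple[CompartmentChain, DepartureEvent | None]:
    """Trigger a terminal-compartment departure if its fold threshold is exceeded.

    The comparison is strict: content exactly at threshold_fold × baseline
    does not depart. ``remove_all`` empties the compartment; ``remove_half``
    leaves the rounded half behind. The removed amount is returned as an
    event, or None if nothing departed.
    """
    if rule is None:
        return state, None
    content = float(state.contents[rule.terminal_index])
    if content <= rule.threshold_fold * state.baseline:
        return state, None
    new = state.copy()
    if rule.action == "remove_all":
        remaining = 0.0
    else:  # remove_half
        remaining = content / 2.0
        if mode == "integer":
            remaining = _round_half_away(remaining)
    new.contents[rule.terminal_index] = remaining
    return new, DepartureEvent(round=round_number, amount=content - remaining)


def run(config: SimulationConfig, n_rounds: int | None = None) -> Trajectory:
    """Simulate a configuration for ``n_rounds`` rounds (default: config's).

    Row 0 of the returned trajectory is the initial state; row k is the
    state after applying the phase of round k and then the departure check.
    Net clamp influx into the non-source system is logged per round so that
    mass-balance accounting (system total + departed − influx) is possible
    downstream.
    """
    violations = validate_config(config)
    if violations:
        raise ConfigError(violations)
    if n_rounds is None:
        n_rounds = config.n_rounds

    state = config.initial_chain()
    n = len(state)
    source_indices = {c.source_index for c in config.clamps}
    system = [i for i in range(n) if i not in source_indices]

    states = np.empty((n_rounds + 1, n))
    states[0] = state.contents
    influx = np.zeros(n_rounds + 1)
    events: list[DepartureEvent] = []

    for k in range(1, n_rounds + 1):
        phase = config.schedule.phase_for_round(k)
        before = state.contents[system].sum()
        state = apply_phase(state, phase, config.rule, config.direction, config.clamps, config.mode)
        influx[k] = state.contents[system].sum() - before
        state, event = check_departure(state, config.departure, k, config.mode)
        if event is not None:
            events.append(event)
        states[k] = state.contents

    return Trajectory(
        labels=config.labels,
        states=states,
        events=events,
        influx=influx,
        baseline=config.baseline,
        mode=config.mode,
        clamped=tuple(sorted(source_indices)),
    )
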