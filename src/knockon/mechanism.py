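"""Soft vs direct knock-on classification of permeation events.

A permeation is *soft* knock-on when, throughout the event's transit
window, the ions in the filter are always separated by water (every frame
with two or more ions in S1..S4 shows a W between each adjacent ion pair).
It is *direct* knock-on when at least one frame shows two ions with no
intervening water — adjacent sites, or separated only by a vacancy: a
vacancy leaves the ion-ion Coulomb repulsion unscreened by water, so it
counts as direct contact (declared rule). Events whose window never holds
two ions are unassigned.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .occupancy import StateSeries
from .permeation import PermeationEvent
from .trajio import ContractViolation

DIRECT, SOFT, UNASSIGNED = "direct", "soft", "unassigned"


def _frame_kind(code: str) -> str:
    """Classify one occupancy code: 'direct' / 'separated' / 'few'."""
    ions = [i for i, c in enumerate(code) if c == "K"]
    if len(ions) < 2:
        return "few"
    for a, b in zip(ions[:-1], ions[1:]):
        between = code[a + 1:b]
        if "W" not in between:
            return "direct"
    return "separated"


def classify_event(event: PermeationEvent, states: StateSeries) -> str:
    """Mechanism label for one event from the frame codes of its window."""
    if len(states) == 0 or states.times_ps[0] > event.t_entry_ps or \
            states.times_ps[-1] < event.t_exit_ps:
        raise ContractViolation(
            f"occupancy states do not cover event window "
            f"[{event.t_entry_ps}, {event.t_exit_ps}] ps")
    win = states.window(event.t_entry_ps, event.t_exit_ps)
    saw_multi = False
    for code in win.codes:
        kind = _frame_kind(str(code))
        if kind == "direct":
            return DIRECT
        if kind == "separated":
            saw_multi = True
    return SOFT if saw_multi else UNASSIGNED


@dataclass
class MechanismCensus:
    n_direct: int
    n_soft: int
    n_unassigned: int

    @property
    def n_assigned(self) -> int:
        return self.n_direct + self.n_soft

    @property
    def total(self) -> int:
        return self.n_assigned + self.n_unassigned

    @property
    def soft_pct(self) -> float:
        return 100.0 * self.n_soft / self.n_assigned

    @property
    def direct_pct(self) -> float:
        return 100.0 * self.n_direct / self.n_assigned

    def pct_2dp(self, which: str = "soft") -> float:
        """Percentage rounded half-up to 2 decimals (reporting convention)."""
        v = self.soft_pct if which == "soft" else self.direct_pct
        return float(Decimal(repr(v)).quantize(Decimal("0.01"),
                                               rounding=ROUND_HALF_UP))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# mechanism\tevents\tpercent_of_assigned\n")
            fh.write(f"direct\t{self.n_direct}\t{self.pct_2dp('direct'):.2f}\n")
            fh.write(f"soft\t{self.n_soft}\t{self.pct_2dp('soft'):.2f}\n")
            fh.write(f"unassigned\t{self.n_unassigned}\t-\n")


def mechanism_census(events: list[PermeationEvent], states: StateSeries,
                     directions: tuple = ("outward",)) -> MechanismCensus:
    """Classify every event (labels written back onto the events) and
    aggregate; percentages are over assigned events."""
    counts = {DIRECT: 0, SOFT: 0, UNASSIGNED: 0}
    for e in events:
        if e.direction not in directions:
            continue
        e.mechanism = classify_event(e, states)
        counts[e.mechanism] += 1
    cen = MechanismCensus(counts[DIRECT], counts[SOFT], counts[UNASSIGNED])
    if cen.n_assigned == 0:
        raise ContractViolation("no assigned events to aggregate")
    return cen


def write_events(events: list[PermeationEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("# ion_id\tt_entry_ns\tt_exit_ns\tdirection\tmechanism\n")
        for e in events:
            fh.write(f"{e.ion_id}\t{e.t_entry_ps / 1e3:.6f}\t"
                     f"{e.t_exit_ps / 1e3:.6f}\t{e.direction}\t"
                     f"{e.mechanism}\n")
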