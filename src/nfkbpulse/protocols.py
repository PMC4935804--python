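"""Stimulation protocols: timed cytokine pulses and the receptor-level signal.

A protocol is an ordered list of cytokine pulses (start time, duration, dose).
The receptor-level signal ``TR_X(t)`` for branch ``X`` (TNFα or IL-1β) is a
saturating Hill function of dose during a pulse and decays exponentially after
washout (cells are washed after each pulse; the decay time constant models
residual cytokine).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence


class Cytokine(str, Enum):
    TNF = "TNF"
    IL1 = "IL1"


#: default pulse used throughout: 5 min at 10 ng/ml
DEFAULT_DURATION = 5.0
DEFAULT_DOSE = 10.0


@dataclass(frozen=True)
class Pulse:
    start: float          # minutes
    duration: float = DEFAULT_DURATION
    cytokine: Cytokine = Cytokine.TNF
    dose: float = DEFAULT_DOSE   # ng/ml

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("pulse duration must be > 0")
        if self.dose < 0:
            raise ValueError("pulse dose must be >= 0")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class StimulationProtocol:
    """Ordered, per-cytokine non-overlapping cytokine pulses."""

    pulses: tuple[Pulse, ...] = ()
    t_end: float = 600.0

    def __post_init__(self) -> None:
        pulses = tuple(sorted(self.pulses, key=lambda p: p.start))
        object.__setattr__(self, "pulses", pulses)
        for cyt in Cytokine:
            mine = [p for p in pulses if p.cytokine == cyt]
            for a, b in zip(mine, mine[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping {cyt.value} pulses at t={a.start} and t={b.start}"
                    )
        if pulses and self.t_end < pulses[-1].end:
            raise ValueError("t_end must cover the last pulse")

    def pulses_of(self, cytokine: Cytokine) -> tuple[Pulse, ...]:
        return tuple(p for p in self.pulses if p.cytokine == cytokine)

    @property
    def pulse_starts(self) -> tuple[float, ...]:
        return tuple(p.start for p in self.pulses)

    def boundaries(self) -> list[float]:
        """Segment boundaries (pulse starts/ends) within [0, t_end]."""
        pts = {0.0, self.t_end}
        for p in self.pulses:
            pts.add(p.start)
            pts.add(min(p.end, self.t_end))
        return sorted(pts)


def two_pulse(delta: float, cytokines: str = "TT", *, dose: float = DEFAULT_DOSE,
              duration: float = DEFAULT_DURATION, tail: float = 300.0) -> StimulationProtocol:
    """Two 5-min pulses at interval ``delta``; ``cytokines`` like "TT", "TI", "IT"."""
    cyts = [Cytokine.TNF if c == "T" else Cytokine.IL1 for c in cytokines]
    pulses = (
        Pulse(0.0, duration, cyts[0], dose),
        Pulse(delta, duration, cyts[1], dose),
    )
    return StimulationProtocol(pulses, t_end=delta + tail)


def continuous(cytokine: Cytokine = Cytokine.TNF, *, dose: float = DEFAULT_DOSE,
               t_end: float = 800.0) -> StimulationProtocol:
    return StimulationProtocol((Pulse(0.0, t_end, cytokine, dose),), t_end=t_end)


_SHORTHAND = re.compile(r"^([TI])@(-?\d+(?:\.\d+)?)$")


def parse_protocol(spec: str, *, t_end: float | None = None,
                   dose: float = DEFAULT_DOSE,
                   duration: float = DEFAULT_DURATION) -> StimulationProtocol:
    """Parse shorthand like ``"T@0,T@60"`` or ``"T@0,I@50,T@100"``.

    Each token is a 5-min, 10 ng/ml pulse unless ``dose``/``duration`` override.
    ``t_end`` defaults to 300 min after the last pulse start.
    """
    pulses = []
    for token in spec.split(","):
        token = token.strip()
        m = _SHORTHAND.match(token)
        if not m:
            raise ValueError(f"cannot parse pulse token {token!r}")
        cyt = Cytokine.TNF if m.group(1) == "T" else Cytokine.IL1
        pulses.append(Pulse(float(m.group(2)), duration, cyt, dose))
    if t_end is None:
        t_end = (max(p.start for p in pulses) + 300.0) if pulses else 300.0
    return StimulationProtocol(tuple(pulses), t_end=t_end)


def dose_activation(dose: float, k_d: float, h_d: float = 1.0) -> float:
    """Saturating receptor occupancy φ(d) = d^h / (d^h + K_d^h)."""
    if dose <= 0:
        return 0.0
    return dose ** h_d / (dose ** h_d + k_d ** h_d)


def receptor_signal(protocol: StimulationProtocol, t: float, cytokine: Cytokine,
                    *, k_d: float, h_d: float = 1.0, tau_w: float = 2.0) -> float:
    """Dimensionless receptor signal in [0, 1] at time ``t`` for one branch.

    φ(dose) during a pulse of that cytokine; after the pulse ends the signal
    decays as exp(-(t - end)/τ_w); zero before any pulse.
    """
    if not isinstance(cytokine, Cytokine):
        raise ValueError(f"unknown cytokine {cytokine!r}")
    sig = 0.0
    for p in protocol.pulses_of(cytokine):
        if t < p.start:
            break
        phi = dose_activation(p.dose, k_d, h_d)
        if t <= p.end:
            sig = phi
        else:
            sig = max(sig, phi * math.exp(-(t - p.end) / tau_w))
    return sig
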