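"""Sonar ping scheduling and received-level / sound-exposure arithmetic.

Mid-frequency active sonar (MFAS) pings are transmitted on a fixed
repetition interval during the exposure phase.  Received level (RL) at the
focal group is modelled with parametric transmission loss (geometric
spreading plus linear absorption); per-ping sound exposure levels (SEL) are
energy-summed into a cumulative SEL (cSEL) for the whole exposure.  For
control CEEs no sound is transmitted, but "mock" received levels are
computed with the same machinery so that range-to-group patterns can be
compared across CEE types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: default simulated-MFAS source level, dB re 1 uPa @ 1 m (RMS)
SOURCE_LEVEL_SIM = 212.0
#: default operational (helicopter-dipped) MFAS source level
SOURCE_LEVEL_NAVY = 215.0
#: default ping repetition interval, s
PING_INTERVAL = 25.0
#: default ping duration, s
PING_DURATION = 1.6
#: default geometric spreading coefficient, dB per decade of range
SPREADING_DB_PER_DECADE = 20.0
#: default absorption at ~3.5 kHz, dB per km
ABSORPTION_DB_PER_KM = 0.25

CEE_TYPES = ("mfas_sim", "mfas_navy", "control")


@dataclass(frozen=True)
class Ping:
    """A single sonar ping as received at the focal group centre."""

    time: float  # s from CEE start
    range: float  # m, source to focal-group centre
    spl: float  # dB re 1 uPa (RMS)
    sel: float  # dB re 1 uPa^2 s
    duration: float = PING_DURATION  # s

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("ping duration must be positive")


@dataclass
class PingLog:
    """Ordered pings of one CEE plus source metadata.

    For control CEEs the pings are "mock": computed as if transmitted, and
    flagged ``transmitted = False``.
    """

    pings: list[Ping] = field(default_factory=list)
    source_level: float = SOURCE_LEVEL_SIM
    cee_type: str = "mfas_sim"

    def __post_init__(self) -> None:
        if self.cee_type not in CEE_TYPES:
            raise ValueError(
                f"unknown cee_type {self.cee_type!r}; expected one of {CEE_TYPES}"
            )
        times = [p.time for p in self.pings]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("ping times must be strictly increasing")

    @property
    def transmitted(self) -> bool:
        return self.cee_type != "control"

    def spls(self) -> np.ndarray:
        return np.array([p.spl for p in self.pings])

    def sels(self) -> np.ndarray:
        return np.array([p.sel for p in self.pings])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": [p.time for p in self.pings],
                "range_m": [p.range for p in self.pings],
                "spl_db": [p.spl for p in self.pings],
                "sel_db": [p.sel for p in self.pings],
                "transmitted": int(self.transmitted),
            }
        )


def ping_schedule(
    phase_start: float,
    phase_end: float,
    interval: float = PING_INTERVAL,
    duration: float = PING_DURATION,
) -> np.ndarray:
    """Ping start times within an exposure phase.

    Pings occur at ``phase_start + k * interval`` and are included while the
    whole ping fits inside the phase (``time + duration <= phase_end``).
    A full 10 min phase at the 25 s repetition interval therefore holds
    exactly 24 pings.
    """
    if phase_end <= phase_start:
        raise ValueError("phase_end must exceed phase_start")
    if interval <= 0:
        raise ValueError("interval must be positive")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    n = int(math.floor((phase_end - duration - phase_start) / interval)) + 1
    n = max(n, 0)
    return phase_start + interval * np.arange(n)


def received_level(
    source_level: float,
    range_m: float,
    spreading_coeff: float = SPREADING_DB_PER_DECADE,
    absorption: float = ABSORPTION_DB_PER_KM,
) -> float:
    """RMS received level under geometric spreading + linear absorption.

    ``spl = SL - spreading_coeff * log10(range) - absorption * range/1000``.
    The model is undefined inside the 1 m reference distance.
    """
    if range_m < 1.0:
        raise ValueError("range must be >= 1 m (reference distance)")
    return (
        source_level
        - spreading_coeff * math.log10(range_m)
        - absorption * range_m / 1000.0
    )


def sel_per_ping(spl: float, duration: float = PING_DURATION) -> float:
    """Per-ping sound exposure level: ``spl + 10 log10(duration)``."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return spl + 10.0 * math.log10(duration)


def cumulative_sel(sels: Sequence[float]) -> float:
    """Energy sum of per-ping SELs: ``10 log10(sum 10^(sel/10))``."""
    sels = np.asarray(sels, dtype=float)
    if sels.size == 0:
        raise ValueError("cumulative SEL of an empty ping list is undefined")
    # sum in the linear (energy) domain, relative to the max for stability
    peak = sels.max()
    return peak + 10.0 * math.log10(np.sum(10.0 ** ((sels - peak) / 10.0)))


def max_rl(pings: PingLog) -> float:
    """Maximum per-ping RMS received level of a CEE."""
    if not pings.pings:
        raise ValueError("ping log is empty")
    return float(pings.spls().max())


def initial_ping_slope(pings: PingLog) -> tuple[float, bool]:
    """Received-level change from the first ping to the sixth.

    Returns ``(delta_db, flagged)`` where ``delta_db = spl_6 - spl_1`` and
    the CEE is flagged when the decline exceeds 1 dB (``delta_db < -1``),
    the pattern expected when a source positioned ahead of a moving group
    opens range over the first ~2 min of exposure.
    """
    if len(pings.pings) < 6:
        raise ValueError("initial ping slope needs at least 6 pings")
    delta = pings.pings[5].spl - pings.pings[0].spl
    return float(delta), bool(delta < -1.0)


def make_ping_log(
    times: Sequence[float],
    ranges: Sequence[float],
    source_level: float = SOURCE_LEVEL_SIM,
    cee_type: str = "mfas_sim",
    duration: float = PING_DURATION,
    spreading_coeff: float = SPREADING_DB_PER_DECADE,
    absorption: float = ABSORPTION_DB_PER_KM,
) -> PingLog:
    """Build a ping log from ping times and source-to-group ranges."""
    times = np.asarray(times, dtype=float)
    ranges = np.asarray(ranges, dtype=float)
    if times.shape != ranges.shape:
        raise ValueError("times and ranges must have equal length")
    pings = []
    for t, r in zip(times, ranges):
        spl = received_level(source_level, r, spreading_coeff, absorption)
        pings.append(
            Ping(time=float(t), range=float(r), spl=spl,
                 sel=sel_per_ping(spl, duration), duration=duration)
        )
    return PingLog(pings=pings, source_level=source_level, cee_type=cee_type)
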