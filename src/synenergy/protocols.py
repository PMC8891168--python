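"""Stimulation protocol generators.

Each generator is a pure function of its arguments plus the seed and returns
a :class:`ProtocolSpec`: presynaptic event times (s), somatic current pulses
(onset s, amplitude nA, width ms), the total duration, and the A_scale
factor the plasticity engine should apply for that protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProtocolSpec",
    "pairing_protocol",
    "afferent_protocol",
    "hfs_protocol",
    "SETTLE_S",
]

#: post-stimulus settle window included in every protocol's duration, s
SETTLE_S = 0.05

PULSE_AMP_NA = 1.0
PULSE_WIDTH_MS = 3.0


@dataclass
class ProtocolSpec:
    """Timed events of one stimulation protocol.

    ``pre_times`` is the template stream of presynaptic event times (s); the
    experiments layer attaches it to concrete compartments via
    :meth:`for_compartments`.  ``pre_events`` (filled by that call) maps
    compartment → event-time array.
    """

    pre_times: np.ndarray
    somatic_pulses: list
    duration: float
    A_scale: float = 1.0
    seed: int | None = None
    name: str = ""
    pre_events: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pre_times = np.sort(np.asarray(self.pre_times, dtype=float))
        if len(self.pre_times) and self.pre_times[0] < 0:
            raise ValueError("presynaptic event times must be non-negative")
        last = max(
            [self.pre_times[-1] if len(self.pre_times) else 0.0]
            + [on + w * 1e-3 for on, _, w in self.somatic_pulses]
        )
        if self.duration < last:
            raise ValueError("duration shorter than the last event")

    def for_compartments(self, compartments, per_compartment_times=None) -> "ProtocolSpec":
        """Attach the presynaptic stream to concrete compartments."""
        events = {}
        for c in compartments:
            t = self.pre_times if per_compartment_times is None else per_compartment_times[c]
            events[c] = np.asarray(t, dtype=float)
        out = ProtocolSpec(
            pre_times=self.pre_times,
            somatic_pulses=list(self.somatic_pulses),
            duration=self.duration,
            A_scale=self.A_scale,
            seed=self.seed,
            name=self.name,
            meta=dict(self.meta),
        )
        out.pre_events = events
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "pre_times_s": self.pre_times.tolist(),
                "somatic_pulses": [list(p) for p in self.somatic_pulses],
                "duration_s": self.duration,
                "A_scale": self.A_scale,
                "seed": self.seed,
                "pre_events": {c: np.asarray(t).tolist() for c, t in self.pre_events.items()},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ProtocolSpec":
        d = json.loads(text)
        out = cls(
            pre_times=np.array(d["pre_times_s"]),
            somatic_pulses=[tuple(p) for p in d["somatic_pulses"]],
            duration=d["duration_s"],
            A_scale=d["A_scale"],
            seed=d["seed"],
            name=d.get("name", ""),
        )
        out.pre_events = {c: np.array(t) for c, t in d.get("pre_events", {}).items()}
        return out


def pairing_protocol(freq: float, delta_t_ms: float, repeats: int = 5) -> ProtocolSpec:
    """Pre/post pairing at a given repetition frequency.

    ``repeats`` pairs at period 1/``freq``; within each pair the somatic
    pulse (1 nA, 3 ms) follows the presynaptic event by ``delta_t_ms`` when
    positive (pre–post) and precedes it by |Δt| when negative (post–pre).
    Five simulated pairs stand in for the 60 pairs of the experimental
    protocol, so A_scale = 12 (= 60/5) is attached.
    """
    if freq <= 0:
        raise ValueError("pairing frequency must be > 0")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    dt_s = delta_t_ms * 1e-3
    base = np.arange(repeats) / freq
    pre = base + max(0.0, -dt_s)
    post = base + max(0.0, dt_s)
    pulses = [(float(t), PULSE_AMP_NA, PULSE_WIDTH_MS) for t in post]
    # duration covers `repeats` full periods regardless of Δt, so sweeps over
    # the pairing interval at fixed frequency share one stimulation time
    # (and hence one supply trajectory)
    last = max(pre[-1], post[-1] + PULSE_WIDTH_MS * 1e-3)
    return ProtocolSpec(
        pre_times=pre,
        somatic_pulses=pulses,
        duration=float(max(repeats / freq, last + 1e-3) + SETTLE_S),
        A_scale=12.0,
        name=f"pairing_{freq:g}Hz_{delta_t_ms:+g}ms",
    )


def afferent_protocol(rate: float, n_pulses: int = 20, seed: int | None = None) -> ProtocolSpec:
    """Presynaptic-only Poisson train: exactly ``n_pulses`` events.

    Count-conditioned Poisson process — inter-event intervals are drawn
    i.i.d. exponential with mean 1/``rate`` until ``n_pulses`` events exist
    (the event count, not the window, is what the protocol fixes).
    """
    if rate <= 0:
        raise ValueError("afferent rate must be > 0")
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    rng = np.random.default_rng(seed)
    times = np.cumsum(rng.exponential(1.0 / rate, size=n_pulses))
    return ProtocolSpec(
        pre_times=times,
        somatic_pulses=[],
        duration=float(times[-1] + SETTLE_S),
        A_scale=1.0,
        seed=seed,
        name=f"afferent_{rate:g}Hz",
    )


def hfs_protocol(seed: int | None = None, inter_series_gap: float = 10.0) -> ProtocolSpec:
    """High-frequency stimulation: 4 series × 10 trains × 10 Poisson shocks.

    Trains within a series start 0.3 s apart; each train carries exactly 10
    shocks drawn as a 100 Hz Poisson process (exponential inter-shock
    intervals); 400 shocks in total.  The separation between series is not
    part of the protocol definition and defaults to 10 s; the supply clock
    runs continuously across all four series.
    """
    if inter_series_gap < 0:
        raise ValueError("inter_series_gap must be >= 0")
    rng = np.random.default_rng(seed)
    series_len = 10 * 0.3
    trains = []
    for s in range(4):
        s_start = s * (series_len + inter_series_gap)
        for tr in range(10):
            t0 = s_start + tr * 0.3
            trains.append(t0 + np.cumsum(rng.exponential(1.0 / 100.0, size=10)))
    times = np.concatenate(trains)
    return ProtocolSpec(
        pre_times=times,
        somatic_pulses=[],
        duration=float(times.max() + SETTLE_S),
        A_scale=1.0,
        seed=seed,
        name="hfs",
        meta={"trains": [t.tolist() for t in trains],
              "train_starts": [s * (series_len + inter_series_gap) + tr * 0.3
                               for s in range(4) for tr in range(10)]},
    )
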