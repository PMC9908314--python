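"""Stimulus protocols and platform-angle waveforms.

A tilt-in-place trial rotates the preparation from horizontal to an eccentric
roll angle, holds it there, and rapidly returns it to horizontal.  Two stimulus
kinds are supported:

``step``
    Rapid ramp to the eccentric angle, a long (>= 1 s, typically 15 s) hold,
    and a rapid return.  Probes tonic (static-tilt) encoding: the fluorescence
    just after the return reflects the steady state at the eccentric angle.
``impulse``
    Ramp out and immediately back (total excursion < ~13 ms).  Probes phasic
    (angular-acceleration) encoding with no steady-state component.

Angles are signed relative to the recorded neuron: positive rolls tilt toward
the neuron's hemisphere (ipsilateral, ear-down on the neuron's side), negative
rolls tilt away (contralateral).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StimulusProtocol",
    "default_transition_ms",
    "default_impulse_hold_s",
    "generate_waveform",
]

#: Measured ramp durations (ms) for step stimuli, by magnitude (degrees).
STEP_TRANSITION_MS = {10.0: 2.2, 20.0: 3.9, 30.0: 5.3}

#: Measured total excursion (ms) and dwell at peak (ms) for impulse stimuli.
IMPULSE_KINEMATICS_MS = {10.0: (5.0, 0.3), 15.0: (5.6, 0.4), 30.0: (13.0, 2.5)}


def default_transition_ms(kind: str, magnitude_deg: float) -> float:
    """Default single-ramp duration in ms for a stimulus of this kind/size.

    Step ramps come from galvanometer measurements at 10/20/30 degrees; impulse
    ramps are (total excursion - dwell at peak) / 2.  Magnitudes not in the
    measured table are linearly interpolated (and clamped at the table ends).
    """
    if kind == "step":
        table = {m: v for m, v in STEP_TRANSITION_MS.items()}
    elif kind == "impulse":
        table = {m: (tot - hold) / 2.0 for m, (tot, hold) in IMPULSE_KINEMATICS_MS.items()}
    else:
        raise ValueError(f"unknown stimulus kind {kind!r}")
    mags = np.array(sorted(table))
    vals = np.array([table[m] for m in mags])
    return float(np.interp(magnitude_deg, mags, vals))


def default_impulse_hold_s(magnitude_deg: float) -> float:
    """Default dwell at the eccentric angle (seconds) for an impulse."""
    mags = np.array(sorted(IMPULSE_KINEMATICS_MS))
    holds = np.array([IMPULSE_KINEMATICS_MS[m][1] for m in mags]) * 1e-3
    return float(np.interp(magnitude_deg, mags, holds))


@dataclass(frozen=True)
class StimulusProtocol:
    """One trial's stimulus description.

    Parameters
    ----------
    kind : {"step", "impulse"}
    direction : {"ipsi", "contra"}
        Roll direction relative to the recorded neuron's hemisphere.
    magnitude_deg : float
        Eccentric angle in degrees (positive).
    baseline_s : float
        Horizontal baseline recording before the ramp (seconds).
    hold_s : float
        Dwell at the eccentric angle.  Steps hold >= 1 s (typically 15 s);
        impulses dwell <= 10 ms.
    response_s : float
        Recording after the return to horizontal.
    transition_ms : float
        Duration of each rapid ramp (out and back), milliseconds.
    """

    kind: str
    direction: str
    magnitude_deg: float
    baseline_s: float = 6.0
    hold_s: float = 15.0
    response_s: float = 5.0
    transition_ms: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("step", "impulse"):
            raise ValueError(f"kind must be 'step' or 'impulse', got {self.kind!r}")
        if self.direction not in ("ipsi", "contra"):
            raise ValueError(f"direction must be 'ipsi' or 'contra', got {self.direction!r}")
        if self.magnitude_deg < 0:
            raise ValueError("magnitude_deg must be >= 0")
        if self.baseline_s <= 0 or self.response_s <= 0:
            raise ValueError("baseline_s and response_s must be positive")
        if self.transition_ms is None:
            object.__setattr__(
                self, "transition_ms", default_transition_ms(self.kind, self.magnitude_deg)
            )
        if self.transition_ms <= 0:
            raise ValueError("transition_ms must be positive")
        if self.kind == "impulse" and self.hold_s > 0.01:
            raise ValueError("impulse stimuli dwell <= 10 ms at the eccentric angle")
        if self.kind == "step" and self.hold_s < 1.0:
            raise ValueError("step stimuli hold >= 1 s at the eccentric angle")

    # -- derived timing (seconds from trial start) --------------------------

    @property
    def sign(self) -> int:
        """+1 for ipsilateral rolls, -1 for contralateral."""
        return 1 if self.direction == "ipsi" else -1

    @property
    def transition_s(self) -> float:
        return self.transition_ms * 1e-3

    @property
    def t_ramp_out(self) -> float:
        """Start of the outgoing ramp (= end of baseline)."""
        return self.baseline_s

    @property
    def t_hold_start(self) -> float:
        return self.baseline_s + self.transition_s

    @property
    def t_hold_end(self) -> float:
        return self.t_hold_start + self.hold_s

    @property
    def t_return(self) -> float:
        """Time at which the platform is back at horizontal."""
        return self.t_hold_end + self.transition_s

    @property
    def total_s(self) -> float:
        return self.t_return + self.response_s

    @property
    def event_times(self) -> tuple[float, float]:
        """Midpoints of the two rapid ramps (phasic event times)."""
        half = self.transition_s / 2.0
        return (self.t_ramp_out + half, self.t_hold_end + half)

    def with_direction(self, direction: str) -> "StimulusProtocol":
        return replace(self, direction=direction)


def generate_waveform(
    protocol: StimulusProtocol, rate_hz: float = 5000.0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the idealized platform-angle trajectory on a fine grid.

    Returns
    -------
    t : ndarray
        Sample times, seconds from trial start, spacing ``1/rate_hz``.
    angle : ndarray
        Signed platform angle in degrees (positive = ipsilateral).

    The trajectory is piecewise linear: flat at 0 during the baseline, a ramp
    of ``transition_ms`` to the signed eccentric angle, a flat hold, a ramp
    back, then flat at 0 for the response period.
    """
    if rate_hz < 1000.0:
        raise ValueError("waveform grid must be >= 1 kHz to resolve ms-scale ramps")
    p = protocol
    t = np.arange(0.0, p.total_s, 1.0 / rate_hz)
    peak = p.sign * p.magnitude_deg
    xp = [0.0, p.t_ramp_out, p.t_hold_start, p.t_hold_end, p.t_return, p.total_s]
    fp = [0.0, 0.0, peak, peak, 0.0, 0.0]
    angle = np.interp(t, xp, fp)
    return t, angle
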