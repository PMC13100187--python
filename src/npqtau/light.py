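"""Actinic light sequences.

A measurement sequence is written as a dash-separated string of phases,
each an integer number of minutes followed by ``HL`` (high light,
~1500 µmol photons m⁻² s⁻¹) or ``D`` (dark), e.g. ``"5HL-10D-5HL"``.
Light intensity enters the kinetic model only through the binary HL/D
label; the irradiance is carried as metadata.  The weak detection laser
used to acquire lifetime snapshots is present throughout a sequence and
drives a small photoinhibition term of its own.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


class LightSequenceError(ValueError):
    """Raised for a malformed light-sequence string."""


_TOKEN = re.compile(r"^(\d+)(HL|D)$")


@dataclass(frozen=True)
class LightProfile:
    """An ordered list of (label, duration) phases.

    Parameters
    ----------
    phases
        Sequence of ``(label, duration_s)`` with label in {"HL", "D"} and
        duration in seconds.
    irradiance_HL
        Metadata: photon flux of the HL phases in µmol m⁻² s⁻¹.
    laser_on
        Whether the detection laser is present throughout (default True).
    """

    phases: tuple[tuple[str, float], ...]
    irradiance_HL: float = 1500.0
    laser_on: bool = True
    spec: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        for label, dur in self.phases:
            if label not in ("HL", "D"):
                raise LightSequenceError(f"unknown phase label {label!r}")
            if not dur > 0:
                raise LightSequenceError(
                    f"non-positive phase duration {dur!r} for label {label!r}"
                )

    @property
    def duration(self) -> float:
        """Total sequence duration in seconds."""
        return float(sum(d for _, d in self.phases))

    @property
    def boundaries(self) -> list[float]:
        """Cumulative phase edge times, starting at 0."""
        edges = [0.0]
        for _, d in self.phases:
            edges.append(edges[-1] + d)
        return edges

    def light_at(self, t: float) -> int:
        """Binary light indicator u(t) ∈ {0, 1} (1 inside an HL phase)."""
        if t < 0:
            return 0
        edges = self.boundaries
        for (label, _), lo, hi in zip(self.phases, edges[:-1], edges[1:]):
            if lo <= t < hi:
                return 1 if label == "HL" else 0
        # at or past the final edge: use the last phase's label
        return 1 if self.phases[-1][0] == "HL" else 0


def parse_light_sequence(
    spec: str, irradiance_HL: float = 1500.0, laser_on: bool = True
) -> LightProfile:
    """Parse a sequence string like ``"5HL-10D-5HL"`` into a LightProfile.

    Each token is ``<int minutes><HL|D>``; durations are converted to
    seconds.  Raises :class:`LightSequenceError` naming the offending
    token on malformed input or a zero-duration phase.
    """
    if not isinstance(spec, str) or not spec.strip():
        raise LightSequenceError(f"empty light sequence {spec!r}")
    phases: list[tuple[str, float]] = []
    for token in spec.strip().split("-"):
        m = _TOKEN.match(token)
        if m is None:
            raise LightSequenceError(
                f"malformed token {token!r} in sequence {spec!r} "
                "(expected <minutes><HL|D>)"
            )
        minutes = int(m.group(1))
        if minutes <= 0:
            raise LightSequenceError(
                f"zero/negative duration in token {token!r} of {spec!r}"
            )
        phases.append((m.group(2), 60.0 * minutes))
    return LightProfile(
        tuple(phases), irradiance_HL=irradiance_HL, laser_on=laser_on, spec=spec
    )


#: The three actinic sequences used throughout: continuous high light,
#: a regular light–dark–light block, and an irregular fluctuating block.
STANDARD_SEQUENCES = ("20HL", "5HL-10D-5HL", "3HL-1D-1HL-3D-9HL-3D")

#: The two sequences used for parameter training (the third is held out).
TRAINING_SEQUENCES = ("5HL-10D-5HL", "3HL-1D-1HL-3D-9HL-3D")
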