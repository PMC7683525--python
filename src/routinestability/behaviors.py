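"""Closed vocabulary of sensed behaviors and their typical daily magnitudes.

Seventeen behaviors are tracked by the passive-sensing pipeline: message
counts, call / phone-unlock / conversation periods, ambient-audio context
(light, sound volume, voice, non-voice, silence), sleep, and the motion
states reported by on-device activity recognition (on-bike, walk,
in-vehicle, tilting, still, unknown).
"""

from __future__ import annotations

MINUTES_PER_DAY = 1440

#: Canonical behavior labels, in fixed order (feature tables follow this order).
BEHAVIORS: tuple[str, ...] = (
    "incoming_messages",
    "outgoing_messages",
    "call",
    "unlock",
    "conversation",
    "ambient_light",
    "ambient_sound_volume",
    "ambient_voice",
    "ambient_nonvoice",
    "ambient_silence",
    "sleep",
    "on_bike",
    "walk",
    "in_vehicle",
    "tilting",
    "still",
    "unknown_activity",
)

#: Discrete count-like behaviors: one instantaneous event of magnitude 1 per occurrence.
EVENT_BEHAVIORS = frozenset({"incoming_messages", "outgoing_messages"})

#: Ambient scalar streams: per-minute non-negative readings supplied directly.
SCALAR_BEHAVIORS = frozenset({"ambient_light", "ambient_sound_volume"})

#: Duration behaviors: periods contributing one unit per covered minute.
PERIOD_BEHAVIORS = frozenset(BEHAVIORS) - EVENT_BEHAVIORS - SCALAR_BEHAVIORS

#: Cohort-typical (mean, SD) of the daily total of each behavior: counts per
#: day for messages, minutes per day for period behaviors, arbitrary sensor
#: units per day for the two ambient scalar streams.
DAILY_MAGNITUDES: dict[str, tuple[float, float]] = {
    "incoming_messages": (3.4, 6.8),
    "outgoing_messages": (3.4, 8.0),
    "call": (10.9, 19.2),
    "unlock": (98.2, 129.8),
    "conversation": (117.1, 81.3),
    "ambient_light": (800.0, 300.0),
    "ambient_sound_volume": (400.0, 150.0),
    "ambient_voice": (54.5, 51.7),
    "ambient_nonvoice": (144.1, 155.8),
    "ambient_silence": (933.3, 453.3),
    "sleep": (630.6, 336.5),
    "on_bike": (1.2, 1.3),
    "walk": (18.2, 19.6),
    "in_vehicle": (28.6, 24.5),
    "tilting": (42.9, 34.0),
    "still": (467.4, 193.4),
    "unknown_activity": (370.2, 172.3),
}
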