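"""Fixed catalogue of calf postures and behaviours.

Labels assigned by observers (or by a classifier) are restricted to this
ethogram.  Behaviour states are mutually exclusive; each behaviour implies
a posture (lying or standing), so a posture track can be derived from a
behaviour track.
"""

from __future__ import annotations

# Behaviour states, in canonical order.
NON_ACTIVE_LYING = "non-active lying"
ACTIVE_LYING = "active lying"
RUMINATING = "ruminating"
SELF_GROOMING = "self-grooming"
NUTRITIVE_SUCKLING = "nutritive suckling"
NON_NUTRITIVE_SUCKLING = "non-nutritive suckling"
LOCOMOTOR_PLAY = "locomotor play"

BEHAVIOURS: tuple[str, ...] = (
    NON_ACTIVE_LYING,
    ACTIVE_LYING,
    RUMINATING,
    SELF_GROOMING,
    NUTRITIVE_SUCKLING,
    NON_NUTRITIVE_SUCKLING,
    LOCOMOTOR_PLAY,
)

# Posture states.
LYING = "lying"
STANDING = "standing"
POSTURES: tuple[str, ...] = (LYING, STANDING)

# Posture implied by each behaviour.  Suckling happens at the milk feeder
# (standing); play is rapid forward movement; self-grooming is treated as
# standing by convention.
POSTURE_OF_BEHAVIOUR: dict[str, str] = {
    NON_ACTIVE_LYING: LYING,
    ACTIVE_LYING: LYING,
    RUMINATING: LYING,
    SELF_GROOMING: STANDING,
    NUTRITIVE_SUCKLING: STANDING,
    NON_NUTRITIVE_SUCKLING: STANDING,
    LOCOMOTOR_PLAY: STANDING,
}

#: Minimum bout duration recorded by the observation protocol (seconds).
MIN_BOUT_S = 3.0


def behaviour_index(behaviour: str) -> int:
    """Stable integer index of a behaviour, used for seed derivation."""
    try:
        return BEHAVIOURS.index(behaviour)
    except ValueError:
        raise KeyError(f"unknown behaviour {behaviour!r}") from None
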