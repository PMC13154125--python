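"""The 65 Sohncke space groups.

Sohncke groups contain only proper symmetry operations (rotations and
translations) and are therefore the only space groups accessible to
enantiopure chiral molecules.
"""

from __future__ import annotations

SOHNCKE_GROUPS: frozenset[int] = frozenset(
    [1]
    + [3, 4, 5]
    + list(range(16, 25))     # 16-24
    + list(range(75, 81))     # 75-80
    + list(range(89, 99))     # 89-98
    + [143, 144, 145, 146]
    + list(range(149, 156))   # 149-155
    + list(range(168, 174))   # 168-173
    + list(range(177, 183))   # 177-182
    + list(range(195, 200))   # 195-199
    + list(range(207, 215))   # 207-214
)

assert len(SOHNCKE_GROUPS) == 65


def is_sohncke(space_group: int) -> bool:
    """Return True if the space-group number belongs to a Sohncke group."""
    return int(space_group) in SOHNCKE_GROUPS
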