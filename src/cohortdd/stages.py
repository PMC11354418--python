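"""Developmental stages of a reared hemipteran cohort.

Post-embryonic development of *Zelus renardii* (and reduviids generally)
passes through five nymphal instars.  The egg stage ``EG`` is the biofix
from which degree-day accumulation starts; ``AD`` (adult) is terminal.
"""

from __future__ import annotations

from enum import IntEnum


class Stage(IntEnum):
    """Life stage codes, totally ordered EG < N1 < ... < N5 < AD."""

    EG = 0
    N1 = 1
    N2 = 2
    N3 = 3
    N4 = 4
    N5 = 5
    AD = 6

    @property
    def code(self) -> str:
        return self.name

    @property
    def is_terminal(self) -> bool:
        return self is Stage.AD

    def next(self) -> "Stage | None":
        """The following stage, or None for the adult stage."""
        if self is Stage.AD:
            return None
        return Stage(self.value + 1)


#: All stages in developmental order.
STAGES: tuple[Stage, ...] = tuple(Stage)

#: Pre-adult stages (the ones with a finite degree-day requirement).
JUVENILE_STAGES: tuple[Stage, ...] = tuple(s for s in Stage if s is not Stage.AD)
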