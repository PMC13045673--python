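"""Three-valued (strong Kleene) truth values for criteria on incomplete records.

Clinical registry records routinely have missing fields, so a criterion such
as "SNOT-22 >= 35" may be undecidable for a given patient.  ``TriState`` adds
an explicit ``UNKNOWN`` to the booleans; the Kleene connectives propagate
``UNKNOWN`` only when the known operands do not already force the outcome
(``FALSE`` absorbs under AND, ``TRUE`` under OR).

The *information order* ``UNKNOWN ⊑ TRUE`` and ``UNKNOWN ⊑ FALSE`` makes the
monotonicity guarantee precise: learning the value of a missing field can
turn ``UNKNOWN`` into a determinate verdict but can never flip ``TRUE`` to
``FALSE`` or vice versa.
"""

from __future__ import annotations

import enum
from typing import Optional


class TriState(enum.Enum):
    """Kleene truth value: TRUE, FALSE, or UNKNOWN (missing information)."""

    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"

    def __bool__(self) -> bool:  # pragma: no cover - guard
        raise TypeError(
            "TriState is three-valued; test identity against TriState members "
            "or use is_determinate()"
        )

    def is_determinate(self) -> bool:
        """True when the value is TRUE or FALSE (not UNKNOWN)."""
        return self is not TriState.UNKNOWN

    def refines(self, other: "TriState") -> bool:
        """Information order: ``other ⊑ self`` — self carries at least as
        much information as *other* and agrees with it where other is
        determinate."""
        return other is TriState.UNKNOWN or other is self


TRUE = TriState.TRUE
FALSE = TriState.FALSE
UNKNOWN = TriState.UNKNOWN


def lift_bool(value: Optional[bool]) -> TriState:
    """Lift a possibly-missing boolean into TriState (None -> UNKNOWN)."""
    if value is None:
        return UNKNOWN
    return TRUE if value else FALSE


def kleene_and(a: TriState, b: TriState) -> TriState:
    """Strong-Kleene conjunction: FALSE absorbs, TRUE is neutral."""
    if a is FALSE or b is FALSE:
        return FALSE
    if a is TRUE and b is TRUE:
        return TRUE
    return UNKNOWN


def kleene_or(a: TriState, b: TriState) -> TriState:
    """Strong-Kleene disjunction: TRUE absorbs, FALSE is neutral."""
    if a is TRUE or b is TRUE:
        return TRUE
    if a is FALSE and b is FALSE:
        return FALSE
    return UNKNOWN
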