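"""Core record model: one annotated sequencing read per record.

Functionality classes follow the standard V(D)J annotation vocabulary:
``productive`` (in-frame, stop-free rearrangement), ``unproductive``
(frame-shifted or containing stops), ``unknown`` (alignable but class
undetermined) and ``no_result`` (no alignment found).  No-result reads are
reported in summaries but excluded from all downstream clonality and
diversity calculations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .genes import GeneCall

logger = logging.getLogger(__name__)

# 20 amino acids plus stop ('*', observed in out-of-frame CDR3 translations)
# and 'X' for undetermined positions.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X")


class Functionality(str, Enum):
    PRODUCTIVE = "productive"
    UNPRODUCTIVE = "unproductive"
    UNKNOWN = "unknown"
    NO_RESULT = "no_result"


def normalize_functionality(token: Optional[str]) -> Functionality:
    """Map a raw functionality token onto the four-class vocabulary.

    Case-insensitive prefix match; annotation portals append parenthetical
    comments ("unproductive (see comment)") that must not defeat the match.
    Empty tokens and "no result(s)" map to NO_RESULT; anything unrecognized
    maps to UNKNOWN with a logged warning.
    """
    t = (token or "").strip().lower().replace("_", " ")
    if not t or t.startswith("no result"):
        return Functionality.NO_RESULT
    if t.startswith("unproductive"):
        return Functionality.UNPRODUCTIVE
    if t.startswith("productive"):
        return Functionality.PRODUCTIVE
    if t.startswith("unknown"):
        return Functionality.UNKNOWN
    logger.warning("unrecognized functionality token %r mapped to 'unknown'", token)
    return Functionality.UNKNOWN


@dataclass(slots=True)
class SequenceRecord:
    """One annotated read.

    ``no_result`` records carry no gene calls or CDR sequences (there was no
    alignment to derive them from).
    """

    sequence_id: str
    functionality: Functionality = Functionality.UNKNOWN
    v_call: Optional[GeneCall] = None
    d_call: Optional[GeneCall] = None
    j_call: Optional[GeneCall] = None
    cdr1_aa: Optional[str] = None
    cdr2_aa: Optional[str] = None
    cdr3_aa: Optional[str] = None
    cdr3_nt: Optional[str] = None
    sequence_nt: Optional[str] = None

    def __post_init__(self) -> None:
        if self.functionality is Functionality.NO_RESULT:
            self.v_call = self.d_call = self.j_call = None
            self.cdr1_aa = self.cdr2_aa = self.cdr3_aa = None
            self.cdr3_nt = None
        if self.cdr3_aa is not None and not self.cdr3_aa:
            self.cdr3_aa = None
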