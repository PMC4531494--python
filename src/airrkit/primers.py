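"""Multiplex-PCR primer matching against annotated reads.

Each primer is searched as an exact substring of the read (degenerate IUPAC
codes in the primer match any compatible base).  Reverse primers are searched
as their reverse complement by default, because annotation pipelines report
reads in V-to-J orientation.  A read contributes at most one hit per primer,
so each primer's relative frequency is the fraction of searched reads that
carry it — the quantity multiplex-PCR efficiency control needs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

# degenerate code -> set of concrete bases it stands for
IUPAC_CODES: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def reverse_complement(sequence: str) -> str:
    """Reverse complement honoring degenerate IUPAC codes (R<->Y, K<->M, ...)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(sequence.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide character {exc.args[0]!r}") from None


@dataclass(frozen=True, slots=True)
class Primer:
    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"


@dataclass
class PrimerSet:
    name: str
    primers: List[Primer] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.primers]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate primer names in set {self.name!r}")

    def __len__(self) -> int:
        return len(self.primers)


def _primer_regex(sequence: str) -> re.Pattern:
    """Compile a primer to a regex over read characters.

    A degenerate primer code matches any read base compatible with it; primer
    N additionally matches read-side ambiguity codes (which otherwise match
    nothing).
    """
    parts = []
    for ch in sequence.upper():
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC character {ch!r} in primer")
        if ch == "N":
            parts.append("[" + "".join(IUPAC_CODES) + "]")
        else:
            expansion = IUPAC_CODES[ch]
            parts.append(expansion if len(expansion) == 1 else f"[{expansion}]")
    return re.compile("".join(parts))


@dataclass
class PrimerMatchReport:
    primer_set: str
    reads_searched: int
    hit_counts: Dict[str, int]
    orientations: Dict[str, str]
    reads_with_no_forward_hit: int
    reads_with_no_reverse_hit: int

    @property
    def frequencies(self) -> Dict[str, float]:
        n = self.reads_searched
        return {p: (c / n if n else 0.0) for p, c in self.hit_counts.items()}

    def to_frame(self) -> pd.DataFrame:
        freqs = self.frequencies
        return pd.DataFrame({
            "primer": list(self.hit_counts),
            "orientation": [self.orientations[p] for p in self.hit_counts],
            "count": list(self.hit_counts.values()),
            "frequency": [freqs[p] for p in self.hit_counts],
        })


def _search_text(record, search_field: str) -> Optional[str]:
    if record.sequence_nt is None:
        return None
    if search_field == "whole_read":
        return record.sequence_nt.upper()
    if search_field == "v_region":
        # No dedicated V-region column exists in the summary dialect; use the
        # read prefix up to the CDR3 (the region multiplex V primers sit in),
        # falling back to the whole read when the CDR3 cannot be located.
        seq = record.sequence_nt.upper()
        if record.cdr3_nt:
            pos = seq.find(record.cdr3_nt.upper())
            if pos > 0:
                return seq[:pos]
        return seq
    raise ValueError(f"unknown search_field {search_field!r}")


def match_primers(records: Sequence, primer_set: PrimerSet,
                  search_field: str = "whole_read",
                  literal: bool = False) -> PrimerMatchReport:
    """Count, per primer, the reads whose sequence contains it exactly.

    ``literal=True`` searches reverse primers as written instead of
    reverse-complementing them.
    """
    if not primer_set.primers:
        raise ValueError("primer set is empty")
    texts = [t for t in (_search_text(r, search_field) for r in records)
             if t is not None]
    if not texts:
        raise ValueError("no record carries a nucleotide read to search")

    patterns = {}
    for p in primer_set.primers:
        seq = p.sequence if (p.orientation == "forward" or literal) \
            else reverse_complement(p.sequence)
        patterns[p.name] = _primer_regex(seq)

    hit_counts = {p.name: 0 for p in primer_set.primers}
    no_fwd = no_rev = 0
    fwd = [p.name for p in primer_set.primers if p.orientation == "forward"]
    rev = [p.name for p in primer_set.primers if p.orientation == "reverse"]
    for text in texts:
        hits = {name for name, pat in patterns.items() if pat.search(text)}
        for name in hits:
            hit_counts[name] += 1
        if fwd and not hits.intersection(fwd):
            no_fwd += 1
        if rev and not hits.intersection(rev):
            no_rev += 1
    return PrimerMatchReport(
        primer_set=primer_set.name,
        reads_searched=len(texts),
        hit_counts=hit_counts,
        orientations={p.name: p.orientation for p in primer_set.primers},
        reads_with_no_forward_hit=no_fwd,
        reads_with_no_reverse_hit=no_rev,
    )
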