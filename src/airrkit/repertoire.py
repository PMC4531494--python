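"""Descriptive repertoire statistics and clonotype counting.

A *clonotype* is a group of reads sharing an identical receptor-defining key.
The key is configurable: a CDR amino-acid sequence (CDR1/2/3), the CDR3
nucleotide sequence, the whole-read nucleotide sequence, or the V-(D)-J gene
(or allele) combination.  No-result reads never enter clonotype counts;
whether unknown/unproductive reads do is controlled by the definition's
include set (default: everything except no-result).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .records import Functionality, SequenceRecord


@dataclass
class FunctionalitySummary:
    """Per-class read counts; frequencies are fractions of the total."""

    counts: Dict[Functionality, int]
    total: int

    @property
    def frequencies(self) -> Dict[Functionality, float]:
        if self.total == 0:
            return {f: 0.0 for f in Functionality}
        return {f: self.counts[f] / self.total for f in Functionality}

    def to_frame(self) -> pd.DataFrame:
        freqs = self.frequencies
        return pd.DataFrame({
            "class": [f.value for f in Functionality],
            "count": [self.counts[f] for f in Functionality],
            "frequency": [freqs[f] for f in Functionality],
        })


def summarize_functionality(records: Sequence[SequenceRecord]) -> FunctionalitySummary:
    """Tally productive / unproductive / unknown / no-result reads."""
    counts = {f: 0 for f in Functionality}
    for r in records:
        counts[r.functionality] += 1
    return FunctionalitySummary(counts=counts, total=len(records))


def gene_usage(records: Sequence[SequenceRecord], segment: str,
               level: str = "gene") -> pd.DataFrame:
    """Occurrence table for one segment (V, D or J).

    Records without a call for the segment are excluded from the denominator.
    Rows are sorted by descending count, ties broken lexicographically —
    deterministic output for export and testing.  Frequencies are fractions.
    """
    if segment not in ("V", "D", "J"):
        raise ValueError(f"segment must be V, D or J, got {segment!r}")
    attr = {"V": "v_call", "D": "d_call", "J": "j_call"}[segment]
    tally: Counter = Counter()
    for r in records:
        call = getattr(r, attr)
        if call is not None:
            tally[call.label(level)] += 1
    total = sum(tally.values())
    rows = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame({
        "segment": [segment] * len(rows),
        "name": [k for k, _ in rows],
        "count": [v for _, v in rows],
        "frequency": [v / total for _, v in rows] if total else [],
    })


class ClonotypeMode(str, Enum):
    CDR1_AA = "cdr1-aa"
    CDR2_AA = "cdr2-aa"
    CDR3_AA = "cdr3-aa"
    CDR3_NT = "cdr3-nt"
    WHOLE_READ_NT = "whole-read"
    VDJ_GENES = "vdj"


DEFAULT_INCLUDE = frozenset({
    Functionality.PRODUCTIVE, Functionality.UNPRODUCTIVE, Functionality.UNKNOWN,
})


@dataclass(frozen=True)
class ClonotypeDefinition:
    """What makes two reads the same clonotype."""

    mode: ClonotypeMode = ClonotypeMode.CDR3_AA
    level: str = "gene"  # for VDJ_GENES: "gene" or "allele"
    include: frozenset = DEFAULT_INCLUDE

    def __post_init__(self) -> None:
        if Functionality.NO_RESULT in self.include:
            raise ValueError("no_result reads are never counted in clonality")

    @classmethod
    def productive_only(cls, mode: ClonotypeMode = ClonotypeMode.CDR3_AA,
                        level: str = "gene") -> "ClonotypeDefinition":
        return cls(mode=mode, level=level,
                   include=frozenset({Functionality.PRODUCTIVE}))


def clonotype_key(record: SequenceRecord,
                  definition: ClonotypeDefinition) -> Optional[str]:
    """Key string for a record under a definition, or None.

    None means the record does not participate: its functionality class is
    excluded or the field the definition needs is absent.  Sequence keys are
    upper-cased and whitespace-stripped; no fuzzy matching.  V-(D)-J keys are
    the segment names joined with '|', an absent D rendered as '-'.
    """
    if record.functionality not in definition.include:
        return None
    mode = definition.mode
    if mode is ClonotypeMode.VDJ_GENES:
        if record.v_call is None or record.j_call is None:
            return None
        d = record.d_call.label(definition.level) if record.d_call else "-"
        return "|".join((record.v_call.label(definition.level), d,
                         record.j_call.label(definition.level)))
    value = {
        ClonotypeMode.CDR1_AA: record.cdr1_aa,
        ClonotypeMode.CDR2_AA: record.cdr2_aa,
        ClonotypeMode.CDR3_AA: record.cdr3_aa,
        ClonotypeMode.CDR3_NT: record.cdr3_nt,
        ClonotypeMode.WHOLE_READ_NT: record.sequence_nt,
    }[mode]
    if value is None:
        return None
    key = value.strip().upper()
    return key or None


@dataclass
class ClonotypeTable:
    """Clonotype counts under one definition.

    Relative frequencies are percentages (0-100) of ``n_records_used``; rows
    are sorted by descending count then ascending key.
    """

    definition: ClonotypeDefinition
    df: pd.DataFrame  # columns: key, count, frequency
    n_records_used: int
    sample_id: Optional[str] = None

    def __len__(self) -> int:
        return len(self.df)

    def frequency_of(self, key: str) -> float:
        hit = self.df.loc[self.df["key"] == key, "frequency"]
        return float(hit.iloc[0]) if len(hit) else 0.0


def build_clonotype_table(records: Sequence[SequenceRecord],
                          definition: Optional[ClonotypeDefinition] = None,
                          sample_id: Optional[str] = None) -> ClonotypeTable:
    """Count identical clonotype keys over all participating records."""
    definition = definition or ClonotypeDefinition()
    keys = [k for k in (clonotype_key(r, definition) for r in records)
            if k is not None]
    return table_from_keys(keys, definition, sample_id=sample_id)


def table_from_keys(keys: Sequence[str], definition: ClonotypeDefinition,
                    sample_id: Optional[str] = None) -> ClonotypeTable:
    tally = Counter(keys)
    n = len(keys)
    rows = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame({
        "key": [k for k, _ in rows],
        "count": [c for _, c in rows],
        "frequency": [100.0 * c / n for _, c in rows] if n else [],
    })
    return ClonotypeTable(definition=definition, df=df, n_records_used=n,
                          sample_id=sample_id)
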