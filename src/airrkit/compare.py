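"""Multi-sample clonotype comparison and longitudinal tracking.

The comparers work on clonotype tables sharing one definition: take the top-c
clonotypes of each sample (default c = 20), form the union of those keys, and
report every key's frequency in every sample (0 when absent).  Matching is
exact key identity.  Tracking reports per-key frequency trajectories across
time-ordered samples for line plots.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .repertoire import ClonotypeDefinition, ClonotypeTable

DEFAULT_TOP_C = 20
_PALETTE_SIZE = 24


def color_index(key: str, palette_size: int = _PALETTE_SIZE, seed: int = 0) -> int:
    """Deterministic key -> palette index, stable across runs and samples, so a
    clonotype matched between reports always renders in the same color."""
    digest = hashlib.sha256(f"{seed}:{key}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % palette_size


@dataclass
class RankedClonotypes:
    """The top-c clonotypes of one sample under the table's deterministic sort."""

    sample_id: str
    definition: ClonotypeDefinition
    entries: pd.DataFrame  # key, count, frequency


def top_clonotypes(table: ClonotypeTable, c: int = DEFAULT_TOP_C,
                   sample_id: Optional[str] = None) -> RankedClonotypes:
    if c < 1:
        raise ValueError("c must be >= 1")
    return RankedClonotypes(
        sample_id=sample_id or table.sample_id or "sample",
        definition=table.definition,
        entries=table.df.head(c).reset_index(drop=True),
    )


@dataclass
class ComparisonReport:
    """Union of per-sample top-c keys with per-sample frequencies (percent)."""

    definition: ClonotypeDefinition
    sample_ids: List[str]
    df: pd.DataFrame               # key, one frequency column per sample, color
    provenance: Dict[str, List[str]]  # key -> sample ids whose top-c contributed


def _check_definitions(tables: Sequence[ClonotypeTable]) -> ClonotypeDefinition:
    first = tables[0].definition
    for t in tables[1:]:
        if t.definition != first:
            raise ValueError("all samples must share one clonotype definition")
    return first


def multi_compare(tables: Sequence[ClonotypeTable], c: int = DEFAULT_TOP_C,
                  sample_ids: Optional[Sequence[str]] = None) -> ComparisonReport:
    """Search every sample's top-c clonotypes in all samples.

    Rows are sorted by descending frequency in the first sample, ties broken
    by key.  Frequencies come from the full tables, not the truncated top
    lists, so a key outside a sample's top-c still shows its true frequency.
    """
    if len(tables) < 2:
        raise ValueError("need at least two samples to compare")
    definition = _check_definitions(tables)
    ids = list(sample_ids) if sample_ids else [
        t.sample_id or f"sample_{i + 1}" for i, t in enumerate(tables)]
    if len(ids) != len(tables):
        raise ValueError("sample_ids length must match tables")

    provenance: Dict[str, List[str]] = {}
    for sid, table in zip(ids, tables):
        for key in table.df.head(c)["key"]:
            provenance.setdefault(key, []).append(sid)

    freq_maps = [dict(zip(t.df["key"], t.df["frequency"])) for t in tables]
    keys = sorted(provenance, key=lambda k: (-freq_maps[0].get(k, 0.0), k))
    data = {"key": keys}
    for sid, fmap in zip(ids, freq_maps):
        data[sid] = [fmap.get(k, 0.0) for k in keys]
    df = pd.DataFrame(data)
    df["color"] = [color_index(k) for k in keys]
    return ComparisonReport(definition=definition, sample_ids=ids, df=df,
                            provenance=provenance)


def pairwise_compare(a: ClonotypeTable, b: ClonotypeTable,
                     c: int = DEFAULT_TOP_C,
                     sample_ids: Optional[Sequence[str]] = None) -> ComparisonReport:
    """Two-sample comparison: each sample's top-c searched in the other."""
    return multi_compare([a, b], c=c, sample_ids=sample_ids)


def track_clonotypes(tables: Sequence[ClonotypeTable],
                     keys: Optional[Sequence[str]] = None,
                     c: int = DEFAULT_TOP_C,
                     sample_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Frequency trajectory of clonotypes across time-ordered samples.

    Returns a long-format frame (key, timepoint, sample_id, frequency), one
    row per key and timepoint, ready for line plotting.  Default key set: the
    union of per-timepoint top-c clonotypes.
    """
    if len(tables) < 2:
        raise ValueError("need at least two timepoints to track")
    definition = _check_definitions(tables)
    del definition  # only validated
    ids = list(sample_ids) if sample_ids else [
        t.sample_id or f"t{i + 1}" for i, t in enumerate(tables)]
    if keys is None:
        seen: Dict[str, None] = {}
        for t in tables:
            for key in t.df.head(c)["key"]:
                seen.setdefault(key)
        keys = sorted(seen)
    freq_maps = [dict(zip(t.df["key"], t.df["frequency"])) for t in tables]
    rows = []
    for key in keys:
        for i, (sid, fmap) in enumerate(zip(ids, freq_maps)):
            rows.append({"key": key, "timepoint": i, "sample_id": sid,
                         "frequency": fmap.get(key, 0.0)})
    return pd.DataFrame(rows, columns=["key", "timepoint", "sample_id", "frequency"])
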