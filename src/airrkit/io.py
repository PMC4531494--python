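"""File formats: annotation summary tables, FASTA split/merge, primer lists.

All tabular inputs and outputs are tab-separated UTF-8 with a header row.
Inputs may be gzip-compressed; compression is detected from the magic bytes,
never from the file name.

FASTA splitting and merging are byte-preserving: chunks keep the source's
exact header lines and sequence line wrapping, so that concatenating the
chunks reproduces the source file byte for byte.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from typing import IO, List, Optional, Sequence

import pandas as pd

from .genes import GeneCall, parse_gene_call
from .primers import IUPAC_CODES, Primer, PrimerSet
from .records import Functionality, SequenceRecord, normalize_functionality

GZIP_MAGIC = b"\x1f\x8b"


class FormatError(ValueError):
    """Malformed input: missing columns, bad FASTA structure, bad alphabet."""


def _is_gzip(path: str) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == GZIP_MAGIC


def open_text(path: str, mode: str = "rt") -> IO[str]:
    """Open a possibly gzip-compressed text file (detection by magic bytes)."""
    if "r" in mode and _is_gzip(path):
        return gzip.open(path, mode, encoding="utf-8")
    if "w" in mode and path.endswith(".gz"):
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------

@dataclass
class SummaryDialect:
    """Column naming for per-read annotation summary tables.

    The defaults define this package's canonical tab-separated dialect; the
    README documents a mapping from IMGT/HighV-QUEST "1_Summary" headers.
    ``d_call`` and the CDR1/2/nucleotide columns are optional because D
    segments do not exist for light-chain-like loci (IGK, IGL, TRA).
    """

    sequence_id: str = "sequence_id"
    functionality: str = "functionality"
    v_call: str = "v_call"
    d_call: str = "d_call"
    j_call: str = "j_call"
    cdr1_aa: str = "cdr1_aa"
    cdr2_aa: str = "cdr2_aa"
    cdr3_aa: str = "cdr3_aa"
    cdr3_nt: str = "cdr3_nt"
    sequence_nt: str = "sequence_nt"
    delimiter: str = "\t"
    missing_value_tokens: frozenset = frozenset({"", "NA", "None"})

    MANDATORY = ("sequence_id", "functionality", "v_call", "j_call", "cdr3_aa")

    def column_order(self) -> List[str]:
        return [
            self.sequence_id, self.functionality, self.v_call, self.d_call,
            self.j_call, self.cdr1_aa, self.cdr2_aa, self.cdr3_aa,
            self.cdr3_nt, self.sequence_nt,
        ]


def _opt(dialect: SummaryDialect, row, col: str) -> Optional[str]:
    val = row.get(col)
    if val is None:
        return None
    val = str(val).strip()
    if val in dialect.missing_value_tokens:
        return None
    return val


def _opt_call(dialect: SummaryDialect, row, col: str) -> Optional[GeneCall]:
    tok = _opt(dialect, row, col)
    return parse_gene_call(tok) if tok else None


def read_summary(path: str, dialect: Optional[SummaryDialect] = None) -> List[SequenceRecord]:
    """Read a per-read annotation summary table into records.

    Raises :class:`FormatError` naming the first mandatory column absent from
    the header.
    """
    dialect = dialect or SummaryDialect()
    with open_text(path) as fh:
        df = pd.read_csv(fh, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    for attr in SummaryDialect.MANDATORY:
        col = getattr(dialect, attr)
        if col not in df.columns:
            raise FormatError(f"mandatory column {col!r} missing from {path}")
    records: List[SequenceRecord] = []
    for row in df.to_dict("records"):
        func = normalize_functionality(row.get(dialect.functionality))
        if func is Functionality.NO_RESULT:
            records.append(SequenceRecord(
                sequence_id=str(row[dialect.sequence_id]), functionality=func,
                sequence_nt=_opt(dialect, row, dialect.sequence_nt),
            ))
            continue
        records.append(SequenceRecord(
            sequence_id=str(row[dialect.sequence_id]),
            functionality=func,
            v_call=_opt_call(dialect, row, dialect.v_call),
            d_call=_opt_call(dialect, row, dialect.d_call),
            j_call=_opt_call(dialect, row, dialect.j_call),
            cdr1_aa=_opt(dialect, row, dialect.cdr1_aa),
            cdr2_aa=_opt(dialect, row, dialect.cdr2_aa),
            cdr3_aa=_opt(dialect, row, dialect.cdr3_aa),
            cdr3_nt=_opt(dialect, row, dialect.cdr3_nt),
            sequence_nt=_opt(dialect, row, dialect.sequence_nt),
        ))
    return records


def write_summary(records: Sequence[SequenceRecord], path: str,
                  dialect: Optional[SummaryDialect] = None) -> None:
    """Write records as a summary table (inverse of :func:`read_summary`)."""
    dialect = dialect or SummaryDialect()

    def cell(value) -> str:
        if value is None:
            return ""
        if isinstance(value, GeneCall):
            return value.raw
        return str(value)

    rows = []
    for r in records:
        rows.append({
            dialect.sequence_id: r.sequence_id,
            dialect.functionality: r.functionality.value,
            dialect.v_call: cell(r.v_call),
            dialect.d_call: cell(r.d_call),
            dialect.j_call: cell(r.j_call),
            dialect.cdr1_aa: cell(r.cdr1_aa),
            dialect.cdr2_aa: cell(r.cdr2_aa),
            dialect.cdr3_aa: cell(r.cdr3_aa),
            dialect.cdr3_nt: cell(r.cdr3_nt),
            dialect.sequence_nt: cell(r.sequence_nt),
        })
    df = pd.DataFrame(rows, columns=dialect.column_order())
    with open_text(path, "wt") as fh:
        df.to_csv(fh, sep=dialect.delimiter, index=False)


# ---------------------------------------------------------------------------
# FASTA split / merge
# ---------------------------------------------------------------------------

@dataclass
class FastaChunkPlan:
    source_path: str
    max_records_per_chunk: int
    chunk_paths: List[str] = field(default_factory=list)
    records_per_chunk: List[int] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return sum(self.records_per_chunk)


def count_fasta_records(path: str) -> int:
    with open_text(path) as fh:
        return sum(1 for line in fh if line.startswith(">"))


def split_fasta(path: str, max_records: int = 500_000,
                out_dir: Optional[str] = None) -> FastaChunkPlan:
    """Split a FASTA file into chunks of at most ``max_records`` records.

    Annotation portals cap submissions (500,000 sequences), hence the default.
    Record order, headers and sequence line wrapping are preserved exactly, so
    concatenating the chunks reproduces the source byte for byte.
    """
    if max_records < 1:
        raise ValueError("max_records must be >= 1")
    out_dir = out_dir or os.path.dirname(os.path.abspath(path))
    base = os.path.basename(path)
    stem = base[:-len(".gz")] if base.endswith(".gz") else base
    stem = os.path.splitext(stem)[0]

    plan = FastaChunkPlan(source_path=path, max_records_per_chunk=max_records)
    out_fh: Optional[IO[str]] = None
    in_chunk = 0
    seen_any_header = False

    def new_chunk() -> IO[str]:
        idx = len(plan.chunk_paths) + 1
        chunk_path = os.path.join(out_dir, f"{stem}.part{idx:03d}.fasta")
        plan.chunk_paths.append(chunk_path)
        plan.records_per_chunk.append(0)
        return open(chunk_path, "w", encoding="utf-8")

    try:
        with open_text(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(">"):
                    seen_any_header = True
                    if out_fh is None or in_chunk == max_records:
                        if out_fh is not None:
                            out_fh.close()
                        out_fh = new_chunk()
                        in_chunk = 0
                    in_chunk += 1
                    plan.records_per_chunk[-1] += 1
                elif line.strip() and not seen_any_header:
                    raise FormatError(
                        f"{path}: sequence data before any FASTA header at line {lineno}")
                if out_fh is not None and (line.startswith(">") or seen_any_header):
                    out_fh.write(line)
    finally:
        if out_fh is not None:
            out_fh.close()
    return plan


def merge_outputs(paths: Sequence[str], out_path: str) -> str:
    """Merge FASTA chunks or same-header tables into a single file.

    FASTA inputs (first non-blank character ``>``) are concatenated verbatim.
    Tables must share an identical header row, written once; a mismatch names
    both offending files.
    """
    if not paths:
        raise ValueError("merge_outputs needs at least one input")

    def first_char(p: str) -> str:
        with open_text(p) as fh:
            for line in fh:
                if line.strip():
                    return line.lstrip()[0]
        return ""

    is_fasta = first_char(paths[0]) == ">"
    with open_text(out_path, "wt") as out:
        if is_fasta:
            for p in paths:
                with open_text(p) as fh:
                    for line in fh:
                        out.write(line)
        else:
            header = None
            header_src = None
            for p in paths:
                with open_text(p) as fh:
                    this_header = fh.readline()
                    if header is None:
                        header, header_src = this_header, p
                        out.write(header)
                    elif this_header != header:
                        raise FormatError(
                            f"header mismatch between {header_src} and {p}")
                    for line in fh:
                        out.write(line)
    return out_path


# ---------------------------------------------------------------------------
# primer lists
# ---------------------------------------------------------------------------

def read_primer_set(path: str, name: Optional[str] = None) -> PrimerSet:
    """Read a primer list from TSV (name/sequence/orientation columns) or
    FASTA (orientation encoded as a ``_fwd`` / ``_rev`` header suffix).

    Sequences are upper-cased and validated against the IUPAC nucleotide
    alphabet; a violation names the offending primer.
    """
    set_name = name or os.path.splitext(os.path.basename(path))[0]
    primers: List[Primer] = []
    with open_text(path) as fh:
        first = fh.readline()
    if first.lstrip().startswith(">"):
        with open_text(path) as fh:
            header = None
            seq_parts: List[str] = []
            entries: List[tuple] = []
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    if header is not None:
                        entries.append((header, "".join(seq_parts)))
                    header, seq_parts = line[1:].strip(), []
                elif line.strip():
                    seq_parts.append(line.strip())
            if header is not None:
                entries.append((header, "".join(seq_parts)))
        for header, seq in entries:
            if header.endswith("_rev"):
                orientation, pname = "reverse", header[:-len("_rev")]
            elif header.endswith("_fwd"):
                orientation, pname = "forward", header[:-len("_fwd")]
            else:
                orientation, pname = "forward", header
            primers.append(_make_primer(pname, seq, orientation))
    else:
        with open_text(path) as fh:
            df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
        for col in ("name", "sequence", "orientation"):
            if col not in df.columns:
                raise FormatError(f"primer list {path} missing column {col!r}")
        for row in df.to_dict("records"):
            primers.append(_make_primer(row["name"].strip(),
                                        row["sequence"],
                                        row["orientation"].strip().lower()))
    return PrimerSet(name=set_name, primers=primers)


def _make_primer(name: str, sequence: str, orientation: str) -> Primer:
    seq = sequence.strip().upper()
    if not seq:
        raise FormatError(f"primer {name!r} has an empty sequence")
    bad = set(seq) - set(IUPAC_CODES)
    if bad:
        raise FormatError(
            f"primer {name!r} contains non-IUPAC character(s) {sorted(bad)}")
    if orientation not in ("forward", "reverse"):
        raise FormatError(f"primer {name!r}: orientation must be forward/reverse, "
                          f"got {orientation!r}")
    return Primer(name=name, sequence=seq, orientation=orientation)
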