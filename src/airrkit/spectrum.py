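"""V-(D)-J combination spectra and germline-reference mapping.

Combination matrices count how often each V-J / V-D / D-J / V-D-J gene (or
allele) combination occurs in a sample.  Mapping a matrix onto the full
spectrum of known germline genes gives every sample identical, naturally
sorted axes — unobserved combinations become explicit zeros — so spectra of
different samples can be compared cell by cell.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .genes import natural_key

logger = logging.getLogger(__name__)

VALID_AXES = {("V", "J"), ("V", "D"), ("D", "J"), ("V", "D", "J")}


@dataclass
class GermlineReference:
    """Known germline genes and alleles per (locus, segment), versioned."""

    version: str
    genes: Dict[Tuple[str, str], Dict[str, List[str]]]  # (locus, seg) -> gene -> alleles

    def gene_names(self, locus: str, segment: str) -> List[str]:
        return sorted(self.genes.get((locus, segment), {}), key=natural_key)

    def allele_names(self, locus: str, segment: str) -> List[str]:
        out = []
        for gene, alleles in self.genes.get((locus, segment), {}).items():
            out.extend(f"{gene}*{a}" for a in alleles)
        return sorted(out, key=natural_key)

    def names(self, locus: str, segment: str, level: str = "gene") -> List[str]:
        return (self.allele_names(locus, segment) if level == "allele"
                else self.gene_names(locus, segment))

    def loci(self) -> List[str]:
        return sorted({locus for locus, _ in self.genes})

    @classmethod
    def from_tsv(cls, path_or_buffer) -> "GermlineReference":
        """Load from TSV with columns locus/segment/gene/alleles; a leading
        ``# germline-version:`` comment line carries the version string."""
        if hasattr(path_or_buffer, "read"):
            lines = path_or_buffer.read().splitlines()
        else:
            with open(path_or_buffer, encoding="utf-8") as fh:
                lines = fh.read().splitlines()
        version = "unversioned"
        data_lines = []
        for line in lines:
            if line.startswith("#"):
                if "germline-version:" in line:
                    version = line.split("germline-version:", 1)[1].strip()
                continue
            if line.strip():
                data_lines.append(line)
        header = data_lines[0].split("\t")
        idx = {name: i for i, name in enumerate(header)}
        genes: Dict[Tuple[str, str], Dict[str, List[str]]] = {}
        for line in data_lines[1:]:
            cells = line.split("\t")
            locus, segment = cells[idx["locus"]], cells[idx["segment"]]
            gene = cells[idx["gene"]]
            alleles = [a for a in cells[idx["alleles"]].split(",") if a]
            bucket = genes.setdefault((locus, segment), {})
            if gene in bucket:
                raise ValueError(f"duplicate gene {gene!r} in reference")
            bucket[gene] = alleles
        return cls(version=version, genes=genes)


def load_bundled_reference() -> GermlineReference:
    """The curated human IG/TR gene list shipped with the package."""
    with (resources.files("airrkit") / "data" / "germline_human.tsv").open() as fh:
        return GermlineReference.from_tsv(fh)


@dataclass
class CombinationMatrix:
    """Counts of gene/allele combinations along 2 or 3 segment axes.

    ``axis_names``, when set (after spectrum mapping), fixes the full ordered
    name list per axis, zeros included.
    """

    axes: Tuple[str, ...]
    level: str
    cells: Dict[Tuple[str, ...], int]
    total: int
    axis_names: Optional[Tuple[List[str], ...]] = None
    unknown_names: Optional[Tuple[List[str], ...]] = None

    def frequency(self, combo: Tuple[str, ...]) -> float:
        return self.cells.get(combo, 0) / self.total if self.total else 0.0

    def marginalize(self, axes: Tuple[str, ...]) -> "CombinationMatrix":
        """Sum counts over the axes not listed (e.g. (V,D,J) -> (V,J))."""
        keep = [self.axes.index(a) for a in axes]
        out: Counter = Counter()
        for combo, count in self.cells.items():
            out[tuple(combo[i] for i in keep)] += count
        return CombinationMatrix(axes=tuple(axes), level=self.level,
                                 cells=dict(out), total=self.total)

    def to_frame(self) -> pd.DataFrame:
        if self.axis_names is not None:
            combos = list(product(*self.axis_names))
        else:
            combos = sorted(self.cells, key=lambda c: tuple(natural_key(x) for x in c))
        rows = {axis: [c[i] for c in combos] for i, axis in enumerate(self.axes)}
        counts = [self.cells.get(c, 0) for c in combos]
        rows["count"] = counts
        rows["frequency"] = [n / self.total if self.total else 0.0 for n in counts]
        return pd.DataFrame(rows)


_SEGMENT_ATTR = {"V": "v_call", "D": "d_call", "J": "j_call"}


def combination_matrix(records: Sequence, axes: Tuple[str, ...] = ("V", "D", "J"),
                       level: str = "gene") -> CombinationMatrix:
    """Tally combinations over records carrying calls for every axis segment."""
    axes = tuple(axes)
    if axes not in VALID_AXES:
        raise ValueError(f"axes must be one of {sorted(VALID_AXES)}, got {axes}")
    cells: Counter = Counter()
    total = 0
    for r in records:
        calls = [getattr(r, _SEGMENT_ATTR[a]) for a in axes]
        if any(c is None for c in calls):
            continue
        cells[tuple(c.label(level) for c in calls)] += 1
        total += 1
    return CombinationMatrix(axes=axes, level=level, cells=dict(cells), total=total)


def _matrix_locus(matrix: CombinationMatrix) -> Optional[str]:
    for combo in matrix.cells:
        return combo[0][:3]
    return None


def map_to_spectrum(matrix: CombinationMatrix, reference: GermlineReference,
                    locus: Optional[str] = None) -> CombinationMatrix:
    """Re-index a matrix onto the full known germline spectrum.

    Axes enumerate every known gene (or allele) of the reference in natural
    order; observed cells keep their counts and everything else is an explicit
    zero.  Observed names absent from the reference are not dropped: they are
    logged and appended after the known names ("unknown" section), so the
    total is conserved.
    """
    locus = locus or _matrix_locus(matrix)
    if locus is None or not any(l == locus for l in reference.loci()):
        raise ValueError(f"locus {locus!r} not present in reference "
                         f"(knows {reference.loci()})")
    axis_names: List[List[str]] = []
    unknown_names: List[List[str]] = []
    for i, segment in enumerate(matrix.axes):
        known = reference.names(locus, segment, matrix.level)
        observed = {combo[i] for combo in matrix.cells}
        unknown = sorted(observed - set(known) - {"-"}, key=natural_key)
        if unknown:
            logger.warning("%s %s name(s) %s not in germline reference %s; "
                           "kept under the unknown section",
                           locus, segment, unknown, reference.version)
        names = list(known)
        if "-" in observed:  # absent-D placeholder on the D axis
            names.append("-")
        names.extend(unknown)
        axis_names.append(names)
        unknown_names.append(unknown)
    return CombinationMatrix(axes=matrix.axes, level=matrix.level,
                             cells=dict(matrix.cells), total=matrix.total,
                             axis_names=tuple(axis_names),
                             unknown_names=tuple(unknown_names))


def filter_by_threshold(matrix: CombinationMatrix,
                        min_frequency: float) -> CombinationMatrix:
    """Keep cells with frequency >= min_frequency.

    The total is deliberately NOT recomputed: surviving frequencies stay
    interpretable as fractions of the original sample.
    """
    if not 0 <= min_frequency <= 1:
        raise ValueError("min_frequency must be in [0, 1]")
    cells = {c: n for c, n in matrix.cells.items()
             if matrix.total and n / matrix.total >= min_frequency}
    return CombinationMatrix(axes=matrix.axes, level=matrix.level, cells=cells,
                             total=matrix.total, axis_names=matrix.axis_names,
                             unknown_names=matrix.unknown_names)
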