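"""IMGT-style gene/allele nomenclature parsing.

A gene call as emitted by V(D)J annotation pipelines looks like
``"Homsap TRBV6-4*01 F"``: an optional species prefix, the gene name
(locus + segment letter + family/gene numbers), an optional ``*``-delimited
allele, and an optional trailing functionality flag (F / ORF / P).
Annotation tools may list several comma-separated alternative calls for one
read; by convention the first listed is the highest-scoring hit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

LOCI = ("IGH", "IGK", "IGL", "TRA", "TRB", "TRG", "TRD")
SEGMENTS = ("V", "D", "J")

_GENE_RE = re.compile(r"^(IG[HKL]|TR[ABGD])([VDJ])(\S*)$")
_FLAGS = {"F", "ORF", "P", "(F)", "[F]", "(P)", "(ORF)"}


class GeneParseError(ValueError):
    """Raised when a token carries no recognizable locus+segment gene name."""


@dataclass(frozen=True, slots=True)
class GeneCall:
    """One parsed gene/allele call."""

    raw: str
    locus: str
    segment: str
    gene: str
    allele: Optional[str] = None
    species: Optional[str] = None
    functionality: Optional[str] = None

    def label(self, level: str = "gene") -> str:
        """Name at the requested resolution: ``"TRBV6-4"`` or ``"TRBV6-4*01"``."""
        if level == "allele" and self.allele is not None:
            return f"{self.gene}*{self.allele}"
        return self.gene

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label("allele")


def parse_gene_call(raw: str) -> GeneCall:
    """Parse one gene-call token.

    When several comma-separated alternatives are present the first listed
    (highest-scoring) call is taken.  Raises :class:`GeneParseError` when no
    locus+segment pattern is found.
    """
    if raw is None or not raw.strip():
        raise GeneParseError("empty gene-call token")
    first = raw.split(",")[0].strip()
    # IMGT writes alternatives as "X, or Y"; the leading "or" belongs to later
    # alternatives only, but strip it defensively.
    if first.lower().startswith("or "):
        first = first[3:].strip()
    tokens = first.split()
    species = None
    functionality = None
    gene_token = None
    for tok in tokens:
        m = _GENE_RE.match(tok)
        if m and gene_token is None:
            gene_token = tok
        elif gene_token is None:
            species = tok
        elif tok in _FLAGS:
            functionality = tok.strip("()[]")
    if gene_token is None:
        raise GeneParseError(f"no recognizable gene name in token {raw!r}")
    m = _GENE_RE.match(gene_token)
    locus, segment = m.group(1), m.group(2)
    allele = None
    name = gene_token
    if "*" in gene_token:
        name, allele = gene_token.split("*", 1)
        if not allele or not allele.replace("-", "").isdigit():
            # tolerate non-numeric allele text but keep it verbatim
            allele = allele or None
    return GeneCall(
        raw=raw.strip(),
        locus=locus,
        segment=segment,
        gene=name,
        allele=allele,
        species=species,
        functionality=functionality,
    )


_NAT_SPLIT = re.compile(r"(\d+)")


def natural_key(name: str):
    """Sort key ordering gene names by numeric fields: TRBV2 < TRBV6-4 < TRBV12-3."""
    return tuple(int(p) if p.isdigit() else p for p in _NAT_SPLIT.split(name))
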