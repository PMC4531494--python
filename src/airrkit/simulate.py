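"""Synthetic multiplex-PCR repertoires with known ground truth.

The generator emulates what an annotated amplicon sequencing run of one locus
looks like: a fixed pool of true clonotypes (distinct CDR3s with V-(D)-J
assignments drawn from a germline reference), a skewed clonal abundance
distribution, a functionality mix, and per-read substitution errors that turn
a fraction of reads into spurious unique clonotypes — the phenomenon the
diversity model's linear ``k*n`` term accounts for.

Every quantity an analysis stage estimates (richness, abundances, gene usage,
functionality counts) is therefore known exactly, which makes end-to-end
testing possible without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as akio
from .genes import parse_gene_call
from .records import Functionality, SequenceRecord
from .spectrum import GermlineReference, load_bundled_reference

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"

# productive, unproductive, unknown, no_result; defaults reflect a typical
# heavy-chain amplicon run (most reads productive, a few percent unalignable)
DEFAULT_MIX = (0.828, 0.104, 0.005, 0.063)
_CLASSES = (Functionality.PRODUCTIVE, Functionality.UNPRODUCTIVE,
            Functionality.UNKNOWN, Functionality.NO_RESULT)


@dataclass
class SimulationConfig:
    n_clonotypes: int = 1000
    abundance_model: str = "geometric"   # uniform | geometric | lognormal
    abundance_param: float = 0.995       # geometric ratio / lognormal sigma
    n_reads: int = 100_000
    error_rate: float = 0.001            # P(read acquires one CDR3 substitution)
    functionality_mix: Tuple[float, float, float, float] = DEFAULT_MIX
    locus: str = "TRB"
    reference: Optional[GermlineReference] = None
    cdr3_length_range: Tuple[int, int] = (8, 16)
    read_flank_lengths: Tuple[int, int] = (60, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")
        if abs(sum(self.functionality_mix) - 1.0) > 1e-9:
            raise ValueError("functionality_mix must sum to 1")
        lo, hi = self.cdr3_length_range
        if lo < 1 or hi < lo:
            raise ValueError("bad cdr3_length_range")
        if self.n_clonotypes > 20 ** lo:
            raise ValueError("key space exhausted: too many clonotypes for the "
                             "minimum CDR3 length")


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    cdr3_keys: List[str]                  # per clonotype
    abundances: np.ndarray                # realized reads per clonotype
    vdj: List[Tuple[str, str, str]]       # raw V/D/J call strings per clonotype
    read_clonotype: np.ndarray            # per read: source clonotype index
    read_error: np.ndarray                # per read: error applied?
    read_functionality: List[Functionality]

    def abundance_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "clonotype": range(len(self.cdr3_keys)),
            "cdr3_aa": self.cdr3_keys,
            "abundance": self.abundances,
        })


def _distinct_cdr3s(rng: np.random.Generator, n: int,
                    length_range: Tuple[int, int]) -> List[str]:
    keys: List[str] = []
    seen = set()
    lo, hi = length_range
    while len(keys) < n:
        length = int(rng.integers(lo, hi + 1))
        key = "".join(rng.choice(list(AA), size=length))
        if key not in seen:
            seen.add(key)
            keys.append(key)
    return keys


def _abundance_probs(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    m = cfg.n_clonotypes
    if cfg.abundance_model == "uniform":
        w = np.ones(m)
    elif cfg.abundance_model == "geometric":
        w = cfg.abundance_param ** np.arange(m)
    elif cfg.abundance_model == "lognormal":
        w = rng.lognormal(mean=0.0, sigma=cfg.abundance_param, size=m)
    else:
        raise ValueError(f"unknown abundance_model {cfg.abundance_model!r}")
    return w / w.sum()


def simulate_repertoire(config: Optional[SimulationConfig] = None
                        ) -> Tuple[List[SequenceRecord], GroundTruth]:
    """Generate annotated reads plus the ground truth behind them.

    Reads are multinomial draws over the clonotype abundance distribution.
    With probability ``error_rate`` a read's CDR3 gets one amino-acid
    substitution (and a matching nucleotide change), usually creating a
    spurious unique clonotype.  No-result reads keep their raw sequence but
    lose all annotation-derived fields, as real unalignable reads do.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    reference = cfg.reference or load_bundled_reference()

    cdr3_keys = _distinct_cdr3s(rng, cfg.n_clonotypes, cfg.cdr3_length_range)

    v_genes = reference.genes[(cfg.locus, "V")]
    j_genes = reference.genes[(cfg.locus, "J")]
    d_genes = reference.genes.get((cfg.locus, "D"), {})

    def pick_call(genes: Dict[str, List[str]]) -> str:
        names = sorted(genes)
        gene = names[int(rng.integers(len(names)))]
        allele = genes[gene][int(rng.integers(len(genes[gene])))]
        return f"Homsap {gene}*{allele} F"

    clono_vdj: List[Tuple[str, str, str]] = []
    clono_cdr12: List[Tuple[str, str]] = []
    clono_cdr3_nt: List[str] = []
    clono_flanks: List[Tuple[str, str]] = []
    pre_len, post_len = cfg.read_flank_lengths
    for key in cdr3_keys:
        clono_vdj.append((pick_call(v_genes),
                          pick_call(d_genes) if d_genes else "",
                          pick_call(j_genes)))
        clono_cdr12.append(("".join(rng.choice(list(AA), size=6)),
                            "".join(rng.choice(list(AA), size=7))))
        clono_cdr3_nt.append("".join(rng.choice(list(NT), size=3 * len(key))))
        clono_flanks.append(("".join(rng.choice(list(NT), size=pre_len)),
                             "".join(rng.choice(list(NT), size=post_len))))

    probs = _abundance_probs(rng, cfg)
    abundances = rng.multinomial(cfg.n_reads, probs)
    read_clono = np.repeat(np.arange(cfg.n_clonotypes), abundances)
    rng.shuffle(read_clono)
    read_error = rng.random(cfg.n_reads) < cfg.error_rate
    func_idx = rng.choice(4, size=cfg.n_reads, p=list(cfg.functionality_mix))

    records: List[SequenceRecord] = []
    functionalities: List[Functionality] = []
    for i in range(cfg.n_reads):
        ci = int(read_clono[i])
        func = _CLASSES[int(func_idx[i])]
        functionalities.append(func)
        cdr3_aa = cdr3_keys[ci]
        cdr3_nt = clono_cdr3_nt[ci]
        if read_error[i]:
            pos = int(rng.integers(len(cdr3_aa)))
            old = cdr3_aa[pos]
            new = AA[(AA.index(old) + 1 + int(rng.integers(19))) % 20]
            cdr3_aa = cdr3_aa[:pos] + new + cdr3_aa[pos + 1:]
            nt_pos = 3 * pos
            old_nt = cdr3_nt[nt_pos]
            new_nt = NT[(NT.index(old_nt) + 1 + int(rng.integers(3))) % 4]
            cdr3_nt = cdr3_nt[:nt_pos] + new_nt + cdr3_nt[nt_pos + 1:]
        pre, post = clono_flanks[ci]
        read_nt = pre + cdr3_nt + post
        if func is Functionality.NO_RESULT:
            records.append(SequenceRecord(
                sequence_id=f"read{i:07d}", functionality=func,
                sequence_nt=read_nt))
            continue
        v_raw, d_raw, j_raw = clono_vdj[ci]
        cdr1, cdr2 = clono_cdr12[ci]
        records.append(SequenceRecord(
            sequence_id=f"read{i:07d}",
            functionality=func,
            v_call=parse_gene_call(v_raw),
            d_call=parse_gene_call(d_raw) if d_raw else None,
            j_call=parse_gene_call(j_raw),
            cdr1_aa=cdr1, cdr2_aa=cdr2,
            cdr3_aa=cdr3_aa, cdr3_nt=cdr3_nt, sequence_nt=read_nt,
        ))

    truth = GroundTruth(
        cdr3_keys=cdr3_keys,
        abundances=abundances,
        vdj=clono_vdj,
        read_clonotype=read_clono,
        read_error=read_error,
        read_functionality=functionalities,
    )
    return records, truth


def write_fixture(records: Sequence[SequenceRecord], truth: GroundTruth,
                  directory: str) -> Dict[str, str]:
    """Write a simulated repertoire as plain-text files.

    Produces a summary table (canonical dialect), a FASTA of the raw reads,
    and the ground-truth abundance table; contents are deterministic given the
    records (and hence the simulation seed).
    """
    import os

    os.makedirs(directory, exist_ok=True)
    paths = {
        "summary": os.path.join(directory, "summary.tsv"),
        "reads": os.path.join(directory, "reads.fasta"),
        "truth": os.path.join(directory, "ground_truth.tsv"),
    }
    akio.write_summary(records, paths["summary"])
    with open(paths["reads"], "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f">{r.sequence_id}\n")
            seq = r.sequence_nt or ""
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    truth.abundance_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
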