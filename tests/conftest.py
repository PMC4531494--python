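import pytest

from airrkit import (
    ClonotypeDefinition,
    Functionality,
    SequenceRecord,
    SimulationConfig,
    parse_gene_call,
    simulate_repertoire,
)


def make_record(i, func=Functionality.PRODUCTIVE, v=None, d=None, j=None,
                cdr3_aa=None, cdr3_nt=None, seq=None, cdr1=None, cdr2=None):
    return SequenceRecord(
        sequence_id=f"r{i}",
        functionality=func,
        v_call=parse_gene_call(v) if v else None,
        d_call=parse_gene_call(d) if d else None,
        j_call=parse_gene_call(j) if j else None,
        cdr1_aa=cdr1, cdr2_aa=cdr2,
        cdr3_aa=cdr3_aa, cdr3_nt=cdr3_nt, sequence_nt=seq,
    )


@pytest.fixture
def small_records():
    """Four annotated reads plus one no-result read."""
    return [
        make_record(0, v="Homsap TRBV6-4*01 F", d="Homsap TRBD2*01 F",
                    j="Homsap TRBJ2-1*01 F", cdr3_aa="ASSMGQNNEQF",
                    cdr3_nt="GCTAGCAGC", seq="AAACCCGCTAGCAGCTTT"),
        make_record(1, v="Homsap TRBV6-4*02 F", d="Homsap TRBD2*01 F",
                    j="Homsap TRBJ2-1*01 F", cdr3_aa="ASSMGQNNEQF",
                    cdr3_nt="GCTAGCAGC", seq="AAACCCGCTAGCAGCTTT"),
        make_record(2, func=Functionality.UNPRODUCTIVE,
                    v="Homsap TRBV12-3*01 F", d="Homsap TRBD1*01 F",
                    j="Homsap TRBJ2-1*01 F", cdr3_aa="ASSDD*RGGTDTQY",
                    cdr3_nt="TTTGGGCCC", seq="CCCTTTGGGCCCAAA"),
        make_record(3, func=Functionality.UNKNOWN,
                    v="Homsap TRBV12-3*01 F", j="Homsap TRBJ2-7*01 F",
                    cdr3_aa="ASSVSGEGSDEQF", seq="GGGAAATTT"),
        make_record(4, func=Functionality.NO_RESULT, seq="NNNNACGT"),
    ]


@pytest.fixture(scope="session")
def sim_repertoire():
    """2,000 reads from 50 clonotypes, error-free, all-productive: ground
    truth and observed clonotypes coincide exactly."""
    cfg = SimulationConfig(n_clonotypes=50, n_reads=2000, error_rate=0.0,
                           functionality_mix=(1.0, 0.0, 0.0, 0.0), seed=42)
    return simulate_repertoire(cfg)


@pytest.fixture
def default_definition():
    return ClonotypeDefinition()
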