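"""Multiplex-PCR primer efficiency from read composition.

Constructs amplicon reads beginning with known forward primers in a 60/25/15
mix, plus one panel primer that produced no product, and reports each
primer's exact-substring hit frequency — the quantity used to spot failing
primers in a multiplex panel.
"""

from airrkit import Primer, PrimerSet, SequenceRecord, match_primers

PRIMERS = {
    "V-fam1": "CCTCAGTGAAGGTCTCC",
    "V-fam2": "GGTCACCGTCTCCTCAG",
    "V-fam3": "TTCAGTGAGACACAGAG",
}
MIX = {"V-fam1": 60, "V-fam2": 25, "V-fam3": 15}

reads = []
i = 0
for name, count in MIX.items():
    for _ in range(count):
        reads.append(SequenceRecord(sequence_id=f"r{i}",
                                    sequence_nt=PRIMERS[name] + "ACGT" * 15))
        i += 1

panel = PrimerSet(name="demo-panel", primers=(
    [Primer(n, s, "forward") for n, s in PRIMERS.items()]
    + [Primer("V-fam7", "TTGGTATTACTGTGCGA", "forward")]))

report = match_primers(reads, panel)
print(f"reads searched: {report.reads_searched}")
print(report.to_frame().to_string(index=False))
print("\nA primer at frequency 0 produced no amplicons — a candidate for "
      "panel redesign.")
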