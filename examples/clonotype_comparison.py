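"""Compare and track clonotypes across timepoints.

Builds three longitudinal samples that share two persistently expanded CDR3
clonotypes, then runs the multi-sample comparer (each sample's top clonotypes
searched in all samples) and prints the per-timepoint frequency trajectories.
"""

from airrkit import ClonotypeDefinition, multi_compare, table_from_keys, track_clonotypes

definition = ClonotypeDefinition()
persistent = {"ASSVSGEGSDEQF": 30, "ASSMGQNNEQF": 20}

tables = []
for t in range(3):
    counts = dict(persistent)
    counts[f"TRANSIENT{t}"] = 25  # expands at one timepoint only
    counts.update({f"BG{t}{i}": 1 for i in range(25)})  # background singletons
    keys = [k for k, n in counts.items() for _ in range(n)]
    tables.append(table_from_keys(keys, definition, sample_id=f"month_{3 * t}"))

report = multi_compare(tables, c=3)
print("top-3 union, frequency (%) per timepoint:")
print(report.df.drop(columns="color").to_string(index=False))

traj = track_clonotypes(tables, keys=list(persistent))
print("\ntrajectories of the persistent clonotypes:")
print(traj.to_string(index=False))
print("\nClonotypes at high frequency in every column are stable expansions; "
      "frequencies collapsing to 0 mark transient responses.")
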