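"""V-(D)-J combination spectrum mapped on the germline gene space.

Simulates a small beta-chain sample, tabulates V-J gene combinations, maps
them onto the full spectrum of known germline genes (so different samples get
identical, comparable axes), and applies a frequency threshold to keep only
the dominant combinations.
"""

from airrkit import (SimulationConfig, combination_matrix, filter_by_threshold,
                     load_bundled_reference, map_to_spectrum,
                     simulate_repertoire)

records, _ = simulate_repertoire(SimulationConfig(
    n_clonotypes=40, n_reads=5000, seed=3))

matrix = combination_matrix(records, axes=("V", "J"), level="gene")
reference = load_bundled_reference()
mapped = map_to_spectrum(matrix, reference)

df = mapped.to_frame()
print(f"germline reference: {reference.version}")
print(f"V-J grid: {len(mapped.axis_names[0])} V genes x "
      f"{len(mapped.axis_names[1])} J genes = {len(df)} cells "
      f"({(df['count'] > 0).sum()} observed, rest explicit zeros)")

dominant = filter_by_threshold(mapped, 0.05)
print("\ncombinations carrying >= 5% of the sample:")
print(dominant.to_frame().query("count > 0").to_string(index=False))
print("\nBecause every sample is mapped on the same germline axes, these "
      "tables can be compared cell-by-cell across samples or timepoints.")
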