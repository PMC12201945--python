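"""Sequential interaction (SI) from spent-media exchange growth counts.

Simulates the two-stage assay: each primary strain grows on algal spent
medium, the filtrate is passed to each secondary strain, and the
secondary's cell counts are compared with growth on unprocessed algal
spent medium. SI = G(s,p)/G(s,PtSM) - 1: -1 means the primary left
nothing to grow on, 0 no effect, positive values facilitation.
"""

from phycoflow import (
    SequentialDesign,
    classify_interaction,
    generate_sequential,
    interaction_tally,
    si_matrix,
)

growth = generate_sequential(SequentialDesign(n_strains=10, seed=7))
si = si_matrix(growth)
print("SI matrix (rows: primary, columns: secondary):")
print(si.values.round(2).to_string())

tally = interaction_tally(si)
print(f"\nOf {tally['n_pairs']} ordered strain pairs, "
      f"{tally['competitive']} have negative SI (competition dominated), "
      f"{tally['facilitative']} positive (facilitation).")

pair = ("S02", "S05")
value = si.get(*pair)
print(f"\nExample: primary {pair[0]} on secondary {pair[1]}: "
      f"SI = {value:.2f} -> {classify_interaction(value)}")
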