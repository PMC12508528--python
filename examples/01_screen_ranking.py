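"""Rank compounds by their ability to down-regulate a chemokine signature.

Simulates a plate screen with spiked hit compounds, normalizes by stable
genes, removes plate batch effects and ranks the library against same-plate
DMSO controls.
"""

from sig2screen import pipeline

res = pipeline.run_screen_arc(
    {
        "screen": {"n_compounds": 500, "n_hits": 5, "hit_log2fc": -1.5,
                   "replicates_per_compound": 3},
        "top_k": 10,
    },
    out_dir="scratch/example_screen",
    seed=1,
)

top = res["ranking"].head(10)
print(top[["compound_id", "score", "log2fc_CXCL1", "log2fc_CXCL2", "rank", "true_hit"]]
      .to_string(index=False))
print(f"\n{int(top['true_hit'].sum())} of 5 spiked hits in the top 10.")
# The score is the mean over CXCL1/CXCL2 of (-log10 p) x (-log2FC): large
# positive means strong, statistically reliable down-regulation of both genes.
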