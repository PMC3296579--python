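"""A miniature power study: a few tests across two odds-ratio settings.

A desk-scale version of the published power tables (30 replicates, 100
permutations) for scenario B, where all causal rare effects point the
same way.  Expect wSC on top, the unselective burden tests lower, and
roughly monotone power in OR.  Runs in about a minute.
"""

from collapsar import PermutationPlan
from collapsar.study import run_table

panel = ["R_sum", "RsumSC", "B_wSum", "B_wSC", "B_wSCd"]
table = run_table(
    "B", [1.6, 2.8], panel, n_reps=30,
    plan=PermutationPlan(n_perm=100, seed=0), base_seed=12,
)

df = table.to_frame().pivot(index="test", columns="or", values="power")
print("rejection proportion at alpha=0.05 (30 replicates, MC SE ~0.09):")
print(df.reindex(panel).to_string(float_format="%.2f"))
print("\nColumns are the OR parameter of the causal rare variants; each cell")
print("is the fraction of simulated regions the test declared associated.")
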