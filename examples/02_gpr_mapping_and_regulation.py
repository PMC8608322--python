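"""From gene fold changes to regulated reaction sets.

Shows the Min/Max rule on GPR expressions — enzyme complexes (AND) change as
their least-changed subunit, isozymes (OR) as their most-changed member —
and the two ways of selecting the up/downregulated reaction sets.
"""

from deltafba import ExpressionDelta, map_all_reactions, parse_gpr, reaction_fold_change
from deltafba.model_io import load_model, split_reversible
from deltafba.regulation import apply_knockout, select_regulated

delta = ExpressionDelta({"b4025": 2.5, "b3916": 0.4, "b1723": 1.6,
                         "b1779": 0.3, "b2926": 1.1})

for rule in ["b4025", "b3916 or b1723", "b1779 and b2926"]:
    fc = reaction_fold_change(parse_gpr(rule), delta)
    print(f"rule {rule!r:24s} -> reaction fold change {fc}")

# on a model: map every reaction, then select regulation sets
net = load_model("tests/data/mini_ecoli.json")
split = split_reversible(net)
rdelta = map_all_reactions(net, delta)
reg = select_regulated(rdelta, split, mode="fc_cutoff", param=1.0)
up = [split.split_ids[k] for k in reg.r_up]
down = [split.split_ids[k] for k in reg.r_down]
print(f"\nupregulated reactions:   {sorted(up)}")
print(f"downregulated reactions: {sorted(down)}")

# a gene-deletion experiment: the knocked-out reaction joins the
# downregulated set with weight 10, overriding expression evidence
apply_knockout(reg, split, ["PGI"], weight=10.0)
print(f"PGI weight after knockout: {reg.r_down[split.split_index('PGI')]}")
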