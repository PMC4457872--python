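#!/usr/bin/env python
"""Generate the three synthetic study families and their ground truth.

Writes, under scratch/families/: a FASTA alignment, taxon table and truth
manifest per scenario, plus a two-chain toy dimer structure — for
inspection and for ad-hoc CLI runs.  The later drivers do not read these
files: they regenerate the same families deterministically from the seeds,
so the pipeline is reproducible from code alone.
"""

import json
from pathlib import Path

from dcapipe.msa import write_alignment, write_taxon_table
from dcapipe.structures import write_contact_map
from dcapipe.synth import (
    clade_scenario,
    gibbs_sample,
    planted_model,
    toy_structure,
    two_state_scenario,
    _sample_pairs,
)
import numpy as np

SEED = 1
OUT = Path("scratch/families")
OUT.mkdir(parents=True, exist_ok=True)

# single family with planted long-range couplings
rng = np.random.default_rng(SEED)
pairs = _sample_pairs(rng, 40, 25)
model = planted_model(40, pairs, seed=SEED)
aln = gibbs_sample(model, 5000, seed=SEED + 100)
write_alignment(aln, OUT / "planted_msa.fasta")
(OUT / "planted_truth.json").write_text(json.dumps({"pairs": pairs}, indent=2) + "\n")
print(f"planted family: M={aln.M}, L={aln.L}, {len(pairs)} planted pairs")

# two-conformer family
sc = two_state_scenario(seed=SEED)
aln2 = gibbs_sample(sc.model, 5000, seed=SEED + 50)
write_alignment(aln2, OUT / "two_state_msa.fasta")
for name, cm in sc.maps.items():
    write_contact_map(cm, OUT / f"two_state_map_{name}.tsv")
(OUT / "two_state_truth.json").write_text(json.dumps(
    {"contacts_a": sc.contacts_a, "contacts_b": sc.contacts_b}, indent=2) + "\n")
print(f"two-state family: M={aln2.M}, L={aln2.L}, "
      f"{len(sc.union_pairs)} coupled pairs (union of A and B)")

# clade-structured family with bacteria-only interface couplings
sc3, aln3 = clade_scenario(seed=SEED)
write_alignment(aln3, OUT / "clade_msa.fasta")
write_taxon_table(aln3, OUT / "clade_taxon.tsv")
write_contact_map(sc3.maps["union"], OUT / "clade_map_union.tsv")
(OUT / "clade_truth.json").write_text(json.dumps(
    {"core": sc3.contacts_a, "interface": sc3.interface}, indent=2) + "\n")
print(f"clade family: M={aln3.M}, L={aln3.L}, "
      f"{len(sc3.contacts_a)} core + {len(sc3.interface)} interface pairs")

# toy dimer structure realizing a mix of intra- and inter-chain contacts
dimer_pairs = [(1, 12), (5, 18), (3, 8), (14, 19), (2, 16)]
pdb, truth = toy_structure(dimer_pairs, 20, seed=SEED, split=10)
(OUT / "toy_dimer.pdb").write_text(pdb)
write_contact_map(truth, OUT / "toy_dimer_truth.tsv")
inter = [(i, j) for i, j in dimer_pairs if (i < 10) != (j < 10)]
print(f"toy dimer: 20 residues in two chains, {len(inter)} inter-chain contacts planted")
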