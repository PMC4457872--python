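# dcapipe

Coevolution-based contact analysis for protein families that live in more
than one conformation. `dcapipe` infers a 21-state Potts model from a
multiple sequence alignment by symmetric pseudo-likelihood maximization,
turns the inferred couplings into ranked residue–residue contact
predictions, and then appraises those predictions against atomic
structures: single-conformer contact maps, multi-conformer union maps,
contact-graph shortest paths, exact interface-enrichment statistics, and
taxon-conditional weight sweeps that ask *which clade carries a signal*.

It is written for structural bioinformaticians studying allostery and
oligomerization in deeply conserved families (the motivating case is the
Hsp70 chaperone fold, with its ATP/ADP conformational cycle and a
candidate homo-dimer interface), and it ships a first-class synthetic-data
module so the entire pipeline is testable end-to-end against planted
ground truth, without downloading a single structure.

## The model

A family alignment with M rows and L columns is modelled as a pairwise
Markov random field over the 21-state alphabet (20 amino acids + gap):

    P(S) = (1/Z) exp( Σ_i h_i(s_i) + Σ_{i<j} J_ij(s_i, s_j) )

Parameters are learned by minimizing the regularized negative
log-pseudo-likelihood — the sum over rows and sites of
−log P(s_i | s_{\i}) — which needs only single-site conditionals, never
the partition function Z. The symmetric variant is used: one shared
coupling block per unordered pair of columns. Fitting is deterministic
L-BFGS from the all-zero model, with L2 penalties λ_h = λ_J = 0.01 on the
per-sequence-averaged objective.

Couplings are scored per pair as the Frobenius norm of the 21×21 block in
the zero-sum gauge, then the average product correction (APC) is
subtracted to suppress per-position background. The top-N pairs at
sequence separation ≥ 5 are the contact predictions.

Downstream, each prediction gets the shortest-path (SP) length between
its two residues on the contact graph of a structure (contacts: minimal
heavy-atom distance < 8.5 Å). SP = 1 is a true positive; SP = 2 means the
pair shares a contacting neighbour; large SP flags predictions
incompatible with that conformer — which is exactly where allosteric and
interface contacts hide. Interface hits among the top predictions are
tested with the exact hypergeometric upper tail

    P_k = Σ_{k'≥k} C(K, k') C(N−K, n−k') / C(N, n).

## Worked example

The analysis drivers run the whole pipeline on synthetic families with
planted truth:

```
$ python analysis/05_taxon_weight_sweep.py
W_E = 0.1: relative interface strength 0.954, TP rate 100%
W_E = 0.3: relative interface strength 0.767, TP rate 100%
W_E = 0.5: relative interface strength 0.558, TP rate 100%
W_E = 0.7: relative interface strength 0.300, TP rate 100%
W_E = 0.9: relative interface strength 0.046, TP rate 75%

bacteria only (W_E = 0): 6/6 planted interface pairs still in the top predictions
```

Here six "interface" couplings exist only in the bacteria-labelled half
of a clade-structured family. As the eukaryote weight fraction W_E grows,
the mean APC score of those six pairs (normalized by the mean over the
reference top predictions) collapses from 0.95 to 0.05, while overall
contact prediction stays intact in the balanced range — the planted
analogue of reading a dimer interface as a bacterial trait.

The enrichment arithmetic at real family scale (624 columns, 624
predictions, 241 interface pairs, 6 hits) is one CLI call:

```
$ dcapipe enrich --n 624 --k 6 --total 194376 --targets 241
P(X >= 6) = 0.000144416  (n=624, K=241, N=194376)
```

i.e. six interface hits among 624 predictions are far more than chance
(P ≈ 1.44×10⁻⁴).

Other drivers: `01_simulate_families.py` (writes the synthetic families
under `scratch/`), `02_contact_recovery.py` (PPV of top predictions vs 25
planted couplings: 1.00 on all seeds), `03_two_conformer_appraisal.py`
(single-state TP 60% vs union TP 100% — the two-conformer signature),
`04_interface_enrichment.py`. End-to-end runs from a TOML config:
`dcapipe run --config cfg.toml --seed 1 --out run_dir`.

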