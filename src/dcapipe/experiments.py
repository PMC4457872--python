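"""Headline experiments on synthetic families with planted ground truth.

Each function runs one self-contained study end-to-end through the library
(sampling -> filtering-free fit -> scoring -> ranking -> appraisal) and
returns plain dictionaries of measured quantities.  The analysis drivers,
the test suite, and the acceptance script all call these, so every
reported number is recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from .msa import TaxonWeighting, taxon_weights
from .potts import apc, fit_plm, frobenius_scores, rank_predictions
from .synth import (
    _sample_pairs,
    clade_scenario,
    gibbs_sample,
    planted_model,
    two_state_scenario,
)
from .topology import annotate, hypergeom_upper_tail, union_sp, weight_sweep

# study conditions for the planted-recovery benchmark
RECOVERY_L = 40
RECOVERY_N_PAIRS = 25
RECOVERY_M = 5000
COUPLING_SCALE = 1.0


def planted_recovery(seed: int, L: int = RECOVERY_L, n_pairs: int = RECOVERY_N_PAIRS,
                     M: int = RECOVERY_M, tol: float = 1e-5) -> dict:
    """Plant ``n_pairs`` couplings, sample M rows, refit, and measure the
    positive predictive value of the top-``n_pairs`` predictions."""
    rng = np.random.default_rng(seed)
    pairs = _sample_pairs(rng, L, n_pairs)
    model = planted_model(L, pairs, coupling_scale=COUPLING_SCALE, seed=seed)
    aln = gibbs_sample(model, M, seed=seed + 100)
    fitted = fit_plm(aln, tol=tol)
    preds = rank_predictions(apc(frobenius_scores(fitted)), n_top=n_pairs, min_sep=5)
    hits = sum(1 for i, j, _ in preds if (i, j) in set(pairs))
    return {"seed": seed, "n_pairs": n_pairs, "hits": hits, "ppv": hits / n_pairs}


def two_state_recovery(seed: int, L: int = 40, n_pairs_per_state: int = 12,
                       n_shared: int = 4, M: int = RECOVERY_M, tol: float = 1e-5) -> dict:
    """Two-conformer study: fraction of exclusive-A and exclusive-B planted
    pairs recovered in the top-|union| predictions, plus per-map and
    union TP rates of those predictions."""
    sc = two_state_scenario(L=L, n_pairs_per_state=n_pairs_per_state,
                            n_shared=n_shared, seed=seed)
    aln = gibbs_sample(sc.model, M, seed=seed + 50)
    fitted = fit_plm(aln, tol=tol)
    preds = rank_predictions(
        apc(frobenius_scores(fitted)), n_top=len(sc.union_pairs), min_sep=5
    )
    top = {(i, j) for i, j, _ in preds}
    excl_a = set(sc.contacts_a) - set(sc.contacts_b)
    excl_b = set(sc.contacts_b) - set(sc.contacts_a)
    annos_a, summary_a = annotate(preds, sc.maps["A"])
    annos_b, summary_b = annotate(preds, sc.maps["B"])
    _, summary_u = annotate(preds, sc.maps["union"])
    merged = union_sp(annos_a, annos_b)
    return {
        "seed": seed,
        "frac_exclusive_a": len(top & excl_a) / len(excl_a),
        "frac_exclusive_b": len(top & excl_b) / len(excl_b),
        "tp_rate_a": summary_a.tp_rate,
        "tp_rate_b": summary_b.tp_rate,
        "tp_rate_union": summary_u.tp_rate,
        "tp_rate_union_sp2": sum(1 for a in merged if a.sp <= 2) / len(merged),
    }


def clade_interface_study(seed: int, L: int = 30, n_core: int = 10,
                          n_interface: int = 6, M_per_clade: int = 1500,
                          grid=(0.1, 0.3, 0.5, 0.7, 0.9), tol: float = 1e-5) -> dict:
    """Clade-asymmetric interface study with the eukaryote weight sweep.

    The reference run uses the natural (equal-count) weighting; its top
    predictions fix the normalization set, and the planted interface pairs
    play the role of the dimer contacts.  Reports the interface enrichment
    of the reference run and the relative interface strength along the
    W_E grid.
    """
    sc, aln = clade_scenario(L=L, n_core=n_core, n_interface=n_interface,
                             M_per_clade=M_per_clade, seed=seed)
    n_top = n_core + n_interface
    # reference: natural fraction (equal clades here -> all weights 1)
    w0 = taxon_weights(aln, TaxonWeighting(0.5))
    model0 = fit_plm(aln, w0, tol=tol)
    scores0 = apc(frobenius_scores(model0))
    preds0 = rank_predictions(scores0, n_top=n_top, min_sep=5)
    top0 = [(i, j) for i, j, _ in preds0]
    k = sum(1 for p in top0 if p in set(sc.interface))
    N = aln.L * (aln.L - 1) // 2
    test = hypergeom_upper_tail(n_top, k, N, len(sc.interface))
    points = weight_sweep(
        aln, list(grid), sc.interface, sc.maps["union"],
        n_top=n_top, min_sep=5, tol=tol, reference_top_pairs=top0,
    )
    return {
        "seed": seed,
        "interface_hits_reference": k,
        "enrichment_p": test.P_k,
        "grid": [p.W_E for p in points],
        "relative_strength": [p.relative_strength for p in points],
        "tp_rate": [p.tp_rate for p in points],
    }


def bacteria_only_interface_rank(seed: int, L: int = 30, n_core: int = 10,
                                 n_interface: int = 6, M_per_clade: int = 1500,
                                 tol: float = 1e-5) -> dict:
    """W_E = 0 (bacteria only): how many planted interface pairs stay in
    the top-(core + interface) predictions."""
    sc, aln = clade_scenario(L=L, n_core=n_core, n_interface=n_interface,
                             M_per_clade=M_per_clade, seed=seed)
    w = taxon_weights(aln, TaxonWeighting(0.0))
    model = fit_plm(aln, w, tol=tol)
    preds = rank_predictions(
        apc(frobenius_scores(model)), n_top=n_core + n_interface, min_sep=5
    )
    top = {(i, j) for i, j, _ in preds}
    return {
        "seed": seed,
        "interface_in_top": len(top & set(sc.interface)),
        "n_interface": n_interface,
    }
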