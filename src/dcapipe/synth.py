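"""Synthetic families with planted ground truth.

Three study designs are emulated, each with a known Potts model so that
every downstream stage can be checked against planted truth:

* a single family with long-range planted couplings (contact recovery);
* a two-conformer family whose generative couplings are the union of two
  mutually exclusive contact sets, exposing "allosteric" pairs that are a
  contact in exactly one synthetic conformer;
* a clade-structured family where a set of interface couplings is active
  only in the bacteria-labelled subgroup, so down-weighting that clade
  erodes the interface signal (the taxon weight sweep's planted analogue).

Sequences are drawn by single-site Gibbs sampling from the planted model.
Toy PDB fixtures realize requested contact sets geometrically so the
structure pipeline can be tested round-trip without real crystal data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .alphabet import AMINO_ACIDS, Q
from .msa import Alignment
from .potts import PottsModel
from .structures import ContactMap

Pair = tuple[int, int]


def _zero_sum_project(block: np.ndarray) -> np.ndarray:
    return (
        block
        - block.mean(axis=1, keepdims=True)
        - block.mean(axis=0, keepdims=True)
        + block.mean()
    )


def _normalize_pairs(pairs) -> list[Pair]:
    out = []
    for i, j in pairs:
        i, j = int(i), int(j)
        if i == j:
            raise ValueError(f"self-pair ({i}, {i})")
        out.append((min(i, j), max(i, j)))
    if len(set(out)) != len(out):
        raise ValueError("duplicate pairs in planted set")
    return out


def planted_model(
    L: int, pairs, coupling_scale: float = 1.0, seed: int = 0
) -> PottsModel:
    """Potts model with h = 0 and seeded zero-sum Gaussian blocks on the
    planted pairs; every other coupling block is zero."""
    if coupling_scale < 0:
        raise ValueError("coupling_scale must be non-negative")
    pairs = _normalize_pairs(pairs)
    rng = np.random.default_rng(seed)
    J = np.zeros((L, L, Q, Q))
    for i, j in pairs:
        if not 0 <= i < L and 0 <= j < L:
            raise ValueError(f"pair ({i}, {j}) outside 0..{L - 1}")
        block = coupling_scale * _zero_sum_project(rng.standard_normal((Q, Q)))
        J[i, j] = block
        J[j, i] = block.T
    return PottsModel(h=np.zeros((L, Q)), J=J)


@njit(cache=True)
def _gibbs_kernel(Jmat, h, L, q, M, burn_in, thin, seed):  # pragma: no cover
    np.random.seed(seed)
    s = np.empty(L, dtype=np.int64)
    for i in range(L):
        s[i] = np.random.randint(0, q)
    cols = np.empty(L, dtype=np.int64)
    for j in range(L):
        cols[j] = j * q + s[j]
    out = np.empty((M, L), dtype=np.int8)
    logits = np.empty(q)
    rec = 0
    sweep = 0
    while rec < M:
        sweep += 1
        for i in range(L):
            base = i * q
            for a in range(q):
                acc = h[i, a]
                row = Jmat[base + a]
                for j in range(L):
                    acc += row[cols[j]]
                logits[a] = acc
            mx = logits[0]
            for a in range(1, q):
                if logits[a] > mx:
                    mx = logits[a]
            tot = 0.0
            for a in range(q):
                logits[a] = np.exp(logits[a] - mx)
                tot += logits[a]
            r = np.random.random() * tot
            c = 0.0
            new_s = q - 1
            for a in range(q):
                c += logits[a]
                if r < c:
                    new_s = a
                    break
            s[i] = new_s
            cols[i] = base + new_s
        if sweep > burn_in and (sweep - burn_in) % thin == 0:
            for i in range(L):
                out[rec, i] = s[i]
            rec += 1
    return out


def gibbs_sample(
    model: PottsModel,
    M: int,
    burn_in_sweeps: int = 200,
    thin_sweeps: int = 5,
    seed: int = 0,
    id_prefix: str = "sample",
) -> Alignment:
    """Draw M rows by single-site Gibbs sweeps in fixed site order.

    One chain; samples recorded every ``thin_sweeps`` sweeps after
    ``burn_in_sweeps``.  Fully determined by ``seed``.
    """
    if M < 1 or burn_in_sweeps < 0 or thin_sweeps < 1:
        raise ValueError("need M >= 1, burn_in >= 0, thin >= 1")
    Jmat = model.coupling_matrix()
    rows = _gibbs_kernel(
        Jmat, model.h, model.L, model.q, M,
        burn_in_sweeps, thin_sweeps, int(seed) % (2**31 - 1),
    )
    ids = [f"{id_prefix}_{k:05d}" for k in range(M)]
    return Alignment(ids=ids, rows=rows)


def sweep_autocorrelation(aln: Alignment) -> float:
    """Lag-1 mean per-column agreement between consecutive samples, a cheap
    mixing monitor (1/q ≈ 0.048 for a perfectly mixed uniform chain)."""
    if aln.M < 2:
        return 0.0
    return float((aln.rows[1:] == aln.rows[:-1]).mean())


@dataclass
class Scenario:
    """A synthetic study with planted ground truth."""

    name: str
    model: PottsModel
    contacts_a: list[Pair]
    contacts_b: list[Pair]
    interface: list[Pair]
    seed: int
    taxon: list[str] | None = None
    maps: dict[str, ContactMap] = field(default_factory=dict)
    clade_models: dict[str, PottsModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for group in (self.contacts_a, self.contacts_b, self.interface):
            for i, j in group:
                if abs(j - i) < 5:
                    raise ValueError(f"planted pair ({i}, {j}) below separation 5")
        ab = set(self.contacts_a) | set(self.contacts_b)
        if ab & set(self.interface):
            raise ValueError("interface pairs must be disjoint from state contacts")

    @property
    def union_pairs(self) -> list[Pair]:
        return sorted(set(self.contacts_a) | set(self.contacts_b))


def _synthetic_column_map(L: int, pairs, threshold: float = 8.5) -> ContactMap:
    """Column-space map whose contacts are the backbone (|i-j| = 1) plus the
    given pairs; planted contacts sit at 4 Å, everything else at +inf."""
    dist = np.full((L, L), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(L - 1):
        dist[i, i + 1] = dist[i + 1, i] = 3.8
    for i, j in pairs:
        dist[i, j] = dist[j, i] = 4.0
    return ContactMap(dist=dist, threshold=threshold, space="column",
                      mapped=np.ones(L, dtype=bool))


def _sample_pairs(rng, L: int, n: int, min_sep: int = 5, exclude=()) -> list[Pair]:
    taken = set(exclude)
    out: list[Pair] = []
    if n == 0:
        return out
    candidates = [(i, j) for i in range(L) for j in range(i + min_sep, L)]
    rng.shuffle(candidates)
    for p in candidates:
        if p in taken:
            continue
        out.append(p)
        taken.add(p)
        if len(out) == n:
            return out
    raise ValueError(f"cannot place {n} pairs with separation >= {min_sep} in L = {L}")


def two_state_scenario(
    L: int = 40,
    n_pairs_per_state: int = 12,
    n_shared: int = 4,
    seed: int = 0,
    coupling_scale: float = 1.0,
) -> Scenario:
    """Two-conformer family: couplings on the union of contact sets A and B.

    A and B share ``n_shared`` pairs; the remainders are mutually
    exclusive, mimicking contacts present in exactly one conformer.  The
    scenario's maps "A" and "B" expose each state separately and "union"
    their elementwise-minimum union.
    """
    if n_shared > n_pairs_per_state:
        raise ValueError("n_shared cannot exceed n_pairs_per_state")
    rng = np.random.default_rng(seed)
    shared = _sample_pairs(rng, L, n_shared)
    n_excl = n_pairs_per_state - n_shared
    excl_a = _sample_pairs(rng, L, n_excl, exclude=shared)
    excl_b = _sample_pairs(rng, L, n_excl, exclude=shared + excl_a)
    contacts_a = sorted(shared + excl_a)
    contacts_b = sorted(shared + excl_b)
    union = sorted(set(contacts_a) | set(contacts_b))
    model = planted_model(L, union, coupling_scale=coupling_scale, seed=seed)
    map_a = _synthetic_column_map(L, contacts_a)
    map_b = _synthetic_column_map(L, contacts_b)
    from .structures import union_map  # local import to avoid cycle at module load

    return Scenario(
        name="two_state",
        model=model,
        contacts_a=contacts_a,
        contacts_b=contacts_b,
        interface=[],
        seed=seed,
        maps={"A": map_a, "B": map_b, "union": union_map(map_a, map_b)},
    )


def clade_scenario(
    L: int = 30,
    n_core: int = 10,
    n_interface: int = 6,
    M_per_clade: int = 1500,
    seed: int = 0,
    coupling_scale: float = 1.0,
    burn_in_sweeps: int = 200,
    thin_sweeps: int = 5,
) -> tuple[Scenario, Alignment]:
    """Clade-structured family: interface couplings active only in bacteria.

    Core couplings are identical in both clades; the interface blocks are
    added to the bacterial generative model only.  Rows are sampled
    per-clade, concatenated, and labelled.  Returns the scenario (ground
    truth) and the labelled alignment.
    """
    rng = np.random.default_rng(seed)
    core = _sample_pairs(rng, L, n_core)
    interface = _sample_pairs(rng, L, n_interface, exclude=core)
    model_core = planted_model(L, core, coupling_scale=coupling_scale, seed=seed)
    model_iface = planted_model(L, interface, coupling_scale=coupling_scale, seed=seed + 1)
    model_bact = PottsModel(h=model_core.h.copy(), J=model_core.J + model_iface.J)

    ss = np.random.SeedSequence([seed, 7])
    s_b, s_e = [int(x % (2**31 - 1)) for x in ss.generate_state(2)]
    aln_b = gibbs_sample(model_bact, M_per_clade, burn_in_sweeps, thin_sweeps, s_b,
                         id_prefix="bact")
    aln_e = gibbs_sample(model_core, M_per_clade, burn_in_sweeps, thin_sweeps, s_e,
                         id_prefix="euk")
    aln = Alignment(
        ids=aln_b.ids + aln_e.ids,
        rows=np.vstack([aln_b.rows, aln_e.rows]),
        taxon=["bacteria"] * M_per_clade + ["eukaryote"] * M_per_clade,
    )
    scenario = Scenario(
        name="clade",
        model=model_bact,
        contacts_a=sorted(core),
        contacts_b=sorted(core),
        interface=sorted(interface),
        seed=seed,
        taxon=list(aln.taxon),
        maps={
            "core": _synthetic_column_map(L, core),
            "union": _synthetic_column_map(L, sorted(set(core) | set(interface))),
        },
        clade_models={"bacteria": model_bact, "eukaryote": model_core},
    )
    return scenario, aln


# ---------------------------------------------------------------------------
# toy structures


_ATOM_OFFSETS = [
    ("N", "N", np.array([0.6, 0.0, 0.0])),
    ("CA", "C", np.array([0.0, 0.0, 0.0])),
    ("C", "C", np.array([0.0, 0.6, 0.0])),
    ("O", "O", np.array([0.0, 0.0, 0.6])),
]

_AA_3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

CONTACT_CENTER_DIST = 6.5  # residue centers of planted contacts (Å)
NONCONTACT_CENTER_DIST = 12.0  # minimum center separation of non-contacts (Å)


def _place_centers(pairs: list[Pair], L: int, rng, max_iter: int = 4000):
    """Relax residue centers so planted pairs sit below 7 Å and all other
    pairs above 12 Å; returns None when the relaxation does not converge."""
    contact = np.zeros((L, L), dtype=bool)
    for i, j in pairs:
        contact[i, j] = contact[j, i] = True
    box = 14.0 * max(2.0, L ** (1.0 / 3.0))
    x = rng.uniform(0, box, size=(L, 3))
    for _ in range(max_iter):
        if not np.isfinite(x).all() or np.abs(x).max() > 1e6:
            return None  # relaxation diverged
        d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        pull = contact & (d > 7.0)
        push = ~contact & (d < NONCONTACT_CENTER_DIST)
        np.fill_diagonal(push, False)
        if not pull.any() and not push.any():
            return x
        disp = np.zeros_like(x)
        ii, jj = np.nonzero(np.triu(pull, 1))
        for i, j in zip(ii, jj):
            u = (x[j] - x[i]) / d[i, j]
            step = 0.55 * (d[i, j] - CONTACT_CENTER_DIST)
            disp[i] += step * u
            disp[j] -= step * u
        ii, jj = np.nonzero(np.triu(push, 1))
        for i, j in zip(ii, jj):
            u = (x[j] - x[i]) / max(d[i, j], 1e-6)
            step = 0.55 * (NONCONTACT_CENTER_DIST + 0.5 - d[i, j])
            disp[i] -= step * u
            disp[j] += step * u
        x = x + disp
    return None


def toy_structure(
    contact_pairs,
    L: int,
    seed: int = 0,
    split: int | None = None,
    max_attempts: int = 8,
) -> tuple[str, ContactMap]:
    """Synthetic PDB fixture realizing exactly the requested contacts.

    Residues are four-heavy-atom pseudo-amino-acids placed so that every
    requested pair has minimal heavy-atom distance < 8.5 Å and every other
    pair > 10 Å.  With ``split`` set, residues [0, split) form chain A and
    [split, L) chain B (residue numbering continues across chains).
    Returns the PDB text and the exact residue-space ground-truth map.
    """
    if L > 60:
        raise ValueError("toy structures are limited to L <= 60")
    pairs = _normalize_pairs(contact_pairs)
    for i, j in pairs:
        if j >= L:
            raise ValueError(f"pair ({i}, {j}) outside 0..{L - 1}")
    rng = np.random.default_rng(seed)
    planted = np.zeros((L, L), dtype=bool)
    for i, j in pairs:
        planted[i, j] = planted[j, i] = True
    iu = np.triu_indices(L, k=1)

    coords_per_res = None
    dist = None
    for _ in range(max_attempts):
        centers = _place_centers(pairs, L, rng)
        if centers is None:
            continue
        candidate = [
            np.array([centers[r] + off for _n, _e, off in _ATOM_OFFSETS])
            for r in range(L)
        ]
        d = np.full((L, L), np.inf)
        for r in range(L):
            for s in range(r + 1, L):
                v = np.linalg.norm(
                    candidate[r][:, None, :] - candidate[s][None, :, :], axis=2
                ).min()
                d[r, s] = d[s, r] = v
        np.fill_diagonal(d, 0.0)
        # realization check at the atom level: planted pairs in contact,
        # all other pairs clear of 10 Å
        if (d[iu][planted[iu]] < 8.5).all() and (d[iu][~planted[iu]] > 10.0).all():
            coords_per_res, dist = candidate, d
            break
    if coords_per_res is None:
        raise RuntimeError(
            f"could not realize {len(pairs)} contacts among {L} residues "
            f"after {max_attempts} attempts"
        )

    aas = [AMINO_ACIDS[k] for k in rng.integers(0, 20, size=L)]
    lines = []
    serial = 1

    def chain_of(r: int) -> str:
        return "A" if split is None or r < split else "B"

    prev_chain = chain_of(0)
    for r in range(L):
        ch = chain_of(r)
        if ch != prev_chain:
            lines.append("TER")
            prev_chain = ch
        res3 = _AA_3[aas[r]]
        for (name, elem, _off), xyz in zip(_ATOM_OFFSETS, coords_per_res[r]):
            name_field = f" {name:<3s}"  # element right-aligned in cols 13-16
            lines.append(
                f"ATOM  {serial:5d} {name_field:4s} {res3:3s} {ch}{r + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {elem:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    truth = ContactMap(
        dist=dist, threshold=8.5, space="residue",
        residue_numbers=list(range(1, L + 1)),
    )
    return pdb_text, truth
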