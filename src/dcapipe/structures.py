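"""Contact maps from atomic structures and their projection onto MSA columns.

Two residues are in contact when the smallest distance between their heavy
(non-hydrogen) atoms is strictly below the threshold (default 8.5 Å).
Residue-space maps are indexed by position in the chain; column-space maps
are indexed by MSA column, with +inf distances wherever a column has no
resolved residue.  The union of two conformers' maps is the elementwise
minimum of their distance matrices, so a pair is a union contact if it is a
contact in either conformer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .alphabet import GAP, decode


class StructureError(ValueError):
    """Raised for unusable structure input."""


class MappingError(ValueError):
    """Raised when an MSA/structure correspondence cannot be built."""


@dataclass
class StructureChain:
    """Ordered residues of one chain: (residue number, one-letter code,
    heavy-atom coordinates)."""

    residues: list[tuple[int, str, np.ndarray]]
    chain_id: str
    source: str = ""

    def __post_init__(self) -> None:
        nums = [r[0] for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise StructureError(f"residue numbers not strictly increasing in chain {self.chain_id}")
        for num, _aa, xyz in self.residues:
            if len(xyz) == 0:
                raise StructureError(f"residue {num} has no heavy atoms")
            if not np.isfinite(xyz).all():
                raise StructureError(f"residue {num} has non-finite coordinates")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r[1] for r in self.residues)

    @property
    def residue_numbers(self) -> list[int]:
        return [r[0] for r in self.residues]


@dataclass
class ContactMap:
    """Minimal heavy-atom distance matrix with a contact threshold.

    ``space`` is "residue" (axis = chain order, ``residue_numbers`` set) or
    "column" (axis = MSA column, ``mapped`` flags resolved columns).
    Missing distances are +inf.
    """

    dist: np.ndarray
    threshold: float = 8.5
    space: str = "residue"
    residue_numbers: list[int] | None = None
    mapped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dist = np.asarray(self.dist, dtype=float)
        n = self.dist.shape[0]
        if self.dist.shape != (n, n):
            raise ValueError("dist must be square")
        if not np.allclose(
            np.where(np.isfinite(self.dist), self.dist, 0.0),
            np.where(np.isfinite(self.dist.T), self.dist.T, 0.0),
        ) or not (np.isfinite(self.dist) == np.isfinite(self.dist.T)).all():
            raise ValueError("dist must be symmetric")
        if np.any(self.dist[np.isfinite(self.dist)] < 0):
            raise ValueError("distances must be non-negative")
        if self.space not in ("residue", "column"):
            raise ValueError("space must be 'residue' or 'column'")
        if self.mapped is None and self.space == "column":
            self.mapped = np.isfinite(self.dist).any(axis=1)

    @property
    def L(self) -> int:
        return self.dist.shape[0]

    @property
    def contacts(self) -> np.ndarray:
        """Boolean contact matrix: dist < threshold, empty diagonal."""
        c = self.dist < self.threshold
        np.fill_diagonal(c, False)
        return c

    def is_mapped(self, i: int) -> bool:
        if self.mapped is None:
            return True
        return bool(self.mapped[i])

    def n_contacts(self, min_sep: int = 0) -> int:
        """Number of contact pairs i < j with j - i >= min_sep."""
        c = self.contacts
        iu = np.triu_indices(self.L, k=max(min_sep, 1))
        return int(c[iu].sum())


@dataclass
class StructureMapping:
    """Injective partial map MSA column -> (chain id, residue number)."""

    column_to_residue: dict[int, tuple[str, int]]
    identity: float

    def __post_init__(self) -> None:
        targets = list(self.column_to_residue.values())
        if len(set(targets)) != len(targets):
            raise MappingError("mapping must be injective")

    @property
    def columns(self) -> list[int]:
        return sorted(self.column_to_residue)


@dataclass
class DimerInterface:
    """Inter-chain residue pairs within the contact threshold."""

    residue_pairs: list[tuple[tuple[str, int], tuple[str, int], float]]
    column_pairs: list[tuple[int, int]]
    threshold: float

    @property
    def K(self) -> int:
        return len(self.residue_pairs)


_3to1 = {k.upper(): v for k, v in protein_letters_3to1.items()}


def _pick_altloc(atom):
    """Resolve a possibly disordered atom: highest occupancy, then
    alphabetical altloc."""
    if not atom.is_disordered():
        return atom
    children = sorted(
        atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def read_structure(path, chains: list[str] | None = None) -> list[StructureChain]:
    """Parse ATOM records of a PDB file into :class:`StructureChain` objects.

    Heavy atoms only (element H/D dropped); waters and non-amino-acid
    heteroatoms excluded; first model only for multi-model entries; altloc
    resolved by highest occupancy then alphabetical.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise StructureError(f"no models in {path}")
    available = {c.id: c for c in model}
    wanted = chains if chains is not None else sorted(available)
    out: list[StructureChain] = []
    for cid in wanted:
        if cid not in available:
            raise StructureError(f"chain {cid!r} not present in {path} (has {sorted(available)})")
        residues = []
        for res in available[cid]:
            hetflag, resseq, _icode = res.get_id()
            if hetflag != " ":
                continue  # waters and heteroatoms
            aa = _3to1.get(res.get_resname().strip().upper())
            if aa is None:
                continue  # non-standard residue
            coords = []
            for atom in res:
                a = _pick_altloc(atom)
                elem = (a.element or "").strip().upper()
                if elem in ("H", "D"):
                    continue
                coords.append(a.get_coord())
            if not coords:
                raise StructureError(f"residue {resseq} in chain {cid} has no heavy atoms")
            residues.append((resseq, aa, np.asarray(coords, dtype=float)))
        if not residues:
            raise StructureError(f"chain {cid!r} has no amino-acid atoms after filtering")
        out.append(StructureChain(residues=residues, chain_id=cid, source=str(path)))
    return out


def _min_dist_matrix(res_a, res_b) -> np.ndarray:
    """Minimal heavy-atom distance between every residue of two lists."""
    coords_a = np.concatenate([r[2] for r in res_a])
    coords_b = np.concatenate([r[2] for r in res_b])
    idx_a = np.repeat(np.arange(len(res_a)), [len(r[2]) for r in res_a])
    idx_b = np.repeat(np.arange(len(res_b)), [len(r[2]) for r in res_b])
    d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=2)
    out = np.full((len(res_a), len(res_b)), np.inf)
    np.minimum.at(out, (idx_a[:, None], idx_b[None, :]), d)
    return out


def contact_map(chain: StructureChain, threshold: float = 8.5) -> ContactMap:
    """Residue-space contact map: minimal heavy-atom distances, strict
    ``< threshold`` contact rule."""
    if chain.n_residues < 2:
        raise StructureError("need at least two residues")
    dist = _min_dist_matrix(chain.residues, chain.residues)
    np.fill_diagonal(dist, 0.0)
    return ContactMap(
        dist=dist,
        threshold=threshold,
        space="residue",
        residue_numbers=chain.residue_numbers,
    )


def map_columns(
    ref_row: np.ndarray,
    chain: StructureChain,
    min_identity: float = 0.9,
) -> StructureMapping:
    """Align the ungapped reference MSA row to the chain sequence.

    Global alignment with match +1, mismatch -1, gap -2; aligned non-gap
    columns map to resolved residues.  Rejected when aligned identity
    (matches over aligned residue pairs) falls below ``min_identity``.
    """
    ref_row = np.asarray(ref_row)
    nongap_cols = np.flatnonzero(ref_row != GAP)
    ref_seq = decode(ref_row[nongap_cols])
    chain_seq = chain.sequence
    if not ref_seq or not chain_seq:
        raise MappingError("empty sequence")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    alignment = aligner.align(ref_seq, chain_seq)[0]
    col_map: dict[int, tuple[str, int]] = {}
    matches = 0
    aligned_pairs = 0
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for off in range(a_end - a_start):
            ai = a_start + off
            bi = b_start + off
            aligned_pairs += 1
            if ref_seq[ai] == chain_seq[bi]:
                matches += 1
            col = int(nongap_cols[ai])
            num = chain.residues[bi][0]
            col_map[col] = (chain.chain_id, num)
    identity = matches / aligned_pairs if aligned_pairs else 0.0
    if identity < min_identity:
        raise MappingError(
            f"aligned identity {identity:.3f} below {min_identity} between the "
            f"reference row and chain {chain.chain_id} ({chain.source})"
        )
    return StructureMapping(column_to_residue=col_map, identity=identity)


def project_map(cm: ContactMap, mapping: StructureMapping, L: int) -> ContactMap:
    """Re-index a residue-space map into MSA-column space.

    Unmapped columns get +inf everywhere (they carry no structural
    information); contacts between mapped columns are preserved exactly.
    """
    if cm.space != "residue":
        raise ValueError("project_map expects a residue-space map")
    if cm.residue_numbers is None:
        raise ValueError("residue-space map lacks residue numbers")
    num_to_idx = {num: k for k, num in enumerate(cm.residue_numbers)}
    cols = []
    ridx = []
    for col, (_cid, num) in mapping.column_to_residue.items():
        if num in num_to_idx and col < L:
            cols.append(col)
            ridx.append(num_to_idx[num])
    cols = np.asarray(cols, dtype=int)
    ridx = np.asarray(ridx, dtype=int)
    dist = np.full((L, L), np.inf)
    dist[np.ix_(cols, cols)] = cm.dist[np.ix_(ridx, ridx)]
    mapped = np.zeros(L, dtype=bool)
    mapped[cols] = True
    return ContactMap(
        dist=dist, threshold=cm.threshold, space="column", mapped=mapped
    )


def union_map(a: ContactMap, b: ContactMap) -> ContactMap:
    """Union of two conformers: elementwise minimum of the distance maps."""
    if a.L != b.L:
        raise ValueError("maps must have the same size")
    if a.threshold != b.threshold:
        raise ValueError("maps must share the contact threshold")
    if a.space != b.space:
        raise ValueError("maps must live in the same coordinate space")
    mapped = None
    if a.mapped is not None and b.mapped is not None:
        mapped = a.mapped | b.mapped
    return ContactMap(
        dist=np.minimum(a.dist, b.dist),
        threshold=a.threshold,
        space=a.space,
        residue_numbers=a.residue_numbers if a.space == "residue" else None,
        mapped=mapped,
    )


def both_mapped_columns(a: ContactMap, b: ContactMap) -> np.ndarray:
    """Columns resolved in both conformers (the comparable region)."""
    if a.mapped is None or b.mapped is None:
        raise ValueError("both maps must be column-space with mapping flags")
    return a.mapped & b.mapped


def interface_contacts(
    chain_a: StructureChain,
    chain_b: StructureChain,
    threshold: float = 8.5,
    mapping_a: StructureMapping | None = None,
    mapping_b: StructureMapping | None = None,
) -> DimerInterface:
    """Inter-chain residue pairs with minimal heavy-atom distance < threshold.

    With per-chain column mappings supplied, each interface pair is also
    projected onto the shared MSA column axis (i, j) with i <= j.
    """
    if chain_a.chain_id == chain_b.chain_id:
        raise StructureError("interface requires two distinct chains")
    dist = _min_dist_matrix(chain_a.residues, chain_b.residues)
    pairs = []
    col_pairs = set()
    inv_a = {num: col for col, (_c, num) in (mapping_a.column_to_residue.items() if mapping_a else [])}
    inv_b = {num: col for col, (_c, num) in (mapping_b.column_to_residue.items() if mapping_b else [])}
    for r in range(chain_a.n_residues):
        for s in range(chain_b.n_residues):
            if dist[r, s] < threshold:
                num_a = chain_a.residues[r][0]
                num_b = chain_b.residues[s][0]
                pairs.append(
                    ((chain_a.chain_id, num_a), (chain_b.chain_id, num_b), float(dist[r, s]))
                )
                if num_a in inv_a and num_b in inv_b:
                    ci, cj = inv_a[num_a], inv_b[num_b]
                    col_pairs.add((min(ci, cj), max(ci, cj)))
    return DimerInterface(
        residue_pairs=pairs,
        column_pairs=sorted(col_pairs),
        threshold=threshold,
    )


def read_contact_map(path, L: int) -> ContactMap:
    """Read a map written by :func:`write_contact_map` into column space."""
    dist = np.full((L, L), np.inf)
    np.fill_diagonal(dist, 0.0)
    threshold = 8.5
    space = "column"
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "threshold" in line:
                    threshold = float(line.split("threshold")[1].split()[0])
                if "residue-space" in line:
                    space = "residue"
                continue
            i, j, d = line.split("\t")
            i, j = int(i) - 1, int(j) - 1
            dist[i, j] = dist[j, i] = float(d)
    kw = {"residue_numbers": list(range(1, L + 1))} if space == "residue" else {}
    return ContactMap(dist=dist, threshold=threshold, space=space, **kw)


def write_contact_map(cm: ContactMap, path) -> None:
    """Tab-separated (i, j, distance) triplets, 1-based, finite upper triangle."""
    with open(path, "w") as fh:
        fh.write(f"# i\tj\tdistance_A (1-based {cm.space}-space indices, "
                 f"contact threshold {cm.threshold} A)\n")
        iu = np.triu_indices(cm.L, k=1)
        for i, j in zip(*iu):
            if np.isfinite(cm.dist[i, j]):
                fh.write(f"{i + 1}\t{j + 1}\t{cm.dist[i, j]:.3f}\n")
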