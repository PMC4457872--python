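"""Multiple sequence alignments: reading, encoding, filtering, weighting.

The alignment is held as an M x L integer matrix over the 21-state alphabet
of :mod:`dcapipe.alphabet`.  Filtering follows the standard pre-processing
for pseudo-likelihood Potts inference: drop rows above a maximal gap
fraction, then greedily remove rows above a maximal pairwise identity to
already-kept rows (a deterministic stand-in for identity-based redundancy
filtering).  Taxon-conditional weighting implements the eukaryote/bacteria
weight sweep: the total weight fraction W_E is assigned to eukaryote rows,
1 - W_E to bacteria rows, and weights are rescaled so that the effective
sample size stays M_E + M_B (all weights are exactly 1 at the natural
fraction W_E = M_E / (M_E + M_B)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .alphabet import GAP, decode, encode

TAXA = ("bacteria", "eukaryote", "other")


class AlignmentFormatError(ValueError):
    """Raised for malformed alignment input."""


@dataclass
class Alignment:
    """Encoded multiple sequence alignment.

    Attributes
    ----------
    ids : list of str
        Unique sequence identifiers, one per row.
    rows : (M, L) int8 array
        Integer states in {0..20}; 0 is the gap state.
    taxon : list of str or None
        Optional per-row labels in {"bacteria", "eukaryote", "other"}.
    """

    ids: list[str]
    rows: np.ndarray
    taxon: list[str] | None = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int8)
        if self.rows.ndim != 2:
            raise AlignmentFormatError("rows must be a 2-D matrix")
        if len(self.ids) != self.rows.shape[0]:
            raise AlignmentFormatError("ids length must equal number of rows")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentFormatError("sequence ids must be unique")
        if self.rows.size and (self.rows.min() < 0 or self.rows.max() > 20):
            raise AlignmentFormatError("states must lie in {0..20}")
        if self.taxon is not None:
            if len(self.taxon) != self.rows.shape[0]:
                raise AlignmentFormatError("taxon must have one label per row")
            bad = set(self.taxon) - set(TAXA)
            if bad:
                raise AlignmentFormatError(f"unknown taxon labels: {sorted(bad)}")

    @property
    def M(self) -> int:
        return self.rows.shape[0]

    @property
    def L(self) -> int:
        return self.rows.shape[1]

    def subset(self, keep: np.ndarray) -> "Alignment":
        """Row subset by boolean mask or index array, order preserved."""
        idx = np.flatnonzero(keep) if np.asarray(keep).dtype == bool else np.asarray(keep)
        return Alignment(
            ids=[self.ids[i] for i in idx],
            rows=self.rows[idx],
            taxon=None if self.taxon is None else [self.taxon[i] for i in idx],
        )


@dataclass
class SequenceWeights:
    """Non-negative per-row weights; M_eff is their sum."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 1 or np.any(self.w < 0):
            raise ValueError("weights must be a 1-D non-negative vector")
        if self.M_eff <= 0:
            raise ValueError("M_eff must be positive")

    @property
    def M_eff(self) -> float:
        return float(self.w.sum())

    @classmethod
    def uniform(cls, M: int) -> "SequenceWeights":
        return cls(np.ones(M))


@dataclass(frozen=True)
class TaxonWeighting:
    """Total weight fraction W_E assigned to eukaryote-labelled rows."""

    W_E: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.W_E <= 1.0:
            raise ValueError("W_E must lie in [0, 1]")


def read_alignment(path, taxon_path=None) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    '-' and '.' (and ambiguity codes) encode as the gap state; lowercase
    letters are uppercased by the encoder.  All records must have the same
    aligned length.  ``taxon_path`` optionally names a two-column
    whitespace-separated table mapping sequence id to taxon label.
    """
    ids: list[str] = []
    seqs: list[np.ndarray] = []
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        if length is None:
            length = len(s)
        elif len(s) != length:
            raise AlignmentFormatError(
                f"record {rec.id!r} has length {len(s)}, expected {length}"
            )
        ids.append(rec.id)
        seqs.append(encode(s))
    if not ids:
        raise AlignmentFormatError(f"no FASTA records found in {path}")
    taxon = None
    if taxon_path is not None:
        table = read_taxon_table(taxon_path)
        taxon = [table.get(i, "other") for i in ids]
    return Alignment(ids=ids, rows=np.vstack(seqs), taxon=taxon)


def write_alignment(aln: Alignment, path) -> None:
    """Write an alignment back to FASTA ('-' for gaps); round-trips exactly."""
    with open(path, "w") as fh:
        for i in range(aln.M):
            fh.write(f">{aln.ids[i]}\n{decode(aln.rows[i])}\n")


def read_taxon_table(path) -> dict[str, str]:
    """Two whitespace-separated columns: sequence id, taxon label."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise AlignmentFormatError(f"bad taxon table line: {line!r}")
            name, label = parts
            if label not in TAXA:
                raise AlignmentFormatError(f"unknown taxon label {label!r}")
            table[name] = label
    return table


def write_taxon_table(aln: Alignment, path) -> None:
    if aln.taxon is None:
        raise ValueError("alignment has no taxon labels")
    with open(path, "w") as fh:
        for name, label in zip(aln.ids, aln.taxon):
            fh.write(f"{name}\t{label}\n")


def filter_by_gap_fraction(aln: Alignment, max_frac: float = 0.25) -> Alignment:
    """Keep rows whose gap fraction is <= ``max_frac`` (boundary kept)."""
    if not 0.0 <= max_frac <= 1.0:
        raise ValueError("max_frac must lie in [0, 1]")
    gap_frac = (aln.rows == GAP).mean(axis=1)
    return aln.subset(gap_frac <= max_frac)


def pairwise_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of identical states over columns where both rows are non-gap.

    Returns 0 when no column has both rows non-gap.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("rows must have equal length")
    both = (a != GAP) & (b != GAP)
    denom = int(both.sum())
    if denom == 0:
        return 0.0
    return float(((a == b) & both).sum()) / denom


def filter_by_identity(aln: Alignment, max_identity: float = 0.9) -> Alignment:
    """Greedy redundancy filter in input order.

    A row is kept iff its pairwise identity to every already-kept row is
    <= ``max_identity``; the pass is deterministic and idempotent.
    """
    if not 0.0 < max_identity <= 1.0:
        raise ValueError("max_identity must lie in (0, 1]")
    nongap = aln.rows != GAP
    kept: list[int] = []
    for r in range(aln.M):
        row = aln.rows[r]
        ng = nongap[r]
        ok = True
        for k in kept:
            both = ng & nongap[k]
            denom = int(both.sum())
            ident = 0.0 if denom == 0 else float(((row == aln.rows[k]) & both).sum()) / denom
            if ident > max_identity:
                ok = False
                break
        if ok:
            kept.append(r)
    return aln.subset(np.asarray(kept, dtype=int))


def taxon_counts(aln: Alignment) -> tuple[int, int, int]:
    """(M_E, M_B, M_other) from the alignment's taxon labels."""
    if aln.taxon is None:
        raise ValueError("alignment has no taxon labels")
    labels = np.asarray(aln.taxon)
    return (
        int((labels == "eukaryote").sum()),
        int((labels == "bacteria").sum()),
        int((labels == "other").sum()),
    )


def taxon_weights(aln: Alignment, tw: TaxonWeighting) -> SequenceWeights:
    """Taxon-conditional weights realising eukaryote weight fraction W_E.

    Eukaryote rows share total weight W_E, bacteria rows share 1 - W_E,
    "other" rows get 0; the vector is rescaled so M_eff = M_E + M_B.  At
    the natural fraction W_E = M_E / (M_E + M_B) every used row has weight
    exactly 1, reproducing the unweighted analysis.
    """
    M_E, M_B, _ = taxon_counts(aln)
    W_E = tw.W_E
    if W_E > 0 and M_E == 0:
        raise ValueError("W_E > 0 but the alignment has no eukaryote rows")
    if W_E < 1 and M_B == 0:
        raise ValueError("W_E < 1 but the alignment has no bacteria rows")
    labels = np.asarray(aln.taxon)
    w = np.zeros(aln.M)
    scale = M_E + M_B
    if M_E:
        w[labels == "eukaryote"] = W_E / M_E * scale
    if M_B:
        w[labels == "bacteria"] = (1.0 - W_E) / M_B * scale
    return SequenceWeights(w)
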