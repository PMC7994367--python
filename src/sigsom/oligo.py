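"""Degenerate oligonucleotide groups and composition vectors.

Genome assemblies register an arbitrary strand per scaffold, so a k-mer and
its reverse complement are interchangeable descriptions of the same
underlying duplex word.  All composition work here therefore pools each
oligonucleotide with its reverse complement into a single *degenerate group*
(e.g. ``AG+CT``); self-complementary words such as ``CG`` form singleton
groups.  Counting on one strand with this grouping is equivalent to
canonical k-mer counting and makes every composition vector exactly
strand-invariant.

Group counts per k: 2 (k=1), 10 (k=2), 32 (k=3), 136 (k=4); in general
``4^k/2`` for odd k and ``(4^k + 4^(k/2))/2`` for even k.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

# byte -> 0..3 for ACGT (upper or lower case), 4 for anything else (N etc.)
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 (A=0, C=1, G=2, T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(states: np.ndarray) -> str:
    """Inverse of :func:`encode` (4 decodes to N)."""
    return _DEC[np.asarray(states, dtype=np.uint8)].tobytes().decode("ascii")


@dataclass(frozen=True)
class DegenerateGroup:
    """A complementary pair of k-mers pooled into one counting unit."""

    label: str
    members: frozenset
    k: int
    self_complementary: bool


def group_label(kmer: str) -> str:
    rc = revcomp(kmer)
    if rc == kmer:
        return kmer
    lo, hi = sorted((kmer, rc))
    return f"{lo}+{hi}"


@functools.lru_cache(maxsize=None)
def enumerate_groups(k: int) -> tuple:
    """All degenerate groups of size k, sorted by label.

    Every k-mer over {A,C,G,T} belongs to exactly one group.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    seen = {}
    for tup in itertools.product(BASES, repeat=k):
        kmer = "".join(tup)
        lab = group_label(kmer)
        if lab not in seen:
            rc = revcomp(kmer)
            seen[lab] = DegenerateGroup(
                label=lab,
                members=frozenset({kmer, rc}),
                k=k,
                self_complementary=rc == kmer,
            )
    return tuple(seen[lab] for lab in sorted(seen))


@functools.lru_cache(maxsize=None)
def group_labels(k: int) -> tuple:
    return tuple(g.label for g in enumerate_groups(k))


def n_groups(k: int) -> int:
    return len(enumerate_groups(k))


def canonical_group(kmer: str) -> str | None:
    """Label of the degenerate group containing ``kmer``.

    Returns None (the "skip" sentinel) for k-mers containing characters
    outside {A,C,G,T}.
    """
    if set(kmer) - set(BASES):
        return None
    return group_label(kmer)


@functools.lru_cache(maxsize=None)
def _group_index_table(k: int) -> np.ndarray:
    """Map base-4 k-mer code -> index into group_labels(k)."""
    labels = {lab: i for i, lab in enumerate(group_labels(k))}
    table = np.empty(4**k, dtype=np.int64)
    for code, tup in enumerate(itertools.product(BASES, repeat=k)):
        table[code] = labels[group_label("".join(tup))]
    return table


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 codes of all overlapping k-mers plus validity mask.

    Positions whose k-mer touches a non-ACGT base are invalid.
    """
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        b = enc[j : j + n]
        valid &= b < 4
        codes *= 4
        codes += b
    return codes, valid


def group_counts(seq, k: int) -> tuple[np.ndarray, int]:
    """Degenerate-group counts over all overlapping k-mers of one strand.

    Parameters
    ----------
    seq : str or uint8 array
        Sequence, raw or pre-encoded with :func:`encode`.
    k : int

    Returns
    -------
    counts : int64 array aligned with ``group_labels(k)``
    total : int
        Number of valid (N-free) k-mers counted.
    """
    enc = encode(seq) if isinstance(seq, (str, bytes)) else np.asarray(seq)
    codes, valid = _kmer_codes(enc, k)
    kmer_counts = np.bincount(codes[valid], minlength=4**k)
    counts = np.zeros(n_groups(k), dtype=np.int64)
    np.add.at(counts, _group_index_table(k), kmer_counts)
    return counts, int(kmer_counts.sum())


@dataclass
class CompositionVector:
    """Normalized degenerate-group frequencies for one window.

    ``values`` is aligned with ``group_labels(k)`` and sums to 1 when
    ``total_count > 0``; a window whose every k-mer touched an N has
    ``total_count == 0`` and is flagged invalid.
    """

    k: int
    values: np.ndarray
    total_count: int
    window_id: str | None = None
    labels: tuple = field(default=None, repr=False)

    def __post_init__(self):
        if self.labels is None:
            self.labels = group_labels(self.k)

    @property
    def valid(self) -> bool:
        return self.total_count > 0


def composition(seq, k: int, window_id: str | None = None) -> CompositionVector:
    """Composition vector of one sequence (k-mers containing N skipped)."""
    enc = encode(seq) if isinstance(seq, (str, bytes)) else np.asarray(seq)
    if enc.size < k:
        raise ValueError(f"sequence shorter than k={k}")
    counts, total = group_counts(enc, k)
    values = counts / total if total > 0 else np.zeros(counts.size)
    return CompositionVector(k=k, values=values, total_count=total, window_id=window_id)


def composition_matrix(records, windows, k: int) -> pd.DataFrame:
    """Composition table for a set of windows cut from ``records``.

    Parameters
    ----------
    records : iterable of GenomeRecord
    windows : iterable of SequenceWindow
    k : int

    Returns
    -------
    DataFrame with metadata columns (window_id, record_id, species, start,
    end, total_count) followed by one frequency column per degenerate group.
    Windows with ``total_count == 0`` are excluded (they carry no valid
    k-mer), consistent with the invalid-vector flag of
    :class:`CompositionVector`.
    """
    enc_by_record = {r.record_id: encode(r.sequence) for r in records}
    labels = group_labels(k)
    meta_rows, freq_rows = [], []
    for w in windows:
        enc = enc_by_record[w.record_id]
        counts, total = group_counts(enc[w.start : w.start + w.length], k)
        if total == 0:
            continue
        meta_rows.append(
            (w.window_id, w.record_id, w.species, w.start, w.start + w.length, total)
        )
        freq_rows.append(counts / total)
    meta = pd.DataFrame(
        meta_rows,
        columns=["window_id", "record_id", "species", "start", "end", "total_count"],
    )
    freqs = pd.DataFrame(np.asarray(freq_rows).reshape(len(meta), len(labels)),
                         columns=list(labels))
    return pd.concat([meta, freqs], axis=1)


META_COLUMNS = ["window_id", "record_id", "species", "start", "end", "total_count"]


def split_matrix(comp: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, list]:
    """Split a composition table into (metadata, X matrix, group labels)."""
    labels = [c for c in comp.columns if c not in META_COLUMNS]
    return comp[META_COLUMNS], comp[labels].to_numpy(dtype=np.float64), labels
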