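"""FASTA input and fixed-length sliding-window extraction.

Coordinates are 0-based half-open everywhere, including BED output.
Windows never cross record (scaffold) boundaries and trailing partial
windows are discarded so that every composition vector describes the same
number of bases.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .oligo import encode

logger = logging.getLogger(__name__)

_INVALID_RE = re.compile(r"[^ACGTN]")


@dataclass
class GenomeRecord:
    """One assembly record (chromosome or scaffold) with its species label."""

    record_id: str
    species: str
    sequence: str
    chromosome_label: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SequenceWindow:
    """A fixed-length genomic fragment with provenance.

    ``start`` is 0-based; the window covers [start, start+length).
    ``n_fraction`` is the fraction of N bases inside the window.
    """

    window_id: str
    record_id: str
    species: str
    start: int
    length: int
    n_fraction: float

    @property
    def end(self) -> int:
        return self.start + self.length


def clean_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase and map characters outside {A,C,G,T,N} to N (logged)."""
    seq = seq.upper()
    n_bad = len(_INVALID_RE.findall(seq))
    if n_bad:
        logger.warning(
            "record %s: %d characters outside {A,C,G,T,N} mapped to N",
            record_id, n_bad,
        )
        seq = _INVALID_RE.sub("N", seq)
    return seq


def read_fasta(path, species: str, chromosome_labels: dict | None = None) -> list:
    """Read a FASTA assembly as a list of :class:`GenomeRecord`.

    Lowercase letters are accepted and uppercased; characters outside
    {A,C,G,T,N} are mapped to N with a logged warning.  Record order is
    preserved.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the file holds no records, or a record has an empty sequence
        (the error names the record).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"FASTA file not found: {path}")
    chromosome_labels = chromosome_labels or {}
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append(
            GenomeRecord(
                record_id=rec.id,
                species=species,
                sequence=clean_sequence(seq, rec.id),
                chromosome_label=chromosome_labels.get(rec.id),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate record ids in {path}")
    return records


def write_fasta(records, path, line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.record_id}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i : i + line_width] + "\n")


def window_id(record_id: str, start: int, end: int) -> str:
    return f"{record_id}:{start}-{end}"


def window_record(
    rec: GenomeRecord,
    window: int,
    step: int,
    max_n_fraction: float = 0.1,
) -> tuple[list, int]:
    """Cut one record into fixed-length windows with a sliding step.

    Windows start at 0, step, 2*step, ... while start+window fits in the
    record; the trailing partial window is discarded.  Windows whose N
    fraction exceeds ``max_n_fraction`` are excluded and counted.

    Returns
    -------
    (windows, n_excluded)
    """
    if not (window >= step >= 1):
        raise ValueError(f"need window >= step >= 1, got window={window} step={step}")
    L = len(rec)
    if L < window:
        return [], 0
    enc = encode(rec.sequence)
    ncum = np.concatenate([[0], np.cumsum(enc == 4, dtype=np.int64)])
    starts = np.arange(0, L - window + 1, step, dtype=np.int64)
    kept, n_excluded = [], 0
    for s in starts:
        s = int(s)
        nfrac = (ncum[s + window] - ncum[s]) / window
        if nfrac > max_n_fraction:
            n_excluded += 1
            continue
        kept.append(
            SequenceWindow(
                window_id=window_id(rec.record_id, s, s + window),
                record_id=rec.record_id,
                species=rec.species,
                start=s,
                length=window,
                n_fraction=float(nfrac),
            )
        )
    return kept, n_excluded


def window_records(records, window: int, step: int, max_n_fraction: float = 0.1):
    """Window every record; returns (windows, per-record exclusion report)."""
    windows, report = [], {}
    for rec in records:
        w, dropped = window_record(rec, window, step, max_n_fraction)
        windows.extend(w)
        report[rec.record_id] = {"kept": len(w), "excluded_n_rich": dropped}
    return windows, report


def windows_frame(windows) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (w.window_id, w.record_id, w.species, w.start, w.end, w.n_fraction)
            for w in windows
        ],
        columns=["window_id", "record_id", "species", "start", "end", "n_fraction"],
    )


def write_windows_bed(windows, path) -> None:
    """BED (0-based half-open): record_id, start, end, window_id, species."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.record_id}\t{w.start}\t{w.end}\t{w.window_id}\t{w.species}\n")


def read_windows_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["record_id", "start", "end", "window_id", "species"],
    )
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a DataFrame as TSV with a header row."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
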