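"""CpG-suppression indexes and sliding-window chromosome profiles.

Vertebrate genomes deplete the CG (CpG) dinucleotide because methylated
cytosine deaminates to thymine.  Two indexes quantify this independently of
base composition:

* Obs/Exp odds ratio: f(CG) / (f(C) * f(G)), with f taken on one strand
  over N-free bases/dinucleotides (the standard CpG odds ratio; ~1 under
  base independence, well below 1 under suppression).
* CG/GC ratio: count(CG) / count(GC); if dinucleotide occurrence only
  reflected base composition it would fluctuate around 1 along a
  chromosome.

Both are invariant under reverse complement (CG and GC are each
self-complementary).  Chromosome landscapes are profiled as per-window
degenerate-group composition (%) with an ordinary least-squares quadratic
baseline and prominence-based peak calls classified terminal vs internal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .oligo import encode, group_counts, group_labels

A, C, G, T = 0, 1, 2, 3


@dataclass
class CGCounts:
    """Raw strand counts backing the CG indexes; addable for pooling."""

    cg: int = 0
    gc: int = 0
    dimers: int = 0  # valid (N-free) dinucleotides
    c: int = 0
    g: int = 0
    at: int = 0
    bases: int = 0  # valid (N-free) bases

    def __add__(self, other: "CGCounts") -> "CGCounts":
        return CGCounts(*(a + b for a, b in zip(self._tuple(), other._tuple())))

    def _tuple(self):
        return (self.cg, self.gc, self.dimers, self.c, self.g, self.at, self.bases)


def count_cg_stats(seq) -> CGCounts:
    enc = encode(seq) if isinstance(seq, (str, bytes)) else np.asarray(seq)
    valid = enc < 4
    left, right = enc[:-1], enc[1:]
    pair_ok = valid[:-1] & valid[1:]
    return CGCounts(
        cg=int(((left == C) & (right == G) & pair_ok).sum()),
        gc=int(((left == G) & (right == C) & pair_ok).sum()),
        dimers=int(pair_ok.sum()),
        c=int((enc == C).sum()),
        g=int((enc == G).sum()),
        at=int(((enc == A) | (enc == T)).sum()),
        bases=int(valid.sum()),
    )


def _as_counts(x) -> CGCounts:
    return x if isinstance(x, CGCounts) else count_cg_stats(x)


def cg_obs_exp(x) -> float:
    """CpG odds ratio f(CG)/(f(C)·f(G)); accepts a sequence or CGCounts.

    Returns NaN (with a warning) when undefined: fewer than 2 valid bases
    or f(C)·f(G) = 0.
    """
    s = _as_counts(x)
    if s.bases < 2 or s.dimers == 0:
        warnings.warn("cg_obs_exp undefined: fewer than 2 valid bases")
        return float("nan")
    f_c, f_g = s.c / s.bases, s.g / s.bases
    if f_c * f_g == 0:
        warnings.warn("cg_obs_exp undefined: f(C)*f(G) = 0")
        return float("nan")
    return (s.cg / s.dimers) / (f_c * f_g)


def cg_gc_ratio(x) -> float:
    """count(CG)/count(GC) on the given strand; NaN when GC count is 0."""
    s = _as_counts(x)
    if s.gc == 0:
        warnings.warn("cg_gc_ratio undefined: GC count is 0")
        return float("nan")
    return s.cg / s.gc


def gc_percent(x) -> float:
    s = _as_counts(x)
    if s.bases == 0:
        return float("nan")
    return 100.0 * (s.c + s.g) / s.bases


@dataclass
class CGSuppressionIndex:
    scope: str  # genome | chromosome | window
    obs_exp: float
    cg_gc: float
    gc_percent: float


def cg_index(x, scope: str = "window") -> CGSuppressionIndex:
    s = _as_counts(x)
    return CGSuppressionIndex(
        scope=scope, obs_exp=cg_obs_exp(s), cg_gc=cg_gc_ratio(s),
        gc_percent=gc_percent(s),
    )


def pooled_cg_index(records, scope: str = "genome") -> CGSuppressionIndex:
    """Genome-wide index from counts pooled over records before division."""
    total = CGCounts()
    for rec in records:
        seq = rec.sequence if hasattr(rec, "sequence") else rec
        total = total + count_cg_stats(seq)
    return cg_index(total, scope=scope)


@dataclass
class Peak:
    index: int
    position: float  # window midpoint, bases
    value: float
    prominence: float
    klass: str  # terminal | internal


@dataclass
class KmerProfile:
    """Per-chromosome sliding-window frequency track for one group."""

    record_id: str
    chromosome_label: str | None
    group_label: str
    starts: np.ndarray
    positions: np.ndarray  # window midpoints, bases
    values: np.ndarray  # group composition, percent
    window: int
    step: int
    record_length: int
    quad_fit: tuple | None = None  # (a, b, c) of y = a x^2 + b x + c
    fitted: np.ndarray | None = None
    peaks: list = field(default_factory=list)


def _label_k(label: str) -> int:
    return len(label.split("+")[0])


def chromosome_profile(
    rec,
    labels,
    window: int = 1_000_000,
    step: int = 100_000,
) -> dict:
    """Sliding-window composition (%) of arbitrary degenerate groups.

    Accepts any degenerate-group labels (e.g. "CG", "CCG+CGG",
    "CTTCC+GGAAG"), possibly of mixed k.  A record shorter than ``window``
    yields empty profiles.

    Returns
    -------
    dict mapping label -> :class:`KmerProfile`.
    """
    if isinstance(labels, str):
        labels = [labels]
    ks = {}
    for lab in labels:
        k = _label_k(lab)
        if lab not in group_labels(k):
            raise KeyError(f"unknown degenerate group label {lab!r}")
        ks.setdefault(k, []).append(lab)
    L = len(rec.sequence)
    enc = encode(rec.sequence)
    starts = np.arange(0, L - window + 1, step, dtype=np.int64) if L >= window else \
        np.empty(0, dtype=np.int64)
    mids = starts + window / 2.0
    out = {}
    values = {lab: np.empty(len(starts)) for lab in labels}
    for n, s in enumerate(starts):
        sl = enc[s : s + window]
        for k, labs in ks.items():
            counts, total = group_counts(sl, k)
            gl = group_labels(k)
            for lab in labs:
                v = counts[gl.index(lab)] / total if total else np.nan
                values[lab][n] = 100.0 * v
    for lab in labels:
        out[lab] = KmerProfile(
            record_id=rec.record_id,
            chromosome_label=getattr(rec, "chromosome_label", None),
            group_label=lab,
            starts=starts,
            positions=mids,
            values=values[lab],
            window=window,
            step=step,
            record_length=L,
        )
    return out


def fit_quadratic(profile: KmerProfile) -> tuple:
    """Least-squares degree-2 fit of the profile (its smooth baseline).

    The fit is done on centered/scaled positions for conditioning and the
    coefficients are mapped back to y = a x^2 + b x + c in base
    coordinates; a < 0 is a downward-opening parabola.  Degenerate
    (collinear) profiles come back with a ~ 0.
    """
    x, y = np.asarray(profile.positions, float), np.asarray(profile.values, float)
    if x.size < 3:
        raise ValueError("need at least 3 profile points for a quadratic fit")
    mx = x.mean()
    sx = x.std()
    if sx == 0:
        raise ValueError("degenerate profile positions")
    u = (x - mx) / sx
    V = np.column_stack([u**2, u, np.ones_like(u)])
    (A2, B1, C0), *_ = np.linalg.lstsq(V, y, rcond=None)
    a = A2 / sx**2
    b = B1 / sx - 2 * A2 * mx / sx**2
    c = C0 - B1 * mx / sx + A2 * mx**2 / sx**2
    profile.quad_fit = (float(a), float(b), float(c))
    profile.fitted = V @ np.array([A2, B1, C0])
    return profile.quad_fit


def call_peaks(
    profile: KmerProfile,
    min_prominence: float | None = None,
    terminal_fraction: float = 0.05,
) -> list:
    """Prominence-based peak calls on the residuals about the quadratic fit.

    Local maxima of (value - fitted baseline) with prominence at least
    ``min_prominence`` (default: 2x the residual SD) are reported; end
    windows can qualify (the track is padded so a monotone profile yields
    at most its end points).  A peak whose midpoint lies within
    ``terminal_fraction`` of either chromosome end is classed terminal,
    else internal.
    """
    if profile.fitted is None:
        fit_quadratic(profile)
    resid = profile.values - profile.fitted
    if min_prominence is None:
        min_prominence = 2.0 * float(resid.std())
    # numerical floor so machine-precision residual wiggles are never peaks
    floor = 1e-8 * max(1.0, float(np.ptp(profile.values)))
    min_prominence = max(min_prominence, floor)
    lo = resid.min() - max(1.0, np.ptp(resid)) * 10 - 1.0
    padded = np.concatenate([[lo], resid, [lo]])
    idx, props = find_peaks(padded, prominence=min_prominence)
    peaks = []
    L = profile.record_length
    for m, p in zip(idx - 1, props["prominences"]):
        pos = float(profile.positions[m])
        klass = (
            "terminal"
            if pos <= terminal_fraction * L or pos >= (1 - terminal_fraction) * L
            else "internal"
        )
        peaks.append(
            Peak(index=int(m), position=pos, value=float(profile.values[m]),
                 prominence=float(p), klass=klass)
        )
    profile.peaks = peaks
    return peaks
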