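"""Synthetic multi-species genome generator with ground-truth tables.

Each species is a first-order Markov chain over {A,C,G,T}: a stationary-ish
base composition ``pi`` plus a CpG-suppression level give a species-specific
dinucleotide signature of the kind a genome-signature map separates.
Chromosome plans add two landscape features:

* a parabolic compositional gradient: the per-position transition matrix is
  ``w(x) * P_edge + (1 - w(x)) * P_center`` with ``w(x) = (2x/L - 1)^2``,
  so the edge model dominates chromosome ends — with a CG-rich edge model
  this emulates the rise of CG toward chromosome ends;
* tandem repeat blocks: n copies of a fixed (typically CG-rich,
  transposon-like, ~520-bp) unit separated by short background spacers,
  forming Mb-scale CG-rich blocks.

Every emitted region is recorded in a truth table so downstream recovery
(territories, satellites, shared nodes, profile peaks) can be scored
against known labels.

CpG suppression
---------------
``cg_suppression`` is the *target* genome-wide CG Obs/Exp odds ratio.  The
chain is built from the independence baseline P(b|a) = pi_b; the C-row
entry for G is multiplied by a factor m and the row renormalized.  Because
renormalization and the shifted stationary distribution feed back on the
odds ratio, m is solved numerically (monotone in the odds ratio, bisected
with brentq) so that the stationary-distribution prediction of Obs/Exp
equals the requested level; ``calibrate=False`` instead uses the raw
multiplier m = s.  The stationary prediction is stored on the model and is
the oracle that empirical estimates are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import _markov
from .genome_io import GenomeRecord, write_fasta
from .oligo import BASES, decode, encode, group_label, group_labels

A, C, G, T = 0, 1, 2, 3


def _stationary(P: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(evals - 1.0)))
    v = np.real(evecs[:, k])
    v = np.abs(v)
    return v / v.sum()


def _suppressed_matrix(pi: np.ndarray, m: float) -> np.ndarray:
    P = np.tile(pi, (4, 1))
    P[C, G] *= m
    P[C] /= P[C].sum()
    return P


def _predicted_obs_exp(P: np.ndarray) -> float:
    pi_hat = _stationary(P)
    # f(CG) = pi_C P(G|C); f(C), f(G) from the stationary distribution
    return float(P[C, G] / pi_hat[G])


@dataclass
class SpeciesModel:
    """First-order Markov genome model for one species.

    With ``gc_drift`` > 0 the background is emitted as a slowly varying
    mixture of a GC-boosted and a GC-reduced variant of the chain
    (piecewise-linear mixture weight with knots every ``drift_scale``
    bases), emulating the Mb-scale isochore-like GC mosaicism of real
    vertebrate chromosomes; without it large fragments of one genome are
    nearly identical in composition, which real genomes are not.  Drift is
    off by default so that the stationary-distribution predictions stay
    exact for the plain chain.
    """

    name: str
    pi: np.ndarray
    P: np.ndarray  # (4, 4) row-stochastic
    cg_suppression: float
    seed: int = 0
    gc_drift: float = 0.0
    drift_scale: int = 500_000
    stationary: np.ndarray = field(default=None, repr=False)
    predicted_obs_exp: float = None
    variants: tuple | None = field(default=None, repr=False)  # (lo, hi)

    def __post_init__(self):
        if self.stationary is None:
            self.stationary = _stationary(self.P)
        if self.predicted_obs_exp is None:
            self.predicted_obs_exp = _predicted_obs_exp(self.P)

    def cum_rows(self) -> np.ndarray:
        return np.cumsum(self.P, axis=1)


def build_species_model(
    name: str,
    pi=None,
    cg_suppression: float = 1.0,
    seed: int = 0,
    transition_bias: dict | None = None,
    calibrate: bool = True,
    gc_drift: float = 0.0,
    drift_scale: int = 500_000,
) -> SpeciesModel:
    """Build a species model with a target CpG Obs/Exp level.

    Parameters
    ----------
    pi : 4 base probabilities (A, C, G, T); default a mildly AT-rich
        vertebrate-like composition (0.30, 0.20, 0.20, 0.30).
    cg_suppression : target genome-wide CG Obs/Exp odds ratio (s >= 0);
        s = 1 leaves the chain at base independence, s = 0 forbids CG.
    transition_bias : optional extra signature shaping, mapping a
        dinucleotide (e.g. "AA") to a multiplicative factor applied to
        P(b|a) before row renormalization.
    calibrate : solve the C->G multiplier so the stationary prediction of
        Obs/Exp equals ``cg_suppression`` exactly; with False the
        multiplier is used raw (the prediction then differs from s and is
        stored on the model).
    gc_drift : relative GC amplitude of isochore-like within-genome
        variation (0 = homogeneous chain); 0.05-0.1 is a realistic
        vertebrate-scale mosaic.
    drift_scale : knot spacing (bases) of the drift track.
    """
    pi = np.asarray(
        [0.30, 0.20, 0.20, 0.30] if pi is None else pi, dtype=np.float64
    )
    if pi.shape != (4,) or (pi <= 0).any() or abs(pi.sum() - 1) > 1e-9:
        raise ValueError("pi must be 4 positive probabilities summing to 1")
    s = float(cg_suppression)
    if s < 0:
        raise ValueError("cg_suppression must be >= 0")
    if s > 1.0 / pi[G]:
        raise ValueError(
            f"cg_suppression {s} exceeds 1/pi_G = {1.0 / pi[G]:.3f}; "
            "row C cannot renormalize"
        )

    def with_bias(P: np.ndarray) -> np.ndarray:
        if transition_bias:
            for dimer, factor in transition_bias.items():
                a, b = (BASES.index(ch) for ch in dimer)
                P[a, b] *= factor
            P /= P.sum(axis=1, keepdims=True)
        return P

    if not calibrate or s in (0.0, 1.0):
        P = with_bias(_suppressed_matrix(pi, s))
    else:
        def gap(m):
            return _predicted_obs_exp(with_bias(_suppressed_matrix(pi, m))) - s

        hi = 1.0 / pi[G] - 1e-9
        if gap(hi) < 0:
            raise ValueError(
                f"target Obs/Exp {s} is unattainable for this pi "
                f"(maximum ≈ {gap(hi) + s:.3f}); use calibrate=False for a raw "
                "multiplier"
            )
        m = brentq(gap, 1e-12, hi, xtol=1e-12)
        P = with_bias(_suppressed_matrix(pi, m))
    variants = None
    if gc_drift > 0:
        shift = np.array([-1.0, 1.0, 1.0, -1.0])
        lo_hi = []
        for sign in (-1.0, 1.0):
            pv = pi * (1.0 + sign * gc_drift * shift)
            pv /= pv.sum()
            lo_hi.append(
                build_species_model(
                    f"{name}_{'hi' if sign > 0 else 'lo'}", pi=pv,
                    cg_suppression=s, seed=seed,
                    transition_bias=transition_bias, calibrate=calibrate,
                )
            )
        variants = (lo_hi[0], lo_hi[1])
    return SpeciesModel(
        name=name, pi=pi, P=P, cg_suppression=s, seed=seed,
        gc_drift=gc_drift, drift_scale=drift_scale, variants=variants,
    )


def predicted_group_frequencies(model: SpeciesModel, k: int = 2) -> pd.Series:
    """Analytic stationary degenerate-group frequencies of the chain.

    Chains the stationary distribution through k-1 transitions for every
    k-mer and pools complementary pairs; the oracle for generated
    composition vectors.
    """
    labels = group_labels(k)
    freq = dict.fromkeys(labels, 0.0)
    import itertools

    for tup in itertools.product(range(4), repeat=k):
        p = model.stationary[tup[0]]
        for a, b in zip(tup[:-1], tup[1:]):
            p *= model.P[a, b]
        kmer = "".join(BASES[t] for t in tup)
        freq[group_label(kmer)] += p
    return pd.Series([freq[lab] for lab in labels], index=list(labels))


@dataclass
class RepeatBlock:
    """n_copies of a fixed unit with background-model spacers between."""

    start: int
    n_copies: int
    unit: str
    spacer_len: int = 30

    @property
    def span(self) -> int:
        return self.n_copies * len(self.unit) + (self.n_copies - 1) * self.spacer_len

    @property
    def end(self) -> int:
        return self.start + self.span


@dataclass
class ForeignSegment:
    """A contiguous region emitted from a different species model."""

    start: int
    end: int
    model: SpeciesModel


@dataclass
class ChromosomePlan:
    """Layout of one synthetic chromosome."""

    name: str
    length: int
    gradient: tuple | None = None  # (edge_model, center_model)
    repeat_blocks: list = field(default_factory=list)
    foreign_segments: list = field(default_factory=list)

    def validate(self) -> None:
        if self.length <= 0:
            raise ValueError("chromosome length must be positive")
        spans = [(b.start, b.end) for b in self.repeat_blocks] + [
            (f.start, f.end) for f in self.foreign_segments
        ]
        spans.sort()
        prev_end = 0
        for s, e in spans:
            if s < 0 or e > self.length:
                raise ValueError(f"feature [{s}, {e}) outside chromosome bounds")
            if s < prev_end:
                raise ValueError("overlapping features in chromosome plan")
            prev_end = e


def cg_rich_repeat_unit(length: int = 520, seed: int = 0) -> str:
    """A fixed CG-dense, C/G-rich unit emulating a transposon-like repeat."""
    model = build_species_model(
        "repeat_unit", pi=[0.15, 0.35, 0.35, 0.15], cg_suppression=2.2, seed=seed,
        calibrate=False,
    )
    rng = np.random.default_rng(seed)
    states = _emit_plain(model, length, rng)
    return decode(states)


def _emit_plain(model: SpeciesModel, n: int, rng) -> np.ndarray:
    if n <= 0:
        return np.empty(0, dtype=np.uint8)
    start = int(rng.choice(4, p=model.stationary))
    u = rng.random(n)
    out = _markov.markov_states(model.cum_rows(), start, u)
    return out


def _emit_model(model: SpeciesModel, n: int, rng) -> np.ndarray:
    """Emit from a model, with isochore-like GC drift when configured."""
    if model.gc_drift <= 0 or model.variants is None or n <= 0:
        return _emit_plain(model, n, rng)
    lo, hi = model.variants
    n_knots = max(2, n // model.drift_scale + 2)
    knots_x = np.linspace(0, n - 1, n_knots)
    knots_v = rng.random(n_knots)
    w = np.interp(np.arange(n, dtype=np.float64), knots_x, knots_v)
    mix0 = w[0] * hi.stationary + (1 - w[0]) * lo.stationary
    start = int(rng.choice(4, p=mix0 / mix0.sum()))
    u = rng.random(n)
    return _markov.markov_states_mixture(hi.P, lo.P, w, start, u)


def _emit_gradient(edge: SpeciesModel, center: SpeciesModel, x0: int, n: int,
                   L: int, rng) -> np.ndarray:
    if n <= 0:
        return np.empty(0, dtype=np.uint8)
    x = x0 + np.arange(n, dtype=np.float64)
    w = (2.0 * x / L - 1.0) ** 2
    mix0 = w[0] * edge.stationary + (1 - w[0]) * center.stationary
    start = int(rng.choice(4, p=mix0 / mix0.sum()))
    u = rng.random(n)
    return _markov.markov_states_mixture(edge.P, center.P, w, start, u)


def _emit_block(block: RepeatBlock, spacer_model: SpeciesModel, rng) -> np.ndarray:
    unit = encode(block.unit)
    n_sp = (block.n_copies - 1) * block.spacer_len
    spacers = _emit_plain(spacer_model, n_sp, rng)
    parts = []
    for c in range(block.n_copies):
        parts.append(unit)
        if c < block.n_copies - 1:
            parts.append(spacers[c * block.spacer_len : (c + 1) * block.spacer_len])
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)


def generate_chromosome(
    species: str,
    model: SpeciesModel | None,
    plan: ChromosomePlan,
    seed: int = 0,
):
    """Emit one chromosome per its plan; returns (GenomeRecord, truth rows).

    Background comes from ``model`` (or the plan's gradient mixture);
    repeat blocks and foreign segments interrupt the background.  Output is
    reproducible given the seed.
    """
    plan.validate()
    if model is None and plan.gradient is None:
        raise ValueError("need a background model or a gradient pair")
    rng = np.random.default_rng(seed)
    features = sorted(
        [("repeat_block", b) for b in plan.repeat_blocks]
        + [("foreign", f) for f in plan.foreign_segments],
        key=lambda t: t[1].start,
    )
    bg_zone = "gradient" if plan.gradient is not None else "background"
    bg_model_name = (
        f"{plan.gradient[0].name}|{plan.gradient[1].name}"
        if plan.gradient is not None
        else model.name
    )
    spacer_model = plan.gradient[1] if plan.gradient is not None else model

    def emit_background(x0, n):
        if plan.gradient is not None:
            edge, center = plan.gradient
            return _emit_gradient(edge, center, x0, n, plan.length, rng)
        return _emit_model(model, n, rng)

    pieces, truth, pos = [], [], 0
    for kind, feat in features:
        if feat.start > pos:
            pieces.append(emit_background(pos, feat.start - pos))
            truth.append((plan.name, pos, feat.start, bg_zone, bg_model_name))
        if kind == "repeat_block":
            pieces.append(_emit_block(feat, spacer_model, rng))
            truth.append(
                (plan.name, feat.start, feat.end, "repeat_block",
                 f"{feat.n_copies}x{len(feat.unit)}bp")
            )
        else:
            pieces.append(_emit_model(feat.model, feat.end - feat.start, rng))
            truth.append(
                (plan.name, feat.start, feat.end, "foreign", feat.model.name)
            )
        pos = feat.end
    if pos < plan.length:
        pieces.append(emit_background(pos, plan.length - pos))
        truth.append((plan.name, pos, plan.length, bg_zone, bg_model_name))
    states = np.concatenate(pieces)
    rec = GenomeRecord(
        record_id=plan.name, species=species, sequence=decode(states),
        chromosome_label=plan.name,
    )
    rows = [
        {"record_id": r[0], "species": species, "start": r[1], "end": r[2],
         "zone": r[3], "detail": r[4], "seed": seed}
        for r in truth
    ]
    return rec, rows


def generate_collection(
    species_models: dict,
    plans: dict,
    seed: int = 0,
    out_dir=None,
):
    """Generate a multi-species collection; deterministic per seed.

    Parameters
    ----------
    species_models : dict species name -> SpeciesModel, or a list of
        SpeciesModel (duplicate names rejected).
    plans : dict species name -> list of ChromosomePlan.
    out_dir : if given, writes one FASTA per species plus truth.tsv there.

    Returns
    -------
    (records, truth) : dict species -> [GenomeRecord, ...] and a truth
    DataFrame covering every emitted coordinate (with per-record seeds).
    """
    if not isinstance(species_models, dict):
        listed = list(species_models)
        names = [m.name for m in listed]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        species_models = {m.name: m for m in listed}
    names = list(species_models)
    ss = np.random.SeedSequence(seed)
    records, truth_rows = {}, []
    for sp in names:
        records[sp] = []
        for plan in plans[sp]:
            child = ss.spawn(1)[0]
            rec_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            rec, rows = generate_chromosome(
                sp, species_models[sp], plan, seed=rec_seed
            )
            records[sp].append(rec)
            truth_rows.extend(rows)
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        for sp in names:
            write_fasta(records[sp], os.path.join(out_dir, f"{sp}.fasta"))
        truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    return records, truth


def label_windows(windows, truth: pd.DataFrame) -> pd.DataFrame:
    """Dominant truth zone per window (zone with the largest base overlap)."""
    out = []
    for w in windows:
        sub = truth[(truth["record_id"] == w.record_id)
                    & (truth["start"] < w.end) & (truth["end"] > w.start)]
        if len(sub) == 0:
            out.append((w.window_id, "unknown", ""))
            continue
        ov = np.minimum(sub["end"], w.end) - np.maximum(sub["start"], w.start)
        best = sub.iloc[int(np.argmax(ov.to_numpy()))]
        out.append((w.window_id, best["zone"], best["detail"]))
    return pd.DataFrame(out, columns=["window_id", "zone", "detail"])
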