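"""Reference synthetic evaluation suites.

Standard study designs used by the test suite, the acceptance script and
the documentation examples: multi-species collections with known Markov
signatures, CG-suppression levels, chromosomal gradients, implanted
foreign segments and shared repeat families.  Every suite is deterministic
given its seed and returns both the data and the truth needed to score
recovery.

Sizes are desk-scale (tens of Mb per species) so a full end-to-end run
takes minutes on one CPU; the map analytics themselves are size-agnostic.
"""

from __future__ import annotations

import numpy as np

from . import blsom, genome_io, oligo
from . import synthetic_data as synth

# Species signatures: distinct base compositions, distinct CpG-suppression
# levels (the three frog-like Obs/Exp levels 0.45 / 0.30 / 0.57), one
# species with an extra purine-transition bias, and an isochore-like GC
# mosaic (gc_drift) so within-species windows form extended clouds as real
# genome fragments do.
_SPECIES_SPECS = {
    "speciesA": dict(pi=[0.32, 0.18, 0.18, 0.32], cg_suppression=0.45),
    "speciesB": dict(pi=[0.24, 0.26, 0.26, 0.24], cg_suppression=0.30),
    "speciesC": dict(
        pi=[0.28, 0.22, 0.22, 0.28], cg_suppression=0.57,
        transition_bias={"AG": 1.4, "CT": 1.4, "CA": 0.8, "TG": 0.8},
    ),
}


def species_models(distinct: bool = True, gc_drift: float = 0.08) -> dict:
    """Three species models; with ``distinct=False`` all share speciesA's
    signature (exchangeable labels) under their own names."""
    out = {}
    for name, spec in _SPECIES_SPECS.items():
        spec = spec if distinct else _SPECIES_SPECS["speciesA"]
        out[name] = synth.build_species_model(name, gc_drift=gc_drift, **spec)
    return out


def map_pipeline(records, window, step, k, avg_per_node,
                 max_n_fraction: float = 0.1):
    """Windows -> composition -> trained grid -> assignment, in one call."""
    allrec = [r for recs in records.values() for r in recs]
    windows, _ = genome_io.window_records(allrec, window, step, max_n_fraction)
    comp = oligo.composition_matrix(allrec, windows, k)
    meta, X, labels = oligo.split_matrix(comp)
    grid = blsom.pca_init(X, group_labels=labels, avg_per_node=avg_per_node)
    grid = blsom.train(grid, X)
    assignment = blsom.assign(grid, X, meta)
    return windows, comp, grid, assignment


def separation_collection(seed: int, distinct: bool = True,
                          mb_per_chromosome: int = 15):
    """Three species, two chromosomes each (30 Mb per species by default).

    With ``distinct=False`` all species share one signature *and* the
    isochore drift is turned off: the exchangeable-labels chance baseline
    (purity -> 1/n_species) presumes windows iid given the label, and
    chromosome-specific finite realizations of the drift track would break
    that at these genome sizes.
    """
    models = species_models(distinct=distinct,
                            gc_drift=0.08 if distinct else 0.0)
    plans = {
        sp: [
            synth.ChromosomePlan(name=f"{sp}_chr{i}",
                                 length=mb_per_chromosome * 1_000_000)
            for i in (1, 2)
        ]
        for sp in models
    }
    return synth.generate_collection(models, plans, seed=seed)


def suppression_models(levels=(0.3, 0.45, 0.57, 1.0)) -> dict:
    """Homogeneous (drift-free) models at the given target Obs/Exp levels,
    each carrying its stationary-distribution prediction as the oracle."""
    return {
        s: synth.build_species_model(f"s{s}", cg_suppression=s)
        for s in levels
    }


def gradient_chromosome(seed: int, edge_rich: bool = True,
                        length: int = 12_000_000):
    """One chromosome with a parabolic CG gradient.

    ``edge_rich=True`` puts the CG-rich model at the ends (CG rises toward
    both ends, upward fitted curvature); False puts it at the center
    (downward dome).
    """
    rich = synth.build_species_model(
        "cg_rich", pi=[0.25, 0.25, 0.25, 0.25], cg_suppression=0.9)
    poor = synth.build_species_model(
        "cg_poor", pi=[0.30, 0.20, 0.20, 0.30], cg_suppression=0.30)
    gradient = (rich, poor) if edge_rich else (poor, rich)
    plan = synth.ChromosomePlan(name="grad_chr", length=length,
                                gradient=gradient)
    return synth.generate_chromosome("gradient_species", None, plan, seed=seed)


def repeat_peak_chromosome(seed: int, length: int = 12_000_000,
                           block_starts=(3_500_000, 7_500_000),
                           n_copies: int = 1818):
    """Flat-background chromosome with ~1-Mb CG-rich tandem repeat blocks.

    Each block is ``n_copies`` of a fixed 520-bp CG-dense unit with 30-bp
    background spacers; returns (record, truth rows, block centers).
    """
    bg = synth.build_species_model(
        "peak_bg", pi=[0.30, 0.20, 0.20, 0.30], cg_suppression=0.30)
    unit = synth.cg_rich_repeat_unit(520, seed=7)
    blocks = [
        synth.RepeatBlock(start=s, n_copies=n_copies, unit=unit, spacer_len=30)
        for s in block_starts
    ]
    plan = synth.ChromosomePlan(name="peak_chr", length=length,
                                repeat_blocks=blocks)
    rec, truth = synth.generate_chromosome("peak_species", bg, plan, seed=seed)
    centers = [(b.start + b.end) / 2.0 for b in blocks]
    return rec, truth, centers


def purine_rich_repeat_unit(length: int = 520, seed: int = 0) -> str:
    """A polypurine/polypyrimidine-type unit (GA-rich on the given strand)."""
    model = synth.build_species_model(
        "pp_unit", pi=[0.40, 0.10, 0.35, 0.15], cg_suppression=1.0, seed=seed)
    rng = np.random.default_rng(seed)
    return synth.decode(synth._emit_plain(model, length, rng))


def ac_rich_repeat_unit(length: int = 520, seed: int = 0) -> str:
    """An AC/GT-dimer-rich unit (CA-microsatellite-like flavor)."""
    model = synth.build_species_model(
        "ac_unit", pi=[0.38, 0.30, 0.12, 0.20], cg_suppression=1.0, seed=seed)
    rng = np.random.default_rng(seed)
    return synth.decode(synth._emit_plain(model, length, rng))


def satellite_collection(seed: int, segment=(3_000_000, 7_000_000)):
    """Two species plus a 4-Mb repeat-rich mosaic zone inside species A.

    The implanted zone emulates an Mb-scale structure rich in kb-scale
    repetitive elements: each 100-kb slot carries random copy numbers
    (50-85 each) of two fixed 520-bp units — one polypurine-type, one
    AC-type — over species-A background, so zone windows scatter over a
    two-dimensional composition cloud.  Both units are GC-moderate, so the
    zone departs from the backgrounds along dimer axes orthogonal to the
    species' internal isochore (GC) spread and is not bridged by the GC
    tail of its host genome; it should occupy a multi-node lattice patch
    disconnected from the main territory.  Slot bounds are
    multiples of 100 kb so non-overlapping 100-kb windows align with the
    truth exactly; every zone window is repeat-dominated (>=55%).
    """
    models = {k: v for k, v in species_models().items()
              if k in ("speciesA", "speciesB")}
    unit_ga = purine_rich_repeat_unit(520, seed=8)
    unit_ac = ac_rich_repeat_unit(520, seed=9)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    blocks = []
    slot = 100_000
    spacing = 30
    per_copy = 520 + spacing
    for start in range(segment[0], segment[1], slot):
        n1 = int(rng.integers(50, 86))
        n2 = int(rng.integers(50, 86))
        b1 = synth.RepeatBlock(start=start, n_copies=n1, unit=unit_ga,
                               spacer_len=spacing)
        b2 = synth.RepeatBlock(start=start + n1 * per_copy, n_copies=n2,
                               unit=unit_ac, spacer_len=spacing)
        blocks.extend([b1, b2])
    plans = {
        "speciesA": [
            synth.ChromosomePlan("a1", 12_000_000),
            synth.ChromosomePlan("a2", 12_000_000, repeat_blocks=blocks),
            synth.ChromosomePlan("a3", 12_000_000),
            synth.ChromosomePlan("a4", 12_000_000),
        ],
        "speciesB": [
            synth.ChromosomePlan("b1", 12_000_000),
            synth.ChromosomePlan("b2", 12_000_000),
        ],
    }
    records, truth = synth.generate_collection(models, plans, seed=seed)
    zone_ids = [
        f"a2:{s}-{s + slot}" for s in range(segment[0], segment[1], slot)
    ]
    return records, truth, zone_ids


def shared_repeat_collection(seed: int):
    """The same ~1-Mb repeat family seeded into one scaffold of each of two
    species; block windows from both species are compositionally near-
    identical and should co-occupy (black) nodes.  Returns
    (records, truth, carrier record ids)."""
    models = {k: v for k, v in species_models().items()
              if k in ("speciesA", "speciesB")}
    unit = synth.cg_rich_repeat_unit(520, seed=7)

    def block(start):
        # spacer-free pure tandem array: block windows are compositionally
        # identical across species, as for a truly shared repeat family
        return [synth.RepeatBlock(start=start, n_copies=1923, unit=unit,
                                  spacer_len=0)]

    plans = {
        "speciesA": [
            synth.ChromosomePlan("a1", 8_000_000),
            synth.ChromosomePlan("a2", 8_000_000, repeat_blocks=block(4_000_000)),
        ],
        "speciesB": [
            synth.ChromosomePlan("b1", 8_000_000),
            synth.ChromosomePlan("b2", 8_000_000, repeat_blocks=block(5_000_000)),
        ],
    }
    records, truth = synth.generate_collection(models, plans, seed=seed)
    return records, truth, {"speciesA": "a2", "speciesB": "b2"}


def cluster_vectors(seed: int, n_per_cluster: int = 1000, n_clusters: int = 3,
                    dim: int = 10) -> np.ndarray:
    """Synthetic composition-like vectors: Dirichlet clusters on the simplex."""
    rng = np.random.default_rng(seed)
    centers = rng.dirichlet(np.ones(dim) * 5, size=n_clusters)
    return np.vstack(
        [rng.dirichlet(c * 400, size=n_per_cluster) for c in centers]
    )
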