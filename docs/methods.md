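# Methods

## Degenerate oligonucleotide composition

Assemblies register an arbitrary strand per scaffold, and for genome-level
composition statistics the two strands carry the same information, so every
k-mer is pooled with its reverse complement into a degenerate group
(`AA+TT`, `AG+CT`, …); self-complementary words (`AT`, `CG`, `GC`, `TA` at
k = 2) form singleton groups.  Counting is single-strand over all
overlapping k-mers, equivalent to canonical k-mer counting; any k-mer
touching an N is skipped, and a window whose every k-mer touches an N is
flagged invalid and excluded downstream.  Group counts are 4^k/2 for odd k
and (4^k + 4^(k/2))/2 for even k: 2, 10, 32, 136 for k = 1–4.  Composition
vectors are frequencies (counts / valid k-mers), so windows of different
lengths are comparable.

Windows are fixed-length with a sliding step (defaults 1 Mb / 100 kb; the
finer 1-Mb / 10-kb setting increases the weight of positional continuity),
never cross record boundaries, and trailing partial windows are discarded
so all vectors describe equal-length fragments.  Windows with more than
`max_n_fraction` (default 0.1) N bases are excluded and counted in a
report.  Coordinates are 0-based half-open everywhere, including BED
output.  Sub-window-size scaffolds are skipped, not concatenated:
concatenation would manufacture chimeric windows across arbitrary scaffold
joins.

## Batch-learning SOM

Weights live on an I × J lattice.  The node budget B = N / `avg_per_node`
(default 10 windows per node; 100 for the fine-step maps) gives
I = round(√(B·σ1/σ2)) and J = ⌈(σ2/σ1)·I⌉, both clipped to ≥ 2, where
σ1, σ2 are the SDs of the first two principal-component scores of the
composition matrix (covariance PCA).  Initial weights are laid out on the
PC1/PC2 plane:

    w_ij = x_av + (5 σ1 / I) · [ b1 (i − I/2) + b2 (j − J/2) ]

so the first lattice dimension spans about five SDs of the widest axis of
the data cloud.  Eigenvector signs are fixed (largest-magnitude component
positive) so maps are reproducible across linear-algebra backends.

Training is fully batch.  Per epoch: (1) every vector is assigned to its
best-matching node (minimal Euclidean distance; ties to the smallest
(i, j)); (2) every node moves halfway toward the mean of the vectors
assigned within its square (Chebyshev) neighborhood,
`w ← w + 0.5 (neighborhood mean − w)`; nodes with empty neighborhoods are
unchanged.  The integer radius shrinks linearly from max(I, J)/2 to 1 (one
epoch per radius, padded to at least 8 epochs, plus two extra radius-1
epochs).  Two alternatives were evaluated and rejected: full mean
replacement at all radii collapses the PCA scaffold onto exact weight
plateaus when clusters are tight (argmin ties then drop whole clusters
onto single nodes), and full replacement at radius 1 drags interpolating
nodes into inter-cluster gaps, bridging territories.  The blended update
preserves both the map topology and the empty "moats" that separate
territories.

**Order-independence, bitwise.**  Floating-point summation is not
associative, so batch updates computed in input order would differ in the
last bits under row permutation.  All reductions (mean, covariance,
per-node sums) are computed over an internal canonical ordering of the
rows (lexicographic sort), which depends only on the multiset of vectors;
permuting the input therefore yields a bit-identical trained map, and
there is no randomness anywhere in initialization or training.
Quantization error is recorded per epoch and is non-increasing over the
late schedule (small transients are possible while the radius is large).

## Map analytics

*Territories.*  A node is `empty` (no members), `pure` (one species),
`majority` (top species fraction strictly > 0.5, only in `majority50`
mode), else `mixed` — rendered black, marking cross-species compositional
similarity.  Clustering purity (Σ per-node max species count / Σ members)
summarizes separation; under exchangeable labels it approaches
1/n_species as node occupancy grows, and a label-permutation null
(`purity_null`) gives the finite-occupancy chance baseline.

*Contribution heat maps.*  For one degenerate group, non-empty nodes are
stably sorted by weight value (descending, then i, j) and cut at ranks
⌈n/3⌉ and ⌈2n/3⌉ into high (pink) / moderate (white) / low (green); value
ties share the class of their first occurrence, so an all-equal map is all
high.

*Satellites.*  A satellite is a small connected component of a species'
nodes disconnected from its main (largest) territory.  Components are
taken under 8-neighbor (Moore) adjacency over the species' *densely
occupied* nodes — nodes holding at least 30% of the species' mean node
occupancy (maps with ~1 member per node are unaffected).  Sparse
classified nodes then act as connectors among minor components
(satellite-internal sparsity) but never merge anything into the main
territory: a sparse node touching the main is read as main-territory
periphery and contributes its windows there.  This density step exists
because a single interpolating node holding one or two stray windows can
otherwise diagonally bridge a genuine satellite into the main territory.
Satellites are reported when `min_size` ≤ dense-node count ≤
`max_fraction_of_main` × main size (defaults 3 and 0.25; both are
configuration, not biology).  Satellite enrichment divides the
count-pooled composition of the satellite's member windows by the species'
whole-genome composition and reports the top-n groups; a zero genome
frequency yields a flagged `inf`.

*Shared and adjacent nodes.*  Shared nodes hold at least one window from
each of two filtered window sets (e.g. two species, or one species versus
one chromosome of another) and report the union of set-A source scaffolds.
Adjacent-node extraction returns set-B-occupied nodes within a Chebyshev
lattice distance of a species territory; distance 0 reduces to
co-occupancy.

## CpG metrics and profiles

`Obs/Exp = f(CG)/(f(C)·f(G))` with single-strand frequencies over N-free
bases and dinucleotides — the standard CpG odds ratio; `CG/GC` is the
plain count ratio on the given strand.  Both are invariant under reverse
complement (CG and GC are self-complementary).  Genome-wide values pool
counts *before* dividing; a mean of per-window ratios is a different (and
biased) statistic.  Undefined cases (f(C)·f(G) = 0, GC count 0, fewer than
2 valid bases) return NaN with a warning.

Chromosome profiles report per-window group composition in percent at
window midpoints, for arbitrary degenerate groups of mixed k (e.g. `CG`,
`CCG+CGG`, pentanucleotide cores such as `CTTCC+GGAAG`).  The smooth
baseline is an ordinary least-squares degree-2 polynomial (fitted on
centered/scaled positions for conditioning, coefficients mapped back to
base coordinates); a < 0 is a downward-opening parabola.  Peaks are local
maxima of the residuals about that baseline with prominence ≥
`min_prominence` (default 2× residual SD, with a 1e-8-scale numerical
floor); the track is padded below its minimum so end windows can qualify.
A peak within `terminal_fraction` (default 0.05) of either chromosome end
is terminal, else internal.

## Synthetic genome generator

Each species is a first-order Markov chain over {A, C, G, T}: base
composition π plus a CpG-suppression level s.  The chain starts from the
independence baseline P(b|a) = π_b; the C-row entry for G is multiplied by
a factor m and the row renormalized.  Because renormalization and the
shifted stationary distribution feed back on the odds ratio, a raw
multiplier m = s does not produce Obs/Exp = s; by default m is solved
numerically (brentq on the monotone map m ↦ predicted Obs/Exp) so that the
stationary-distribution prediction equals the requested target exactly
(`calibrate=False` keeps the raw-multiplier construction).  The stationary
prediction — P(G|C)/π̂_G with π̂ the numerically solved stationary
distribution — is stored on the model and serves as the oracle for
empirical estimates; on a 10-Mb chromosome the pipeline recovers it within
Monte-Carlo error (compared at 3 standard errors estimated from 100-kb
chunks).  Optional `transition_bias` multiplies arbitrary P(a→b) entries
before renormalization to shape distinct species signatures.

Three landscape features:

* **Isochore-like GC drift** (`gc_drift`, default off): the background is
  emitted as a position-varying mixture of GC-boosted and GC-reduced
  variants of the chain, with a piecewise-linear mixture track (uniform
  knots every `drift_scale` = 500 kb).  Real vertebrate chromosomes are
  Mb-scale GC mosaics; without this, all windows of a species are nearly
  identical and collapse onto one or two map nodes, which real data do
  not.  Drift is off by default so the stationary oracle stays exact; the
  territory study suites use 0.08 (≈ ±1.5% G+C swing).
* **Parabolic gradient**: per-position transition matrix
  `w(x)·P_edge + (1 − w(x))·P_center` with `w(x) = (2x/L − 1)²`, so the
  edge model dominates both chromosome ends.  A CG-rich edge model yields
  end maxima and an upward fitted curvature; a CG-rich center model yields
  the downward dome.
* **Repeat blocks**: n copies of a fixed unit (default a 520-bp CG-dense,
  C/G-rich transposon-like unit generated once from a high-CG chain) with
  short background spacers; ~1,800 copies form an Mb-scale CG-rich block
  that profiles as a sharp internal peak.

All randomness flows from one numpy `SeedSequence`; per-record child seeds
are recorded in the truth tables, and regeneration at the same seed is
byte-identical.  Sequence emission uses a numba-jitted chain walker fed
with pre-drawn Generator uniforms, so output does not depend on the JIT
backend's RNG.  Truth tables tile every emitted coordinate with zone
labels (background / gradient / repeat_block / foreign) and support
window-level labeling by maximal overlap.

### What the suites emulate — and what they do not

The reference suites (`sigsom.suites`) fix the study designs used by the
tests and the acceptance script: three 30-Mb species with distinct
signatures at suppression targets 0.45 / 0.30 / 0.57 (the span observed
across real frog genomes) for separation; the same sizes with one shared
signature and no drift for the exchangeability control (the 1/n chance
baseline presumes windows iid given the label, which a finite drift
realization would break); 12-Mb chromosomes for gradients and peak calls;
a 4-Mb repeat-rich mosaic zone (random 50–85 copies per 100-kb slot of two
GC-moderate 520-bp families, polypurine-type and AC-type) implanted in one
species for satellite recovery; and a spacer-free ~1-Mb tandem array of
one CG-rich unit seeded into one scaffold of each of two species for
shared-node recovery.  Desk-scale sizes (≈ 300 Mb generated in total) keep
a full acceptance run within minutes on one CPU.

First-order chains control dinucleotide-level signatures; real genome
signatures extend to tetranucleotides and beyond, and real repeats mutate,
nest and fragment.  Passing these suites therefore demonstrates that the
pipeline recovers planted dinucleotide-scale structure and repeat blocks
under realistic noise — not that it resolves every signature difference
real genomes exhibit, nor anything about assembly quality, repeat
annotation or alignment, which are out of scope.

## Numerical and design notes

* Mononucleotide maps use the degenerate pairs {A+T}, {C+G} (two
  dimensions), keeping the strand convention uniform across k.
* `assign` breaks exact distance ties to the smallest (i, then j);
  `contribution_heatmap` resolves value ties by first occurrence in the
  stable sort.
* `size_grid` warns and forces J = 2 when σ2 is degenerate (zero second
  axis).
* PCA initialization requires ≥ 3 distinct vectors; all-identical input is
  an error, as is NaN anywhere in the composition matrix.
* Quadratic fits require ≥ 3 points; collinear input returns a ≈ 0 rather
  than an error.
* Known limitations: territories of compositionally overlapping species
  merge (black) by design; satellite extraction is sensitive to its
  density and size thresholds on very small maps; the generator's
  gradient and drift models are mixtures of two chains, not continuous
  families.
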