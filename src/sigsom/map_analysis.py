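"""Map products derived from BLSOM assignments.

Turns node assignments into the analytics used to read a genome-signature
map: species territory classification (pure / >50%-majority / mixed-black /
empty nodes), rank-based per-oligonucleotide contribution heat maps
(pink/white/green tertiles), satellite-territory extraction with
composition-enrichment ratios, and shared / adjacent node extraction across
species.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .blsom import BLSOMGrid, NodeAssignment
from .oligo import META_COLUMNS

_MOORE = np.ones((3, 3), dtype=bool)  # 8-neighbor lattice adjacency


@dataclass
class TerritoryMap:
    """Per-node species classification of a lattice.

    ``frame`` has one row per node: i, j, n, top_species, top_fraction,
    klass in {empty, pure, majority, mixed}.  In ``pure_only`` mode any node
    with more than one species is mixed; in ``majority50`` mode a node whose
    top species exceeds 50% of members takes that species' color.
    """

    I: int
    J: int
    mode: str
    frame: pd.DataFrame

    def klass_lattice(self) -> np.ndarray:
        arr = np.empty((self.I, self.J), dtype=object)
        arr[self.frame["i"], self.frame["j"]] = self.frame["klass"]
        return arr

    def species_mask(self, species: str) -> np.ndarray:
        """Boolean (I, J) mask of nodes classified to ``species``."""
        mask = np.zeros((self.I, self.J), dtype=bool)
        sel = self.frame[
            (self.frame["top_species"] == species)
            & self.frame["klass"].isin(["pure", "majority"])
        ]
        mask[sel["i"], sel["j"]] = True
        return mask


def classify_nodes(assignment: NodeAssignment, mode: str = "majority50") -> TerritoryMap:
    """Classify every lattice node as empty / pure / majority / mixed."""
    if mode not in ("majority50", "pure_only"):
        raise ValueError(f"unknown mode {mode!r}")
    counts = assignment.species_counts()
    n = counts.sum(axis=1)
    rows = []
    species_cols = list(counts.columns)
    values = counts.to_numpy()
    for idx, (i, j) in enumerate(counts.index):
        total = int(n.iloc[idx])
        if total == 0:
            rows.append((i, j, 0, None, np.nan, "empty"))
            continue
        top = int(values[idx].argmax())
        top_n = int(values[idx][top])
        frac = top_n / total
        n_species = int((values[idx] > 0).sum())
        if n_species == 1:
            klass = "pure"
        elif mode == "majority50" and frac > 0.5:
            klass = "majority"
        else:
            klass = "mixed"
        rows.append((i, j, total, species_cols[top], frac, klass))
    frame = pd.DataFrame(
        rows, columns=["i", "j", "n", "top_species", "top_fraction", "klass"]
    )
    return TerritoryMap(I=assignment.I, J=assignment.J, mode=mode, frame=frame)


def territory_purity(assignment: NodeAssignment) -> float:
    """Clustering purity: sum of per-node max species counts / total windows.

    1.0 means every non-empty node is single-species; the chance level for
    exchangeable labels approaches 1/n_species as per-node occupancy grows
    (see :func:`purity_null` for the finite-occupancy baseline).
    """
    counts = assignment.species_counts().to_numpy()
    total = counts.sum()
    if total == 0:
        raise ValueError("assignment is empty")
    return float(counts.max(axis=1).sum() / total)


def purity_null(assignment: NodeAssignment, n_perm: int = 20, seed: int = 0) -> float:
    """Chance purity under random species labels (label permutation null)."""
    rng = np.random.default_rng(seed)
    frame = assignment.frame
    vals = []
    for _ in range(n_perm):
        shuffled = frame.copy()
        shuffled["species"] = rng.permutation(frame["species"].to_numpy())
        vals.append(
            territory_purity(NodeAssignment(assignment.I, assignment.J, shuffled))
        )
    return float(np.mean(vals))


@dataclass
class ContributionHeatmap:
    """Rank-tertile classes of one degenerate group over non-empty nodes.

    high (pink) / moderate (white) / low (green); empty nodes carry None.
    """

    group_label: str
    I: int
    J: int
    frame: pd.DataFrame  # i, j, value, klass over non-empty nodes

    def klass_lattice(self) -> np.ndarray:
        arr = np.full((self.I, self.J), None, dtype=object)
        arr[self.frame["i"], self.frame["j"]] = self.frame["klass"]
        return arr


def contribution_heatmap(
    grid: BLSOMGrid, assignment: NodeAssignment, group_label: str
) -> ContributionHeatmap:
    """Tertile heat map of one group's weight value over non-empty nodes.

    Non-empty nodes are stably sorted by (value descending, i, j); ranks in
    the top / middle / bottom tertile (boundaries at ceil(n/3) and
    ceil(2n/3)) class as high / moderate / low, and value ties all share the
    class of their first occurrence.
    """
    if group_label not in grid.group_labels:
        raise KeyError(f"unknown group label {group_label!r}")
    gi = list(grid.group_labels).index(group_label)
    occupied = assignment.frame.groupby(["i", "j"]).size().index
    nodes = [(int(i), int(j)) for i, j in occupied]
    values = {ij: grid.weights[grid.node_index(*ij), gi] for ij in nodes}
    order = sorted(nodes, key=lambda ij: (-values[ij], ij[0], ij[1]))
    n = len(order)
    hi_end, mid_end = math.ceil(n / 3), math.ceil(2 * n / 3)
    klass, prev_val = {}, None
    for rank, ij in enumerate(order):
        k = "high" if rank < hi_end else ("moderate" if rank < mid_end else "low")
        if prev_val is not None and values[ij] == prev_val:
            k = klass[order[rank - 1]]
        klass[ij] = k
        prev_val = values[ij]
    frame = pd.DataFrame(
        [(i, j, values[(i, j)], klass[(i, j)]) for i, j in order],
        columns=["i", "j", "value", "klass"],
    )
    return ContributionHeatmap(group_label=group_label, I=grid.I, J=grid.J, frame=frame)


@dataclass
class SatelliteTerritory:
    """A small species territory disconnected from the species' main one."""

    species: str
    nodes: list  # [(i, j), ...]
    window_ids: list
    size: int
    enrichment: list = field(default_factory=list)  # [(group label, ratio), ...]


def extract_satellites(
    tmap: TerritoryMap,
    assignment: NodeAssignment,
    species: str,
    min_size: int = 3,
    max_fraction_of_main: float = 0.25,
    min_node_members: int | None = None,
) -> list:
    """Connected components of a species' nodes other than its main territory.

    Components are taken under 8-neighbor (Moore) adjacency over the
    species' *densely occupied* nodes; the largest is the main territory,
    and every other component with
    ``min_size <= size <= max_fraction_of_main * main_size`` is reported
    together with the windows assigned to its nodes.

    Density denoising: a node holding only a stray window or two is not
    territory — left in place, a single sparse interpolating node can
    diagonally bridge two otherwise separate regions.  Components are
    therefore labeled over nodes with at least ``min_node_members`` members
    (default: 30% of the species' mean node occupancy, so maps with
    ~1 member/node are untouched).  Sparse species nodes then act as
    connectors among *minor* components — satellite-internal sparsity —
    but never merge anything into the main territory: a sparse node
    touching the main is read as main-territory periphery and its windows
    go to the main.
    """
    if tmap.mode != "majority50":
        raise ValueError("satellite extraction expects a majority50 territory map")
    mask = tmap.species_mask(species)
    if not mask.any():
        raise ValueError(f"species {species!r} holds no nodes on this map")
    counts = np.zeros((tmap.I, tmap.J), dtype=int)
    occ = assignment.frame.groupby(["i", "j"]).size()
    counts[occ.index.get_level_values(0), occ.index.get_level_values(1)] = occ
    if min_node_members is None:
        min_node_members = int(np.ceil(0.3 * counts[mask].mean()))
    dense = mask & (counts >= min_node_members)
    if not dense.any():
        dense = mask
    labeled, n_comp = ndimage.label(dense, structure=_MOORE)
    dense_sizes = np.bincount(labeled.ravel(), minlength=n_comp + 1)
    main = int(dense_sizes[1:].argmax()) + 1
    main_size = int(dense_sizes[main])

    parent = list(range(n_comp + 1))

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    comp_of = {
        (int(i), int(j)): int(labeled[i, j]) for i, j in zip(*np.nonzero(dense))
    }
    unresolved = {(int(i), int(j)) for i, j in zip(*np.nonzero(mask & ~dense))}
    changed = True
    while changed and unresolved:
        changed = False
        for node in sorted(unresolved):
            i, j = node
            neigh = {
                find(comp_of[(i + di, j + dj)])
                for di in (-1, 0, 1)
                for dj in (-1, 0, 1)
                if (i + di, j + dj) in comp_of
            }
            if not neigh:
                continue
            if find(main) in neigh:
                comp_of[node] = find(main)
            else:
                tgt = min(neigh)
                for c in neigh:
                    parent[find(c)] = tgt
                comp_of[node] = tgt
            unresolved.discard(node)
            changed = True

    classes = {}
    for node, c in comp_of.items():
        classes.setdefault(find(c), []).append(node)
    frame = assignment.frame
    out = []
    for root in sorted(classes):
        if root == find(main):
            continue
        nodes = classes[root]
        size = int(sum(1 for n in nodes if dense[n]))
        if not (min_size <= size <= max_fraction_of_main * main_size):
            continue
        node_set = set(nodes)
        members = frame[
            [(i, j) in node_set for i, j in zip(frame["i"], frame["j"])]
        ]
        out.append(
            SatelliteTerritory(
                species=species,
                nodes=sorted(node_set),
                window_ids=members["window_id"].tolist(),
                size=size,
            )
        )
    return out


def pooled_composition(comp: pd.DataFrame, window_ids=None) -> pd.Series:
    """Count-pooled group frequencies over a window subset (or all windows).

    Pools counts before normalizing (frequencies weighted by each window's
    total k-mer count), which is the correct aggregate composition rather
    than a mean of per-window frequencies.
    """
    sub = comp if window_ids is None else comp[comp["window_id"].isin(set(window_ids))]
    if len(sub) == 0:
        raise ValueError("no windows selected for pooling")
    labels = [c for c in comp.columns if c not in META_COLUMNS]
    totals = sub["total_count"].to_numpy(dtype=np.float64)
    pooled = (sub[labels].to_numpy() * totals[:, None]).sum(axis=0) / totals.sum()
    return pd.Series(pooled, index=labels)


def enrichment_ratios(
    satellite: SatelliteTerritory,
    comp: pd.DataFrame,
    genome_freq: pd.Series,
    top_n: int = 10,
) -> list:
    """Top-n group enrichment of a satellite vs. the entire genome.

    Pools the satellite members' composition and divides element-wise by the
    species' whole-genome composition; returns the ``top_n`` (label, ratio)
    pairs in descending ratio order.  A zero genome frequency with non-zero
    satellite frequency yields ``inf`` (flagged by a warning).
    """
    if not satellite.window_ids:
        raise ValueError("satellite has no member windows")
    sat = pooled_composition(comp, satellite.window_ids)
    genome = genome_freq.reindex(sat.index).to_numpy(dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = sat.to_numpy() / genome
    ratio = np.where((genome == 0) & (sat.to_numpy() == 0), 1.0, ratio)
    if np.isinf(ratio).any():
        warnings.warn("genome frequency of some groups is 0; ratio reported as inf")
    order = np.argsort(-ratio, kind="stable")[:top_n]
    pairs = [(sat.index[o], float(ratio[o])) for o in order]
    satellite.enrichment = pairs
    return pairs


@dataclass
class SharedNodeSet:
    """Black nodes co-occupied by two window sets, with set-A provenance."""

    nodes: list  # [(i, j), ...]
    a_record_ids: list
    frame: pd.DataFrame  # members of either set on the shared nodes


def _apply_filter(frame: pd.DataFrame, filt) -> pd.Series:
    """Window filter: dict of column -> value(s), or callable(frame) -> mask."""
    if callable(filt):
        return pd.Series(np.asarray(filt(frame), dtype=bool), index=frame.index)
    mask = pd.Series(True, index=frame.index)
    for col, val in filt.items():
        if col not in frame.columns:
            raise KeyError(f"filter column {col!r} not in assignment frame")
        if isinstance(val, (list, tuple, set)):
            mask &= frame[col].isin(val)
        else:
            mask &= frame[col] == val
    return mask


def shared_nodes(assignment: NodeAssignment, set_a_filter, set_b_filter) -> SharedNodeSet:
    """Nodes holding at least one window from each of two filtered sets.

    Returns the co-occupied node coordinates, the union of set-A source
    record ids (scaffolds) on those nodes, and the member windows.
    """
    frame = assignment.frame
    mask_a = _apply_filter(frame, set_a_filter)
    mask_b = _apply_filter(frame, set_b_filter)
    if not mask_a.any() or not mask_b.any():
        warnings.warn("a shared-node filter selected no windows; result is empty")
        return SharedNodeSet(nodes=[], a_record_ids=[], frame=frame.iloc[0:0])
    nodes_a = set(map(tuple, frame.loc[mask_a, ["i", "j"]].itertuples(index=False)))
    nodes_b = set(map(tuple, frame.loc[mask_b, ["i", "j"]].itertuples(index=False)))
    shared = sorted(nodes_a & nodes_b)
    shared_set = set(shared)
    on_shared = [
        (i, j) in shared_set for i, j in zip(frame["i"], frame["j"])
    ]
    members = frame[(mask_a | mask_b) & pd.Series(on_shared, index=frame.index)]
    a_members = frame[mask_a & pd.Series(on_shared, index=frame.index)]
    return SharedNodeSet(
        nodes=shared,
        a_record_ids=sorted(a_members["record_id"].unique().tolist()),
        frame=members,
    )


def adjacent_nodes(
    assignment: NodeAssignment,
    set_b_filter,
    territory_species: str,
    max_lattice_distance: int,
    tmap: TerritoryMap | None = None,
):
    """Set-B-occupied nodes within Chebyshev distance of a species territory.

    With ``max_lattice_distance=0`` this reduces to set-B occupancy of the
    territory's own nodes.  Returns (node list, set-B window ids).
    """
    if tmap is None:
        tmap = classify_nodes(assignment, "majority50")
    mask = tmap.species_mask(territory_species)
    if max_lattice_distance > 0:
        mask = ndimage.binary_dilation(
            mask, structure=_MOORE, iterations=max_lattice_distance
        )
    frame = assignment.frame
    mask_b = _apply_filter(frame, set_b_filter)
    sel = mask_b & pd.Series(
        mask[frame["i"].to_numpy(), frame["j"].to_numpy()], index=frame.index
    )
    nodes = sorted(set(map(tuple, frame.loc[sel, ["i", "j"]].itertuples(index=False))))
    return nodes, frame.loc[sel, "window_id"].tolist()
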