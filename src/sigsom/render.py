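"""Optional PNG rendering of lattices and chromosome profiles.

Colors follow the map conventions: a per-species palette, black for mixed
nodes, white for empty ones; contribution heat maps in pink (high), white
(moderate), green (low); profiles as a value track with the quadratic
baseline dashed.
"""

from __future__ import annotations

import numpy as np

_HEAT_COLORS = {"high": "#ff9ecb", "moderate": "#ffffff", "low": "#7fc97f"}


def _axes(figsize):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=figsize)
    return fig, ax


def plot_territory(tmap, path, palette=None):
    from matplotlib.colors import ListedColormap

    species = sorted(
        s for s in tmap.frame["top_species"].dropna().unique()
    )
    if palette is None:
        import matplotlib.pyplot as plt

        cmap = plt.get_cmap("tab10")
        palette = {sp: cmap(n % 10) for n, sp in enumerate(species)}
    colors = {"__empty__": (1, 1, 1, 1), "__mixed__": (0, 0, 0, 1)}
    keys = ["__empty__", "__mixed__"] + species
    img = np.zeros((tmap.I, tmap.J), dtype=int)
    for row in tmap.frame.itertuples():
        if row.klass in ("pure", "majority"):
            img[row.i, row.j] = keys.index(row.top_species)
        elif row.klass == "mixed":
            img[row.i, row.j] = 1
    cmap = ListedColormap([colors.get(k, palette.get(k)) for k in keys])
    fig, ax = _axes((6, 6 * tmap.J / max(tmap.I, 1)))
    ax.imshow(img.T, origin="lower", cmap=cmap, vmin=0, vmax=len(keys) - 1)
    ax.set_xlabel("i")
    ax.set_ylabel("j")
    ax.set_title(f"species territories ({tmap.mode})")
    fig.savefig(path, dpi=150, bbox_inches="tight")


def plot_heatmap(hm, path):
    img = np.ones((hm.I, hm.J, 3))
    for row in hm.frame.itertuples():
        c = _HEAT_COLORS[row.klass]
        img[row.i, row.j] = [int(c[k : k + 2], 16) / 255 for k in (1, 3, 5)]
    fig, ax = _axes((6, 6 * hm.J / max(hm.I, 1)))
    ax.imshow(img.transpose(1, 0, 2), origin="lower")
    ax.set_title(f"contribution of {hm.group_label}")
    fig.savefig(path, dpi=150, bbox_inches="tight")


def plot_profile(profile, path):
    fig, ax = _axes((8, 3))
    x = profile.positions / 1e6
    ax.plot(x, profile.values, lw=0.8)
    if profile.fitted is not None:
        ax.plot(x, profile.fitted, "--", color="brown", lw=1.0)
    for p in profile.peaks:
        ax.axvline(p.position / 1e6, color="red" if p.klass == "internal" else "gray",
                   alpha=0.4, lw=0.8)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel(f"{profile.group_label} composition (%)")
    ax.set_title(profile.record_id)
    fig.savefig(path, dpi=150, bbox_inches="tight")
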