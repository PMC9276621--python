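"""Optional figure helpers (requires matplotlib; not a core dependency).

Regenerates the two standard views from a written run directory: cell
profiles n(x, t) with the advancing/stalling front, and the front path
L(t).  These are conveniences for inspection, not part of the library API.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .interface import read_trajectory


def plot_run(run_dir, times=None, ax=None):
    """Plot n(x) snapshots and L(t) from a trajectory run directory."""
    import matplotlib.pyplot as plt

    front, profiles, manifest = read_trajectory(run_dir)
    xi = np.array([float(c) for c in profiles.columns[1:]])
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    t_all = profiles["t"].to_numpy()
    sel = np.linspace(0, len(t_all) - 1, 8).astype(int) if times is None else [
        int(np.argmin(np.abs(t_all - t))) for t in times
    ]
    for k in sel:
        L = front["L"].iloc[k]
        axes[0].plot(xi * L, profiles.iloc[k, 1:], "k-", lw=0.8)
    axes[0].set(xlabel="x", ylabel="n(x, t)")
    axes[1].plot(front["t"], front["L"], "k-")
    axes[1].set(xlabel="t", ylabel="L(t)")
    fig.tight_layout()
    return fig
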