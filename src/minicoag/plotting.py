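"""Optional matplotlib helpers (side-effect only; nothing quantitative).

All acceptance-relevant output of the package is CSV/JSON; these plots are
conveniences for eyeballing thrombin-generation curves.
"""

from __future__ import annotations

from typing import Mapping

from .simulate import Trajectory, thrombin_series

__all__ = ["plot_thrombin_curves", "plot_species_panel"]


def plot_thrombin_curves(trajectories: Mapping[str, Trajectory], ax=None, path=None):
    """Overlay thrombin-generation curves of several models.

    Parameters
    ----------
    trajectories : mapping of label -> Trajectory
    ax : matplotlib Axes, optional
    path : str, optional
        If given, the figure is saved there.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, traj in trajectories.items():
        times, th = thrombin_series(traj)
        ax.plot(times, th, label=label)
    ax.set_xlabel("time [s]")
    ax.set_ylabel("[TH] [mM]")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def plot_species_panel(reference: Trajectory, candidate: Trajectory,
                       species: Mapping[str, str], path=None):
    """Side-by-side species comparison between two trajectories.

    ``species`` maps the reference model's species names to the candidate
    model's (e.g. ``{"FX": "X"}``).
    """
    import matplotlib.pyplot as plt

    n = len(species)
    ncols = min(3, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows),
                             squeeze=False)
    for ax, (ref_name, cand_name) in zip(axes.flat, species.items()):
        ax.plot(reference.times, reference.series(ref_name), "--", label="reference")
        ax.plot(candidate.times, candidate.series(cand_name), "-", label="minimal")
        ax.set_title(ref_name)
        ax.set_xlabel("time [s]")
        ax.set_ylabel("[mM]")
    axes.flat[0].legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig
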