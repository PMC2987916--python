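"""Matplotlib views of network metrics across sparsity."""

from __future__ import annotations

import pandas as pd


def plot_small_world_curve(curve: pd.DataFrame, ax=None):
    """Plot gamma and lambda versus sparsity for one group.

    ``curve`` is the output of :func:`covnet.model.small_world_curve`.
    gamma staying above 1 while lambda hugs 1 is the small-world signature.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve["sparsity"], curve["gamma"], "o-", color="tab:blue", label=r"$\gamma = C_p/C_p^{rand}$")
    ax.plot(curve["sparsity"], curve["lambda"], "s-", color="black", label=r"$\lambda = L_p/L_p^{rand}$")
    ax.axhline(1.0, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("sparsity")
    ax.set_ylabel("ratio to degree-matched surrogates")
    ax.legend()
    return ax


def plot_group_metric(curves: dict[str, pd.DataFrame], metric: str = "Cp", ax=None):
    """Overlay one metric (Cp, Lp, gamma or lambda) for several groups."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for group, curve in curves.items():
        ax.plot(curve["sparsity"], curve[metric], "o-", label=group)
    ax.set_xlabel("sparsity")
    ax.set_ylabel(metric)
    ax.legend()
    return ax
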