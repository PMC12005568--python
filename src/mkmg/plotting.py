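"""Minimal density/hazard overlay plots (smoke-level helper).

Requires matplotlib (optional dependency, ``pip install mkmg[plots]``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_density_hazard"]


def plot_density_hazard(model, x_max: float | None = None, ax=None, sample=None):
    """Plot the model PDF and HRF, optionally over a sample histogram."""
    import matplotlib.pyplot as plt

    if x_max is None:
        x_max = float(model.ppf(0.995))
    x = np.linspace(x_max / 400, x_max, 400)
    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(9, 3.5))
    if sample is not None:
        ax[0].hist(sample, bins="auto", density=True, alpha=0.4, color="grey")
    ax[0].plot(x, model.pdf(x))
    ax[0].set_title("density")
    ax[1].plot(x, model.hrf(x))
    ax[1].set_title("hazard")
    return ax
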