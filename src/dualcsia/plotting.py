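"""Minimal dual-element scatter with the fitted regression line."""

from __future__ import annotations

import numpy as np


def dual_element_plot(results, ax=None):
    """delta13C vs delta37Cl scatter plus the fitted Lambda line.

    Parameters
    ----------
    results : DualElementResults
        A fitted dual-element model (must carry its model/series).
    ax : matplotlib Axes, optional

    Returns
    -------
    matplotlib Axes
    """
    import matplotlib.pyplot as plt

    if results.model is None:
        raise ValueError("plotting needs a results object fitted from a series")
    if ax is None:
        _, ax = plt.subplots()
    pts = results.model.series.paired_points()
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    ax.plot(x, y, "o", mfc="none", label="measurements")
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(
        grid,
        results.intercept + results.lam * grid,
        "--",
        label=rf"$\Lambda$ = {results.lam:.1f} (R$^2$ = {results.r_squared:.2f})",
    )
    ax.set_xlabel(r"$\delta^{37}$Cl [‰]")
    ax.set_ylabel(r"$\delta^{13}$C [‰]")
    series = results.model.series
    ax.set_title(f"{series.compound} ({series.cultivation_acceptor}-grown cells)")
    ax.legend()
    return ax
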