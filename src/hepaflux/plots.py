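"""Diagnostic plots for the outcome model."""

from __future__ import annotations

import numpy as np

from .outcome_model import OutcomeModelFit, partial_residuals


def partial_residual_plot(fit: OutcomeModelFit, term: str, ax=None):
    """Partial residual (component-plus-residual) plot for one model term.

    Dots are per-liver partial residuals against the term's value; the line
    has slope b_term — the term's coefficient with the other predictors held
    fixed. Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    x = fit.model_table[term].to_numpy(dtype=float)
    pr = partial_residuals(fit, term)
    b = fit.coefficient(term)
    ax.scatter(x, pr, s=18, color="0.2")
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, b * (grid - x.mean()) + pr.mean(), color="crimson")
    ax.set_xlabel(term)
    ax.set_ylabel(f"partial residual ({fit.outcome})")
    return ax
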