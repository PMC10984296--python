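"""Observed-vs-predicted concentration plots for fitted subjects."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .data import SubjectRecord
from .model import StructuralParameters, concentration_profile

__all__ = ["plot_observed_vs_predicted"]


def plot_observed_vs_predicted(
        subjects: Sequence[SubjectRecord],
        fitted: dict[str, StructuralParameters],
        path: str | Path) -> None:
    """One panel per subject: observed samples and the fitted profile.

    ``fitted`` maps subject_id to the MAP structural parameters.  BLQ
    samples are drawn at their LLOQ as open markers.
    """
    n = len(subjects)
    if n == 0:
        raise ValueError("no subjects to plot")
    ncols = min(3, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows),
                             squeeze=False, sharey=True)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    for ax, subj in zip(axes.ravel(), subjects):
        params = fitted[subj.subject_id]
        t_end = max([e.start_time for e in subj.dosing]
                    + [o.time for o in subj.observations]) + 12.0
        grid = np.linspace(0.0, t_end, 300)
        ax.plot(grid, concentration_profile(params, subj.dosing, grid),
                lw=1.5, label="predicted")
        quant = [o for o in subj.observations if not o.blq_flag]
        if quant:
            ax.plot([o.time for o in quant], [o.value for o in quant],
                    "o", ms=5, label="observed")
        blq = [o for o in subj.observations if o.blq_flag]
        if blq:
            ax.plot([o.time for o in blq], [o.lloq for o in blq],
                    "v", mfc="none", ms=5, label="BLQ (at LLOQ)")
        ax.set_title(subj.subject_id)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("concentration (mg/L)")
    axes.ravel()[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
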