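"""Population-profile plots: mean line with 5th-95th percentile band per arm."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .population import PopulationSimResult

__all__ = ["plot_population_bands"]

_ARM_LABELS = {"control": "RIV alone", "test": "RIV + CBZ"}
_ARM_COLORS = {"control": "tab:blue", "test": "tab:red"}


def plot_population_bands(result: PopulationSimResult, path: str | Path) -> Path:
    """Two panels (first dosing interval, steady state), one band per arm."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, phase, title in zip(axes, ("first", "ss"),
                                ("First dosing interval", "Steady state")):
        for arm in ("control", "test"):
            profs = result.profiles.get((arm, phase), [])
            if not profs:
                continue
            times = profs[0].times
            mat = np.vstack([p.conc for p in profs])
            mean = mat.mean(axis=0)
            p5 = np.percentile(mat, 5, axis=0)
            p95 = np.percentile(mat, 95, axis=0)
            color = _ARM_COLORS[arm]
            ax.plot(times, mean, color=color, label=_ARM_LABELS[arm])
            ax.fill_between(times, p5, p95, color=color, alpha=0.2)
        ax.set_title(title)
        ax.set_xlabel("time (h)")
    axes[0].set_ylabel("rivaroxaban concentration (ng/mL)")
    axes[0].legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
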