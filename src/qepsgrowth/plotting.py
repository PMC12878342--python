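"""Figure generation for fitted individuals."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .core import (
    e_function,
    p_function,
    q_function,
    qs_function,
    total_height,
)
from .fitting import FitResult, GrowthRecord
from .reference import ReferenceModel

__all__ = ["plot_individual"]

PLOT_MODES = ("components", "sds", "puberty_aligned")


def plot_individual(
    fit: FitResult,
    record: GrowthRecord,
    mode: str = "components",
    ref: ReferenceModel | None = None,
    path=None,
):
    """Render one individual's fitted curve.

    Modes: ``components`` overlays T/QE/Q/E/P with the measurement points;
    ``sds`` plots the height-for-age z-score trajectory (requires ``ref``);
    ``puberty_aligned`` shifts the age axis so pubertal onset sits at zero.
    """
    if not fit.converged:
        raise ValueError(f"refusing to plot non-converged fit for {fit.record_id}")
    if mode not in PLOT_MODES:
        raise ValueError(f"unknown plot mode {mode!r}; use one of {PLOT_MODES}")

    params = fit.params
    fig, ax = plt.subplots(figsize=(7, 5))

    if mode == "components":
        ages = np.linspace(0.0, 20.0, 400)
        ax.plot(ages, total_height(ages, params), label="T", color="black")
        ax.plot(
            ages,
            e_function(ages, params) + q_function(ages, params),
            label="QE",
            ls="--",
        )
        ax.plot(ages, q_function(ages, params), label="Q", ls=":")
        ax.plot(ages, e_function(ages, params), label="E", ls="-.")
        ax.plot(ages, p_function(ages, params), label="P")
        ax.plot(record.ages, record.heights, "o", ms=4, color="tab:red", label="data")
        ax.set_ylabel("height (cm)")
    elif mode == "sds":
        if ref is None:
            raise ValueError("sds mode requires a reference model")
        ages = np.linspace(0.0, 20.0, 400)
        ax.plot(ages, ref.height_sds(ages, total_height(ages, params)), color="black")
        ax.plot(record.ages, ref.height_sds(record.ages, record.heights), "o", ms=4)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_ylabel("height SDS")
    else:  # puberty_aligned
        onset = fit.derived.age_p5_years
        ages = np.linspace(onset - 4.0, onset + 8.0, 400)
        ax.plot(ages - onset, total_height(ages, params), label="T", color="black")
        ax.plot(ages - onset, qs_function(ages, params) + e_function(ages, params),
                label="QES", ls="--")
        ax.plot(ages - onset, p_function(ages, params), label="P", ls=":")
        ax.plot(record.ages - onset, record.heights, "o", ms=4, color="tab:red")
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_ylabel("height (cm)")
        ax.set_xlabel("years since pubertal onset")

    if mode != "puberty_aligned":
        ax.set_xlabel("age (years)")
    if mode != "sds":
        ax.legend(loc="best", fontsize=8)
    ax.set_title(f"{fit.record_id} ({mode})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
        return path
    return fig
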