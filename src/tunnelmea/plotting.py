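"""Optional plot helpers; CSV tables are the contract, these are convenience."""

from __future__ import annotations

import pandas as pd


def plot_timecourse(timecourse: pd.DataFrame, metric: str, ax=None):
    """Mean +/- s.d. of one metric over DIV, one line per condition.

    ``timecourse`` is the output of :func:`tunnelmea.assemble_timecourse`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = timecourse[timecourse["metric"] == metric]
    for condition, grp in sub.groupby("condition"):
        grp = grp.sort_values("div")
        ax.errorbar(grp["div"], grp["mean"], yerr=grp["sd"], label=str(condition),
                    marker="o", capsize=3)
    ax.set_xlabel("DIV")
    ax.set_ylabel(metric)
    ax.legend()
    return ax


def plot_directionality_bars(direction: pd.DataFrame, kind: str = "spike", ax=None):
    """Stacked bars of A->B vs B->A percentages per well."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = direction[(direction["scope"] == "well") & (direction["kind"] == kind)]
    wells = sub["well"].tolist()
    ab = sub["pct_a_to_b"].to_numpy()
    ba = sub["pct_b_to_a"].to_numpy()
    ax.bar(wells, ab, label="A→B (MO origin)")
    ax.bar(wells, ba, bottom=ab, label="B→A (HBO origin)")
    ax.set_ylabel(f"% of directional {kind}s")
    ax.set_ylim(0, 100)
    ax.legend()
    return ax
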