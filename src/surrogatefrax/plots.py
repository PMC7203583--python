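"""Comparison scatter plots (surrogate vs. reference probabilities)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless rendering; reports are written to files
import matplotlib.pyplot as plt
import pandas as pd

from surrogatefrax.errors import EmptySelectionError


def comparison_scatter(
    reference: pd.DataFrame,
    surrogate: pd.DataFrame,
    age: int,
    reference_name: str = "reference model",
    surrogate_name: str = "surrogate model",
):
    """Scenario-grid scatter at one age: panels sex x outcome, identity line.

    Each point is one clinical scenario; points on the diagonal mean the
    surrogate reproduces the reference probability exactly.
    """
    sexes = [s for s in ("M", "F") if s in set(reference["sex"])]
    outcomes = ["mof", "hip"]
    if not sexes:
        raise EmptySelectionError("reference grid has no sexes to plot")
    fig, axes = plt.subplots(
        len(outcomes), len(sexes), figsize=(4.2 * len(sexes), 4.2 * len(outcomes)),
        squeeze=False,
    )
    sex_label = {"M": "Men", "F": "Women"}
    for i, outcome in enumerate(outcomes):
        for j, sex in enumerate(sexes):
            ax = axes[i][j]
            ref = reference[
                (reference["age"] == age)
                & (reference["sex"] == sex)
                & (reference["outcome"] == outcome)
            ].set_index("profile_id")["probability"]
            sur = surrogate[
                (surrogate["age"] == age)
                & (surrogate["sex"] == sex)
                & (surrogate["outcome"] == outcome)
            ].set_index("profile_id")["probability"]
            common = ref.index.intersection(sur.index)
            if len(common) == 0:
                raise EmptySelectionError(
                    f"no paired scenarios for age={age}, sex={sex}, outcome={outcome}"
                )
            x = 100.0 * ref[common]
            y = 100.0 * sur[common]
            ax.scatter(x, y, s=8, alpha=0.5, edgecolors="none")
            top = max(x.max(), y.max()) * 1.05
            ax.plot([0, top], [0, top], "k-", lw=0.8)
            ax.set_xlim(0, top)
            ax.set_ylim(0, top)
            ax.set_xlabel(f"{reference_name} 10-y probability (%)")
            ax.set_ylabel(f"{surrogate_name} 10-y probability (%)")
            ax.set_title(f"{sex_label[sex]}, {outcome.upper()}, age {age}")
    fig.tight_layout()
    return fig
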