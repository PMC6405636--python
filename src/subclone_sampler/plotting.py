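"""Optional rendering of design curves (cosmetic; requires matplotlib)."""

from __future__ import annotations

from .design import DesignTable


def plot_design_table(table: DesignTable, path: str) -> None:
    """One line per confidence level: minimal sample size versus clonal
    frequency, both axes logarithmic."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for p, sub in table.frame.groupby("confidence"):
        ax.plot(sub["frequency"], sub["min_sample_size"], label=f"p = {p:g}")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("clonal frequency")
    ax.set_ylabel("minimum cells to sample")
    ax.set_title(
        f"N = {table.population_size:,} cells, capture ≥ {table.min_captured}"
    )
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
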