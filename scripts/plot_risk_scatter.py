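#!/usr/bin/env python
"""Convenience plot of an exported risk scatter (d_minus vs d_plus).

Usage:  python scripts/plot_risk_scatter.py out/scatter_test.csv risk.png

Green points are true AKI- patients, red true AKI+; the dashed y = x line
separates predicted-safe (above) from predicted-risky (below).  Not part
of the library contract — the core exports data only.
"""

import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def main(scatter_csv: str, out_png: str) -> None:
    df = pd.read_csv(scatter_csv)
    fig, ax = plt.subplots(figsize=(5, 5))
    for group, color in (("AKI-", "tab:green"), ("AKI+", "tab:red")):
        sub = df[df["truth"] == group]
        ax.scatter(sub["d_minus"], sub["d_plus"], s=12, c=color, label=group, alpha=0.7)
    lim = float(df[["d_minus", "d_plus"]].to_numpy().max()) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="y = x")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("distance to AKI- Planner output")
    ax.set_ylabel("distance to AKI+ Planner output")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    print(f"wrote {out_png}")


if __name__ == "__main__":
    if len(sys.argv) != 3:
        sys.exit(__doc__)
    main(sys.argv[1], sys.argv[2])
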