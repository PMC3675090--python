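"""Figure rendering for tool outputs.

Kept out of the computational core: plotting reads the CSVs the other
subcommands write, so the simulator itself has no display dependency.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_csv(csv_path: Union[str, Path], kind: str, out_path: Optional[Union[str, Path]] = None) -> Path:
    csv_path = Path(csv_path)
    out = Path(out_path) if out_path else csv_path.with_suffix(".png")
    df = pd.read_csv(csv_path)
    fig, ax = plt.subplots(figsize=(5.0, 3.4), constrained_layout=True)
    if kind == "trajectory":
        ax.plot(df["tau"], df["xi"], label=r"bond density $\xi$")
        ax.plot(df["tau"], df["zeta"], label=r"filament density $\zeta$")
        ax.set_xlabel(r"normalized time $\tau$")
        ax.set_ylabel("density")
        ax.legend(frameon=False)
    elif kind == "angle-sweep":
        ax.plot(df["theta_deg"], df["zeta_bar"], marker="o", ms=3)
        ax.set_xlabel(r"orientation $\theta$ (deg)")
        ax.set_ylabel(r"long-time filament density $\bar\zeta$")
    elif kind == "population":
        ax.plot(df["tau"], df["S"])
        ax.set_xlabel(r"normalized time $\tau$")
        ax.set_ylabel("order parameter S")
        ax.set_ylim(-1.05, 1.05)
    elif kind == "steady-state":
        ax.plot(df["beta"], df["xi_ss"], label=r"$\xi_{ss}$")
        ax.plot(df["beta"], df["zeta_ss"], label=r"$\zeta_{ss}$")
        ax.set_xlabel(r"substrate compliance $\beta$")
        ax.set_ylabel("steady-state density")
        ax.legend(frameon=False)
    else:
        raise ValueError(f"unknown plot kind {kind!r}")
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
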