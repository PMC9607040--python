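"""Rendering of sweep tables as figures (presentational only)."""
from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

log = logging.getLogger(__name__)

_LABELS = {
    "G": "G(y)",
    "mean_u": r"$\langle u \rangle$",
    "Q": r"$\langle Q \rangle$",
    "d_wall": r"$D_{wall}$",
}


def render_figures(table: pd.DataFrame, out_dir, *, stem: str = "sweep",
                   fmt: str = "png", dpi: int = 150) -> list[Path]:
    """One panel per variant, one curve per swept value.

    The table must be in the long format produced by ``run_sweep``:
    columns (swept parameter, abscissa, variant, observable).  Returns the
    written paths; an empty table produces no files and a warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if table.empty:
        log.warning("empty sweep table; nothing to render")
        return []
    cols = list(table.columns)
    sweep_col, x_col, obs_col = cols[0], cols[1], cols[3]
    written: list[Path] = []
    for variant, sub in table.groupby("variant"):
        fig, ax = plt.subplots(figsize=(5.0, 3.6))
        for value, curve in sub.groupby(sweep_col):
            ax.plot(curve[x_col], curve[obs_col],
                    label=f"{sweep_col}={value:g}")
        ax.set_xlabel(x_col)
        ax.set_ylabel(_LABELS.get(obs_col, obs_col))
        ax.set_title(f"{obs_col} ({variant})")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out_dir / f"{stem}_{variant.lower()}.{fmt}"
        fig.savefig(path, dpi=dpi)
        plt.close(fig)
        written.append(path)
    return written
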