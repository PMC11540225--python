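"""Reading and writing TFR grids and metrics tables.

Text formats only: a TFR is stored as a tab-delimited matrix with the
axes and kind in ``#``-prefixed header lines, so a grid round-trips
through a single human-inspectable file.  A compact ``.npz`` container is
also provided for large grids.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import TFRGrid

__all__ = ["write_tfr", "read_tfr", "write_tfr_npz", "read_tfr_npz",
           "write_metrics_table", "plot_tfr"]


def write_tfr(path, tfr: TFRGrid) -> None:
    """Write a TFR as delimited text with axis header lines."""
    if tfr.kind == "complex_coeff":
        raise ValueError("text format stores real grids; write the modulus")
    header = "\n".join(
        [
            f"kind={tfr.kind}",
            "freqs_hz=" + " ".join(f"{f:.10g}" for f in tfr.freqs),
            "times_s=" + " ".join(f"{t:.10g}" for t in tfr.times),
        ]
    )
    np.savetxt(path, tfr.values, delimiter="\t", header=header)


def read_tfr(path) -> TFRGrid:
    kind = None
    freqs = times = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if body.startswith("kind="):
                kind = body[5:]
            elif body.startswith("freqs_hz="):
                freqs = np.fromstring(body[9:], sep=" ")
            elif body.startswith("times_s="):
                times = np.fromstring(body[8:], sep=" ")
    if kind is None or freqs is None or times is None:
        raise ValueError(f"{path} is missing TFR header lines")
    values = np.loadtxt(path, ndmin=2)
    return TFRGrid(values, freqs, times, kind)


def write_tfr_npz(path, tfr: TFRGrid) -> None:
    np.savez_compressed(
        path, values=tfr.values, freqs=tfr.freqs, times=tfr.times,
        kind=np.asarray(tfr.kind),
    )


def read_tfr_npz(path) -> TFRGrid:
    with np.load(path) as data:
        return TFRGrid(
            data["values"], data["freqs"], data["times"], str(data["kind"])
        )


def write_metrics_table(path, table: pd.DataFrame) -> None:
    """Write a tidy metrics table (one row per TFR) as TSV, with the
    normalization conventions recorded in header comments."""
    with open(path, "w") as fh:
        for key, value in sorted(table.attrs.items()):
            fh.write(f"# {key}={value}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def plot_tfr(tfr: TFRGrid, path=None, title: str = "", db_floor: float = 60.0):
    """PNG heatmap with time in ms on x and frequency in Hz on y.

    Requires matplotlib.  Returns the figure; saves to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mag = np.abs(tfr.values)
    top = mag.max()
    with np.errstate(divide="ignore"):
        z = 10 * np.log10(np.maximum(mag, top * 10 ** (-db_floor / 10)) / top)
    fig, ax = plt.subplots(figsize=(6, 4))
    mesh = ax.pcolormesh(tfr.times * 1e3, tfr.freqs, z, shading="auto")
    fig.colorbar(mesh, ax=ax, label="dB re max")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("frequency (Hz)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
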