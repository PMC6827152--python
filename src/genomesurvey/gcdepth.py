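"""GC content versus sequencing depth along the assembly.

Windows tile each assembly sequence without overlap; per window we report
the GC percent over unambiguous bases and the mean depth of the window's
N-free canonical k-mers, looked up in the k-mer table built from the same
read set. Using k-mer depth instead of read alignment is a deliberate
proxy: the profile is a QC visualisation (contamination shows up as extra
GC-depth clusters), and k-mer depth tracks read depth closely while
keeping the package free of an aligner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._encode import encode
from .kmer import KmerTable, _canonical_codes

__all__ = ["GcDepthRecord", "GcDepthSummary", "window_gc_depth", "summarize_gc", "plot_gc_depth"]

DEFAULT_WINDOW = 500


@dataclass
class GcDepthRecord:
    sequence_id: str
    window_start: int  # 0-based
    window_length: int
    gc_percent: float
    mean_depth: float


@dataclass
class GcDepthSummary:
    """Weighted mean GC, central GC range and depth quantiles of all windows."""

    mean_gc: float  # percent, weighted by window base count
    gc_low: float  # 0.5th percentile of per-window GC
    gc_high: float  # 99.5th percentile
    depth_quartiles: tuple[float, float, float]  # 25/50/75th of mean_depth
    n_windows: int


def window_gc_depth(
    assembly: Sequence[tuple[str, str]],
    kmer_depths: KmerTable,
    window: int = DEFAULT_WINDOW,
) -> list[GcDepthRecord]:
    """Tile each sequence into windows and profile GC and k-mer depth.

    Trailing partial windows shorter than window/2 merge into the previous
    window, so windows tile each sequence exactly. Sequences shorter than
    k are skipped with a warning.
    """
    k = kmer_depths.k
    if window < k:
        raise ValueError("window must be >= k")
    records: list[GcDepthRecord] = []
    for seq_id, seq in assembly:
        L = len(seq)
        if L < k:
            warnings.warn(f"sequence {seq_id} shorter than k={k}; skipped", stacklevel=2)
            continue
        starts = list(range(0, L, window))
        # merge a short trailing remainder into the previous window
        if len(starts) > 1 and L - starts[-1] < window / 2:
            starts.pop()
        codes_full = encode(seq)
        for wi, ws in enumerate(starts):
            we = starts[wi + 1] if wi + 1 < len(starts) else L
            wcodes = codes_full[ws:we]
            acgt = wcodes < 4
            n_acgt = int(acgt.sum())
            gc = int(((wcodes == 1) | (wcodes == 2)).sum())
            gc_percent = 100.0 * gc / n_acgt if n_acgt else 0.0
            kmers = _canonical_codes(wcodes, k) if we - ws >= k else np.empty(0, np.int64)
            if kmers.size:
                mean_depth = float(kmer_depths.depth_of(kmers).mean())
            else:
                mean_depth = 0.0
            records.append(
                GcDepthRecord(
                    sequence_id=seq_id,
                    window_start=ws,
                    window_length=we - ws,
                    gc_percent=gc_percent,
                    mean_depth=mean_depth,
                )
            )
    return records


def summarize_gc(records: Sequence[GcDepthRecord]) -> GcDepthSummary:
    """Summary over windows; mean GC is weighted by window base count."""
    if not records:
        raise ValueError("no windows to summarise")
    gcs = np.array([r.gc_percent for r in records])
    lens = np.array([r.window_length for r in records], dtype=np.float64)
    depths = np.array([r.mean_depth for r in records])
    mean_gc = float(np.average(gcs, weights=lens))
    lo, hi = (float(x) for x in np.percentile(gcs, [0.5, 99.5]))
    q = tuple(float(x) for x in np.percentile(depths, [25, 50, 75]))
    return GcDepthSummary(mean_gc, lo, hi, q, len(records))


def write_records_tsv(records: Sequence[GcDepthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tlength\tgc_percent\tmean_depth\n")
        for r in records:
            fh.write(
                f"{r.sequence_id}\t{r.window_start}\t{r.window_length}"
                f"\t{r.gc_percent:.4f}\t{r.mean_depth:.4f}\n"
            )


def plot_gc_depth(records: Sequence[GcDepthRecord], path: str | Path) -> None:
    """Scatter of depth vs GC with marginal histograms, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gcs = [r.gc_percent for r in records]
    depths = [r.mean_depth for r in records]
    fig = plt.figure(figsize=(7, 7))
    grid = fig.add_gridspec(2, 2, width_ratios=(4, 1), height_ratios=(1, 4), hspace=0.05, wspace=0.05)
    ax = fig.add_subplot(grid[1, 0])
    ax_top = fig.add_subplot(grid[0, 0], sharex=ax)
    ax_right = fig.add_subplot(grid[1, 1], sharey=ax)
    ax.scatter(gcs, depths, s=3, alpha=0.3, color="tab:blue", rasterized=True)
    ax.set_xlabel("GC content (%)")
    ax.set_ylabel("mean k-mer depth")
    ax_top.hist(gcs, bins=50, color="tab:blue")
    ax_right.hist(depths, bins=50, orientation="horizontal", color="tab:blue")
    ax_top.tick_params(labelbottom=False)
    ax_right.tick_params(labelleft=False)
    fig.savefig(path, dpi=150)
    plt.close(fig)
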