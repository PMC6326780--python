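"""Reference-point coverage metaprofiles from bedGraph tracks.

Coverage is averaged in fixed-width bins (default 10 bp) around the
midpoints of a set of reference intervals (ITR centres, TSS, ...), after
1x-genome (RPGC) or RPKM normalization; an input profile may be
subtracted cell-wise from the IP profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_intervals import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    """Rows = reference points, columns = bins, values = mean coverage/bp."""

    matrix: np.ndarray
    halfwidth: int
    bin_size: int
    normalization: str = "none"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        expect = 2 * self.halfwidth // self.bin_size
        if self.matrix.ndim != 2 or self.matrix.shape[1] != expect:
            raise ValueError(
                f"matrix must have {expect} columns for halfwidth "
                f"{self.halfwidth} and bin {self.bin_size}")

    @property
    def n_points(self) -> int:
        return self.matrix.shape[0]

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin-centre offsets relative to the reference point, in bp."""
        n = self.matrix.shape[1]
        return (np.arange(n) - n // 2) * self.bin_size + self.bin_size / 2

    def mean_profile(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    def median_profile(self) -> np.ndarray:
        return np.median(self.matrix, axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix,
                            columns=[f"{int(c)}" for c in self.bin_centers])


def _tracks_to_arrays(track: pd.DataFrame,
                      chrom_sizes: Optional[dict[str, int]] = None,
                      ) -> dict[str, np.ndarray]:
    """Expand a bedGraph into dense per-chromosome coverage arrays."""
    arrays = {}
    for chrom, sub in track.groupby("chrom", sort=True):
        size = (chrom_sizes or {}).get(chrom, int(sub["end"].max()))
        arr = np.zeros(size)
        for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
            arr[start:min(end, size)] = value
        arrays[chrom] = arr
    return arrays


def normalize_track(track: pd.DataFrame, mode: str,
                    genome_size: Optional[int] = None,
                    read_length: Optional[int] = None,
                    total_reads: Optional[int] = None,
                    bin_size: int = 10) -> pd.DataFrame:
    """Scale a bedGraph to 1x genome coverage (RPGC) or RPKM.

    RPGC multiplies values by genome_size / (total_reads x read_length),
    so the genome-wide mean depth becomes one. RPKM scales per-bin values
    by 1e9 / (total_reads x bin_size).
    """
    out = track.copy()
    if mode == "none":
        return out
    if total_reads is None or total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if mode == "rpgc_1x":
        if genome_size is None or read_length is None:
            raise ValueError("rpgc_1x needs genome_size and read_length")
        scale = genome_size / (total_reads * read_length)
    elif mode == "rpkm":
        scale = 1e9 / (total_reads * bin_size)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    out["value"] = out["value"] * scale
    return out


def profile_matrix(track: pd.DataFrame, points: Sequence[GenomicInterval],
                   halfwidth: int = 2000, bin_size: int = 10,
                   normalization: str = "none",
                   chrom_sizes: Optional[dict[str, int]] = None,
                   ) -> ProfileMatrix:
    """Binned coverage matrix around the midpoints of reference intervals.

    Each row holds the mean per-base coverage in consecutive bins of
    ``bin_size`` bp spanning ``[mid - halfwidth, mid + halfwidth)``, the
    midpoint being ``floor((start + end) / 2)``. Rows for minus-strand
    points are reversed so bins always read 5'->3'. Points whose window
    leaves the covered sequence are dropped (count logged and recorded).
    """
    if (2 * halfwidth) % bin_size != 0:
        raise ValueError("bin_size must divide 2*halfwidth")
    arrays = _tracks_to_arrays(track, chrom_sizes)
    n_bins = 2 * halfwidth // bin_size
    rows = []
    dropped = 0
    for p in points:
        arr = arrays.get(p.chrom)
        mid = p.midpoint
        lo, hi = mid - halfwidth, mid + halfwidth
        if arr is None or lo < 0 or hi > len(arr):
            dropped += 1
            continue
        window = arr[lo:hi].reshape(n_bins, bin_size).mean(axis=1)
        if p.strand == "-":
            window = window[::-1]
        rows.append(window)
    if not rows:
        raise ValueError("no usable reference points")
    if dropped:
        logger.info("dropped %d edge-clipped reference points", dropped)
    return ProfileMatrix(matrix=np.vstack(rows), halfwidth=halfwidth,
                         bin_size=bin_size, normalization=normalization,
                         n_dropped=dropped)


def subtract_input(ip: ProfileMatrix, control: ProfileMatrix) -> ProfileMatrix:
    """Cell-wise IP minus input; geometry and normalization must match."""
    if (ip.matrix.shape != control.matrix.shape
            or ip.halfwidth != control.halfwidth
            or ip.bin_size != control.bin_size):
        raise ValueError("profile geometry mismatch")
    if ip.normalization != control.normalization:
        raise ValueError("normalization mismatch")
    return ProfileMatrix(matrix=ip.matrix - control.matrix,
                         halfwidth=ip.halfwidth, bin_size=ip.bin_size,
                         normalization=ip.normalization,
                         n_dropped=max(ip.n_dropped, control.n_dropped))


def plot_profile(profile: ProfileMatrix, path: str, title: str = "") -> None:
    """Write a simple mean-profile line plot."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.bin_centers, profile.mean_profile())
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("distance from reference point (bp)")
    ax.set_ylabel(f"coverage ({profile.normalization})")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
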