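"""Windowed binding signal, sliding-window GC content, and their covariation.

The binding signal per fixed-width bin is

    S(w) = (IP_w / Input_w) * (TotalInput / TotalIP)

where the totals are the *library* totals carried as track metadata, not
per-replicon sums. Bins with zero input coverage are marked undefined and
propagate as missing — never as 0 or infinity. An algebraic consequence of
the normalization is that the Input-weighted mean of S over defined bins is
exactly 1 when the totals equal the summed counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .genome import FormatError, GenomeAssembly


@dataclass
class BinnedTrack:
    """Fixed-width per-bin read counts for one sample across replicons.

    ``counts`` maps replicon name to a float array of length
    ceil(replicon_length / bin_width). ``total_count`` is the sample's
    genome-wide mapped-read total (library total).
    """

    counts: dict[str, np.ndarray]
    bin_width: int = 100
    total_count: float | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.counts = {rep: np.asarray(c, dtype=float) for rep, c in self.counts.items()}
        if self.total_count is None:
            self.total_count = float(sum(c.sum() for c in self.counts.values()))
        if any((c < 0).any() for c in self.counts.values()):
            raise ValueError("negative bin counts")

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_width == other.bin_width
            and set(self.counts) == set(other.counts)
            and all(len(self.counts[r]) == len(other.counts[r]) for r in self.counts)
        )


@dataclass
class WindowSignal:
    """Per-window values on a genomic grid.

    Backed by a DataFrame with columns ``replicon, start, end, value,
    defined``. ``start`` is the window anchor (0-based); windows from
    different operations pair by shared ``(replicon, start)`` anchor.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"replicon", "start", "end", "value", "defined"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"WindowSignal table missing columns: {sorted(missing)}")

    @property
    def defined(self) -> pd.DataFrame:
        return self.table[self.table["defined"]]

    def values_by_anchor(self) -> pd.Series:
        df = self.defined
        return pd.Series(
            df["value"].to_numpy(), index=pd.MultiIndex.from_frame(df[["replicon", "start"]])
        )


def binding_signal(ip: BinnedTrack, input_track: BinnedTrack) -> WindowSignal:
    """Library-size-normalized IP/input ratio per bin.

    Bins where the input has zero reads are flagged undefined rather than
    raising: they are data absence, not signal.
    """
    if not ip.same_grid(input_track):
        raise ValueError("IP and input tracks are on different bin grids")
    if ip.total_count <= 0 or input_track.total_count <= 0:
        raise ValueError("track totals must be positive")
    scale = input_track.total_count / ip.total_count
    rows = []
    for rep in sorted(ip.counts):
        ipc, inc = ip.counts[rep], input_track.counts[rep]
        starts = np.arange(len(ipc)) * ip.bin_width
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (ipc / inc) * scale
        ok = inc > 0
        s = np.where(ok, s, np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "replicon": rep,
                    "start": starts,
                    "end": starts + ip.bin_width,
                    "value": s,
                    "defined": ok,
                }
            )
        )
    return WindowSignal(pd.concat(rows, ignore_index=True))


_VALID = set("ACGTN")


def gc_windows(
    assembly: GenomeAssembly, window: int = 500, step: int = 100
) -> WindowSignal:
    """GC percentage in sliding windows anchored every ``step`` bp.

    Circular replicons wrap across the origin; linear replicons truncate the
    final windows. N bases are excluded from numerator and denominator; a
    window of all N is undefined. Characters outside {A, C, G, T, N} raise.
    """
    if window < step:
        raise ValueError("window must be >= step")
    rows = []
    for rep in assembly.replicons:
        seq = rep.sequence.upper()
        bad = set(seq) - _VALID
        if bad:
            raise FormatError(f"replicon {rep.name}: non-IUPAC characters {sorted(bad)}")
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_n = arr == ord("N")
        # prefix sums for O(1) window queries
        cg = np.concatenate([[0], np.cumsum(is_gc)])
        cn = np.concatenate([[0], np.cumsum(is_n)])
        L = rep.length

        def span_counts(a: int, b: int) -> tuple[int, int]:
            return int(cg[b] - cg[a]), int(cn[b] - cn[a])

        for start in range(0, L, step):
            end = start + window
            if end <= L:
                gc, nn = span_counts(start, end)
                width = window
            elif rep.circular:
                gc1, nn1 = span_counts(start, L)
                gc2, nn2 = span_counts(0, end - L)
                gc, nn = gc1 + gc2, nn1 + nn2
                width = window
            else:
                gc, nn = span_counts(start, L)
                width = L - start
            denom = width - nn
            ok = denom > 0
            rows.append(
                (rep.name, start, start + width, 100.0 * gc / denom if ok else np.nan, ok)
            )
    return WindowSignal(
        pd.DataFrame(rows, columns=["replicon", "start", "end", "value", "defined"])
    )


def signal_gc_correlation(
    signal: WindowSignal, gc: WindowSignal, method: str = "pearson"
) -> float:
    """Correlation between binding signal and GC content paired by anchor start.

    Undefined windows on either side are dropped pairwise.
    """
    a = signal.values_by_anchor()
    b = gc.values_by_anchor()
    joined = pd.concat([a.rename("signal"), b.rename("gc")], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("fewer than 3 paired defined windows")
    if method == "pearson":
        r = _sps.pearsonr(joined["signal"], joined["gc"]).statistic
    elif method == "spearman":
        r = _sps.spearmanr(joined["signal"], joined["gc"]).statistic
    else:
        raise ValueError(f"unknown method: {method}")
    return float(r)


# ---------------------------------------------------------------------------
# bedGraph I/O (fixed-step bins)
# ---------------------------------------------------------------------------

def write_bedgraph(track: BinnedTrack, path: str | Path,
                   lengths: Mapping[str, int] | None = None) -> None:
    """Write a binned track as bedGraph; one line per bin, last bin clipped
    to the replicon length when ``lengths`` is given."""
    with open(path, "w") as fh:
        fh.write(f"# total_count={track.total_count:.10g} bin_width={track.bin_width}\n")
        for rep in sorted(track.counts):
            c = track.counts[rep]
            L = lengths.get(rep) if lengths else None
            for i, v in enumerate(c):
                s = i * track.bin_width
                e = s + track.bin_width
                if L is not None:
                    e = min(e, L)
                fh.write(f"{rep}\t{s}\t{e}\t{v:.10g}\n")


def read_bedgraph(path: str | Path) -> BinnedTrack:
    path = Path(path)
    total = None
    bin_width = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            k, _, v = tok.partition("=")
            if k == "total_count":
                total = float(v)
            elif k == "bin_width":
                bin_width = int(v)
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "value"])
    if df.empty:
        raise FormatError(f"{path}: no data lines")
    if bin_width is None:
        bin_width = int((df["end"] - df["start"]).max())
    counts = {}
    for rep, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        idx = (sub["start"] // bin_width).to_numpy()
        arr = np.zeros(idx.max() + 1, dtype=float)
        arr[idx] = sub["value"].to_numpy()
        counts[str(rep)] = arr
    return BinnedTrack(counts=counts, bin_width=bin_width, total_count=total)
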