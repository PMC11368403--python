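"""Genomic coordinate frame, annotations, interval algebra and flat-file I/O.

All internal coordinates are 0-based half-open. GFF3 (1-based inclusive) is
converted at the parsing boundary. Intervals are strandless; strand is carried
on genes but ignored by every overlap computation, because ChIP footprints
have no strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """Malformed input file or coordinate outside the assembly."""


@dataclass(frozen=True)
class Replicon:
    name: str
    sequence: str
    circular: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeAssembly:
    """Named replicons defining the coordinate frame for every track/interval."""

    replicons: list[Replicon]

    def __post_init__(self) -> None:
        names = [r.name for r in self.replicons]
        if len(set(names)) != len(names):
            raise FormatError(f"duplicate replicon names: {names}")

    def __getitem__(self, name: str) -> Replicon:
        for r in self.replicons:
            if r.name == name:
                return r
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(r.name == name for r in self.replicons)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.replicons]

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.replicons)


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    replicon: str
    start: int  # 0-based half-open
    end: int
    strand: str = "+"
    is_insertion_sequence: bool = False
    tu_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Strandless genomic intervals with merge/intersect/coverage semantics.

    Intervals are stored per replicon as an (n, 2) int array. ``normalize``
    sorts and merges overlapping *and bookended* intervals (a zero-gap pair of
    fragments is one genomic footprint) and is idempotent.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        self._by_rep: dict[str, np.ndarray] = {}
        rows: dict[str, list[tuple[int, int]]] = {}
        for rep, start, end in intervals:
            if start < 0 or end < start:
                raise FormatError(f"invalid interval [{start}, {end}) on {rep}")
            if end > start:
                rows.setdefault(rep, []).append((int(start), int(end)))
        for rep, ivs in rows.items():
            self._by_rep[rep] = np.array(ivs, dtype=np.int64).reshape(-1, 2)

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for rep in sorted(self._by_rep):
            for s, e in self._by_rep[rep]:
                yield rep, int(s), int(e)

    def __len__(self) -> int:
        return sum(arr.shape[0] for arr in self._by_rep.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self) == list(other)

    def __repr__(self) -> str:
        return f"IntervalSet({list(self)!r})"

    @property
    def replicons(self) -> list[str]:
        return sorted(self._by_rep)

    def arrays(self, replicon: str) -> np.ndarray:
        return self._by_rep.get(replicon, np.empty((0, 2), dtype=np.int64))

    # -- algebra ------------------------------------------------------------
    def normalize(self) -> "IntervalSet":
        out = IntervalSet()
        for rep, arr in self._by_rep.items():
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            arr = arr[order]
            merged: list[list[int]] = []
            for s, e in arr:
                if merged and s <= merged[-1][1]:  # overlap or bookended
                    merged[-1][1] = max(merged[-1][1], int(e))
                else:
                    merged.append([int(s), int(e)])
            if merged:
                out._by_rep[rep] = np.array(merged, dtype=np.int64)
        return out

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Base-pair intersection; both operands are normalized first."""
        a, b = self.normalize(), other.normalize()
        result: list[tuple[str, int, int]] = []
        for rep in a.replicons:
            xs, ys = a.arrays(rep), b.arrays(rep)
            i = j = 0
            while i < len(xs) and j < len(ys):
                s = max(xs[i, 0], ys[j, 0])
                e = min(xs[i, 1], ys[j, 1])
                if s < e:
                    result.append((rep, int(s), int(e)))
                if xs[i, 1] < ys[j, 1]:
                    i += 1
                else:
                    j += 1
        return IntervalSet(result)

    def overlaps(self, replicon: str, start: int, end: int) -> bool:
        arr = self.arrays(replicon)
        return bool(np.any((arr[:, 0] < end) & (arr[:, 1] > start)))

    def covered_bp(self, replicon: str, start: int, end: int) -> int:
        """Base pairs of [start, end) covered by the union of intervals."""
        arr = self.normalize().arrays(replicon)
        lo = np.maximum(arr[:, 0], start)
        hi = np.minimum(arr[:, 1], end)
        return int(np.clip(hi - lo, 0, None).sum())

    def total_length(self) -> int:
        return sum(
            int((arr[:, 1] - arr[:, 0]).sum())
            for arr in self.normalize()._by_rep.values()
        )


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """Base-pair Jaccard index |a & b| / |a | b| over all replicons."""
    an, bn = a.normalize(), b.normalize()
    inter = an.intersect(bn).total_length()
    union = an.total_length() + bn.total_length() - inter
    return inter / union if union else 1.0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a FASTA file into a :class:`GenomeAssembly` (sequences upper-cased)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no records")
    replicons = []
    for rec in records:
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: empty record '{rec.id}'")
        replicons.append(Replicon(name=rec.id, sequence=str(rec.seq).upper()))
    return GenomeAssembly(replicons)


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rep in assembly.replicons:
            fh.write(f">{rep.name}\n")
            for i in range(0, rep.length, width):
                fh.write(rep.sequence[i : i + width] + "\n")


_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _gff_attr(attributes: str, key: str) -> str | None:
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def read_annotations(
    path: str | Path,
    fmt: str = "gff3",
    assembly: GenomeAssembly | None = None,
) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 or BED6 into 0-based half-open records.

    GFF3 attributes used: ``ID`` (gene id), ``tu_id`` (optional transcriptional
    unit), ``is_element=true`` (insertion-sequence flag). BED6 uses the name
    column as gene id.
    """
    path = Path(path)
    genes: list[GeneAnnotation] = []
    if fmt == "gff3":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=_GFF_COLS,
            dtype={"start": int, "end": int},
        )
        for row in df.itertuples(index=False):
            start, end = row.start - 1, row.end  # 1-based inclusive -> half-open
            if start >= end:
                raise FormatError(f"{path}: start > end for line with seqid {row.seqid}")
            gid = _gff_attr(row.attributes, "ID") or f"{row.seqid}:{start}-{end}"
            tu = _gff_attr(row.attributes, "tu_id")
            is_el = (_gff_attr(row.attributes, "is_element") or "").lower() == "true"
            genes.append(
                GeneAnnotation(gid, str(row.seqid), start, end,
                               strand=str(row.strand), is_insertion_sequence=is_el,
                               tu_id=tu if tu not in (None, "NA", "") else None)
            )
    elif fmt == "bed6":
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        for row in df.itertuples(index=False):
            if row.start >= row.end:
                raise FormatError(f"{path}: start >= end for {row.name}")
            genes.append(
                GeneAnnotation(str(row.name), str(row.chrom), int(row.start),
                               int(row.end), strand=str(row.strand))
            )
    else:
        raise ValueError(f"unknown annotation format: {fmt}")

    if assembly is not None:
        for g in genes:
            if g.replicon not in assembly:
                raise FormatError(f"gene {g.gene_id}: unknown replicon {g.replicon}")
            if g.end > assembly[g.replicon].length:
                raise FormatError(
                    f"gene {g.gene_id}: end {g.end} beyond replicon "
                    f"{g.replicon} length {assembly[g.replicon].length}"
                )
    return genes


def write_gff3(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.tu_id:
                attrs += f";tu_id={g.tu_id}"
            if g.is_insertion_sequence:
                attrs += ";is_element=true"
            fh.write(
                f"{g.replicon}\tnapscape\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_bed3(path: str | Path) -> IntervalSet:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    return IntervalSet(
        (str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples(index=False)
    )


def write_bed3(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rep, s, e in intervals:
            fh.write(f"{rep}\t{s}\t{e}\n")
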