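"""Gene/TU occupancy classification against binding regions and genome coverage.

A feature is classified by the fraction of its span covered by the union of
binding regions: ``entire`` iff every base is covered, ``not_bound`` iff no
base is covered, ``partial`` otherwise. "Overlapped" means >= 1 bp by
default; a minimum overlap fraction is exposed for sensitivity analysis.
TU spans run from the minimum start to the maximum end of member genes,
including intergenic gaps — a transcriptional unit is one transcript.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .genome import GeneAnnotation, GenomeAssembly, IntervalSet


@dataclass(frozen=True)
class OccupancyCall:
    feature_id: str
    klass: str  # {"not_bound", "partial", "entire"}
    overlap_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction outside [0, 1]")
        if (self.klass == "entire") != (self.overlap_fraction == 1.0):
            raise ValueError("entire <=> overlap_fraction == 1")
        if (self.klass == "not_bound") != (self.overlap_fraction == 0.0):
            raise ValueError("not_bound <=> overlap_fraction == 0")


def _call(feature_id: str, covered: int, length: int,
          min_overlap_fraction: float) -> OccupancyCall:
    frac = covered / length
    if covered == length:
        klass = "entire"
    elif covered == 0 or frac < min_overlap_fraction:
        # below the reporting threshold counts as unbound
        klass, frac = "not_bound", 0.0 if covered == 0 else frac
        if covered > 0:
            return OccupancyCall(feature_id, "not_bound", 0.0)
    else:
        klass = "partial"
    return OccupancyCall(feature_id, klass, frac)


def classify_occupancy(
    features: Sequence[GeneAnnotation],
    regions: IntervalSet,
    assembly: GenomeAssembly | None = None,
    min_overlap_fraction: float = 0.0,
) -> list[OccupancyCall]:
    """Classify each gene by overlap with the union of binding regions."""
    regions = regions.normalize()
    calls = []
    for g in features:
        if assembly is not None:
            if g.replicon not in assembly or g.end > assembly[g.replicon].length:
                raise ValueError(f"feature {g.gene_id} outside assembly")
        covered = regions.covered_bp(g.replicon, g.start, g.end)
        calls.append(_call(g.gene_id, covered, g.length, min_overlap_fraction))
    return calls


def classify_tu_occupancy(
    genes: Sequence[GeneAnnotation],
    regions: IntervalSet,
    assembly: GenomeAssembly | None = None,
    min_overlap_fraction: float = 0.0,
) -> list[OccupancyCall]:
    """Classify transcriptional units (spans of member genes) by overlap.

    Genes without a TU assignment are skipped. A TU id with no member genes
    cannot arise from this grouping; an explicitly empty group is an error.
    """
    by_tu: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        if g.tu_id is not None:
            by_tu.setdefault(g.tu_id, []).append(g)
    regions = regions.normalize()
    calls = []
    for tu_id in sorted(by_tu):
        members = by_tu[tu_id]
        if not members:
            raise ValueError(f"TU {tu_id}: no member genes")
        reps = {g.replicon for g in members}
        if len(reps) > 1:
            raise ValueError(f"TU {tu_id} spans multiple replicons: {sorted(reps)}")
        rep = reps.pop()
        start = min(g.start for g in members)
        end = max(g.end for g in members)
        if assembly is not None and end > assembly[rep].length:
            raise ValueError(f"TU {tu_id} outside assembly")
        covered = regions.covered_bp(rep, start, end)
        calls.append(_call(tu_id, covered, end - start, min_overlap_fraction))
    return calls


def genome_coverage_fraction(
    regions: IntervalSet,
    assembly: GenomeAssembly,
    replicon_scope: Iterable[str] | None = None,
) -> float:
    """Merged region length divided by total replicon length in scope.

    ``replicon_scope=None`` counts every replicon (chromosome and plasmids).
    """
    scope = list(replicon_scope) if replicon_scope is not None else assembly.names
    denom = sum(assembly[name].length for name in scope)
    if denom == 0:
        raise ValueError("replicon scope has zero total length")
    merged = regions.normalize()
    num = sum(
        int((merged.arrays(name)[:, 1] - merged.arrays(name)[:, 0]).sum())
        for name in scope
    )
    return num / denom


def occupancy_table(calls: Sequence[OccupancyCall]) -> pd.DataFrame:
    """Flat TSV-ready table: feature_id, class, overlap_fraction."""
    return pd.DataFrame(
        {
            "feature_id": [c.feature_id for c in calls],
            "class": [c.klass for c in calls],
            "overlap_fraction": [c.overlap_fraction for c in calls],
        }
    )
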