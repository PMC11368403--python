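"""Replicate-consensus peak calling rules.

Narrow summits: pooled summits from both replicates and the untagged control
are single-linkage clustered at a maximum merge distance (default 40 bp); a
cluster becomes a consensus summit only if it contains at least one summit
from each replicate and *no* control summit anywhere in the chain — the most
conservative reading of control exclusion. The consensus position is the
floored midpoint of the two contributing replicate summits (strongest-scored
summit per replicate when a cluster holds several).

Broad regions: base-pair intersection of the two replicate interval sets;
any resulting interval overlapping a control interval (>= 1 bp by default)
is removed whole, because exclusion names peaks, not base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field


from .genome import IntervalSet


@dataclass
class SummitSet:
    """Per-replicate candidate narrow-peak summits."""

    sample_id: str
    summits: list[tuple[str, int, float]] = field(default_factory=list)
    # each summit: (replicon, 0-based position, score)

    def positions(self, replicon: str) -> list[tuple[int, float]]:
        return [(p, s) for rep, p, s in self.summits if rep == replicon]

    @property
    def replicons(self) -> list[str]:
        return sorted({rep for rep, _, _ in self.summits})


@dataclass
class ConsensusSummits:
    """Consensus summits with provenance back to the replicate summits."""

    summits: list[tuple[str, int]] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)

    def positions(self, replicon: str) -> list[int]:
        return [p for rep, p in self.summits if rep == replicon]

    def __len__(self) -> int:
        return len(self.summits)


def merge_summits(
    rep1: SummitSet,
    rep2: SummitSet,
    control: SummitSet | None = None,
    distance: int = 40,
) -> ConsensusSummits:
    """Merge replicate summits within ``distance`` bp, excluding control clusters."""
    if distance < 0:
        raise ValueError("merge distance must be non-negative")
    control = control or SummitSet("control", [])
    out = ConsensusSummits()
    replicons = sorted(set(rep1.replicons) | set(rep2.replicons) | set(control.replicons))
    for rep in replicons:
        pooled: list[tuple[int, float, str]] = []
        for src, sset in (("rep1", rep1), ("rep2", rep2), ("control", control)):
            pooled.extend((pos, score, src) for pos, score in sset.positions(rep))
        pooled.sort(key=lambda t: (t[0], t[2]))
        # single-linkage: a gap > distance between consecutive pooled summits
        # breaks the chain
        cluster: list[tuple[int, float, str]] = []
        for item in pooled:
            if cluster and item[0] - cluster[-1][0] > distance:
                _emit(out, rep, cluster)
                cluster = []
            cluster.append(item)
        if cluster:
            _emit(out, rep, cluster)
    out.summits.sort()
    out.provenance.sort(key=lambda d: (d["replicon"], d["position"]))
    return out


def _emit(out: ConsensusSummits, replicon: str, cluster: list[tuple[int, float, str]]) -> None:
    srcs = {src for _, _, src in cluster}
    if "control" in srcs or not {"rep1", "rep2"} <= srcs:
        return
    best: dict[str, tuple[int, float]] = {}
    for pos, score, src in cluster:
        # strongest summit per replicate; ties break to the leftmost position
        if (src not in best or score > best[src][1]
                or (score == best[src][1] and pos < best[src][0])):
            best[src] = (pos, score)
    p1, p2 = best["rep1"][0], best["rep2"][0]
    midpoint = (p1 + p2) // 2  # floored for determinism on the integer grid
    out.summits.append((replicon, midpoint))
    out.provenance.append(
        {"replicon": replicon, "position": midpoint, "rep1": p1, "rep2": p2,
         "cluster_size": len(cluster)}
    )


def intersect_broad(
    rep1: IntervalSet,
    rep2: IntervalSet,
    control: IntervalSet | None = None,
    min_control_overlap: int = 1,
) -> IntervalSet:
    """Replicate intersection of broad peaks, dropping control-overlapped ones.

    An intersected interval is removed if it shares at least
    ``min_control_overlap`` bp with any control interval.
    """
    inter = rep1.intersect(rep2)
    if control is None or len(control) == 0:
        return inter.normalize()
    ctrl = control.normalize()
    kept = [
        (rep, s, e)
        for rep, s, e in inter
        if ctrl.covered_bp(rep, s, e) < min_control_overlap
    ]
    return IntervalSet(kept).normalize()
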