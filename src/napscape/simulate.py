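"""Synthetic study generator: genome, ChIP tracks, expression and 3C tables.

Generates every input the pipeline consumes with the statistical structure
the analysis assumes: a small multi-replicon genome carrying AT-rich tracts,
a broad binder whose footprint is exactly those low-GC tracts (~15% of the
genome by default), point-binding sigma-factor summits preferentially
excluded from the footprint, insertion-sequence genes enriched inside the
tracts, four planted temporal expression classes, and locus-vs-bait 3C
interaction profiles rendered as Ct values under a known amplification
efficiency.

Count noise is Poisson per bin — the minimal read-count model, which keeps
recovery analytic. FDR columns are planted rather than computed because
differential-expression fitting is out of scope here. Everything is
deterministic under a fixed seed.

Note on realized binding signal: the library-total normalization makes the
input-weighted mean signal exactly 1, so with enrichment E on a footprint
fraction f the realized in-footprint signal is E / (1 + (E-1)·f), not E.
The two agree only for small f.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import SummitSet
from .dynamics import ContrastTable
from .genome import (
    GeneAnnotation,
    GenomeAssembly,
    IntervalSet,
    Replicon,
    write_bed3,
    write_fasta,
    write_gff3,
)
from .occupancy import OccupancyCall
from .signal import BinnedTrack, write_bedgraph
from .threec import CtTable

DEFAULT_CLASS_FRACTIONS = {
    "transient": 0.02,
    "plateau": 0.10,
    "continuous": 0.033,
    "late": 0.02,
}
DEFAULT_SIGMA_FACTORS = {
    # factor -> (number of summits, probability of exclusion from the footprint)
    "SigE": (250, 0.90),
    "SigA": (250, 0.65),
}


@dataclass
class SimulationTruth:
    """Ground truth planted by the generator, for recovery tests."""

    nap_regions: IntervalSet
    sigma_summits: dict[str, list[tuple[str, int]]]
    sigma_exclusion: dict[str, float]
    gene_classes: dict[str, str]
    planted_if: dict[str, float] = field(default_factory=dict)
    seed: int = 0


@dataclass
class ChipSimulation:
    """Binned tracks plus per-replicate candidate summits/regions."""

    tracks: dict[str, BinnedTrack]
    candidate_regions: dict[str, IntervalSet]       # "rep1", "rep2"
    control_regions: IntervalSet
    candidate_summits: dict[str, dict[str, SummitSet]]  # factor -> replicate
    control_summits: SummitSet


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """Per-base sampling: Bernoulli(gc) for G/C, then a fair coin within the pair."""
    is_gc = rng.random(length) < gc
    coin = rng.random(length) < 0.5
    out = np.empty(length, dtype="<U1")
    out[is_gc & coin] = "G"
    out[is_gc & ~coin] = "C"
    out[~is_gc & coin] = "A"
    out[~is_gc & ~coin] = "T"
    return out


def _place_tracts(
    rng: np.random.Generator,
    lengths: Sequence[int],
    at_tracts: Sequence[tuple[int, float]],
    min_gap: int = 2000,
) -> list[tuple[int, int, int, float]]:
    """Assign tracts to replicons (probability ~ length) without overlap.

    Returns (replicon_index, start, end, gc) per tract.
    """
    total = sum(lengths)
    placed: list[tuple[int, int, int, float]] = []
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(lengths))}
    for tract_len, tract_gc in at_tracts:
        if tract_len > max(lengths):
            raise ValueError(f"tract length {tract_len} exceeds every replicon")
        for _ in range(10_000):
            ri = int(rng.choice(len(lengths), p=np.array(lengths) / total))
            if tract_len > lengths[ri]:
                continue
            start = int(rng.integers(0, lengths[ri] - tract_len + 1))
            end = start + tract_len
            if all(start - min_gap >= e or end + min_gap <= s
                   for s, e in occupied[ri]):
                occupied[ri].append((start, end))
                placed.append((ri, start, end, tract_gc))
                break
        else:
            raise ValueError("could not place AT tracts without overlap; "
                             "genome too small for the requested tract load")
    return placed


def simulate_genome(
    n_replicons: int = 2,
    lengths: Sequence[int] = (600_000, 60_000),
    background_gc: float = 0.52,
    at_tracts: Sequence[tuple[int, float]] | None = None,
    n_genes: int = 1000,
    is_fraction: float = 0.03,
    seed: int = 0,
    circular: bool = True,
    class_fractions: Mapping[str, float] = DEFAULT_CLASS_FRACTIONS,
    sigma_factors: Mapping[str, tuple[int, float]] = DEFAULT_SIGMA_FACTORS,
    transient_in_footprint_prob: float = 0.9,
) -> tuple[GenomeAssembly, list[GeneAnnotation], SimulationTruth]:
    """Generate a genome with AT tracts, tiled genes/TUs and planted truth.

    The broad-binder footprint is the set of AT tracts. By default 19 tracts
    cover 15% of a 660 kb two-replicon genome. Insertion-sequence genes land
    inside tracts preferentially; each transient-class gene is drawn from the
    footprint-overlapping gene pool with probability
    ``transient_in_footprint_prob`` and from the free pool otherwise, so the
    class is planted enriched over the geometric background (the footprint's
    share of genes).
    """
    if not 0 < background_gc < 1:
        raise ValueError("background_gc must be in (0, 1)")
    lengths = list(lengths)[:n_replicons]
    if len(lengths) != n_replicons:
        raise ValueError("need one length per replicon")
    if at_tracts is None:
        # ~15% of each replicon in 5 kb (chromosome) / 4.5 kb (plasmid) tracts
        at_tracts = [(5000, 0.30)] * round(0.15 * lengths[0] / 5000)
        if n_replicons > 1:
            at_tracts = list(at_tracts) + [
                (4500, 0.30)] * max(1, round(0.15 * sum(lengths[1:]) / 4500))
    for tract_len, tract_gc in at_tracts:
        if not 0 < tract_gc < 1:
            raise ValueError("tract gc must be in (0, 1)")

    rng = np.random.default_rng(seed)
    names = ["chr"] + [f"plasmid{i}" for i in range(1, n_replicons)]
    placements = _place_tracts(rng, lengths, at_tracts)

    replicons = []
    for i, (name, L) in enumerate(zip(names, lengths)):
        seq = _random_sequence(rng, L, background_gc)
        for ri, s, e, gc in placements:
            if ri == i:
                seq[s:e] = _random_sequence(rng, e - s, gc)
        replicons.append(Replicon(name=name, sequence="".join(seq), circular=circular))
    assembly = GenomeAssembly(replicons)

    nap = IntervalSet(
        (names[ri], s, e) for ri, s, e, _ in placements
    ).normalize()

    # --- genes tiled in operons of 1-7 genes -------------------------------
    genes: list[GeneAnnotation] = []
    gi = 0
    tu_i = 0
    for name, L in zip(names, lengths):
        pos = int(rng.integers(50, 200))
        while gi < n_genes:
            tu_i += 1
            tu_id = f"TU{tu_i:04d}"
            operon_size = int(rng.integers(1, 8))
            strand = "+" if rng.random() < 0.5 else "-"
            for _ in range(operon_size):
                if gi >= n_genes:
                    break
                glen = int(rng.integers(300, 601))
                if pos + glen > L - 50:
                    pos = None
                    break
                gi += 1
                genes.append(GeneAnnotation(
                    gene_id=f"g{gi:04d}", replicon=name, start=pos, end=pos + glen,
                    strand=strand, tu_id=tu_id,
                ))
                pos += glen + int(rng.integers(10, 51))
            if pos is None:
                break
            pos += int(rng.integers(50, 201))
    if gi < n_genes:
        raise ValueError(f"genome too small: placed {gi} of {n_genes} genes")

    in_nap = np.array([
        nap.covered_bp(g.replicon, g.start, g.end) > 0 for g in genes
    ])

    # IS genes preferentially inside AT tracts (weight 9:1)
    n_is = round(is_fraction * len(genes))
    if n_is > 0:
        w = np.where(in_nap, 9.0, 1.0)
        idx = rng.choice(len(genes), size=n_is, replace=False, p=w / w.sum())
        for i in idx:
            g = genes[i]
            genes[i] = GeneAnnotation(g.gene_id, g.replicon, g.start, g.end,
                                      g.strand, True, g.tu_id)

    # --- temporal classes ---------------------------------------------------
    gene_ids = [g.gene_id for g in genes]
    classes = {gid: "none" for gid in gene_ids}
    available = np.arange(len(genes))
    n_transient = round(class_fractions.get("transient", 0) * len(genes))
    if n_transient > 0:
        pool_in = available[in_nap[available]]
        pool_out = available[~in_nap[available]]
        chosen_list: list[int] = []
        for _ in range(n_transient):
            use_in = (rng.random() < transient_in_footprint_prob
                      and len(pool_in) > 0) or len(pool_out) == 0
            pool = pool_in if use_in else pool_out
            pick = int(rng.choice(pool))
            chosen_list.append(pick)
            pool_in = pool_in[pool_in != pick]
            pool_out = pool_out[pool_out != pick]
        chosen = np.array(chosen_list)
        for i in chosen:
            classes[gene_ids[i]] = "transient"
        available = np.setdiff1d(available, chosen)
    for klass in ("plateau", "continuous", "late"):
        n_k = round(class_fractions.get(klass, 0) * len(genes))
        if n_k > 0:
            chosen = rng.choice(available, size=n_k, replace=False)
            for i in chosen:
                classes[gene_ids[i]] = klass
            available = np.setdiff1d(available, chosen)

    # --- sigma summits by rejection sampling against the footprint ---------
    sigma_summits: dict[str, list[tuple[str, int]]] = {}
    sigma_exclusion: dict[str, float] = {}
    total = sum(lengths)
    probs = np.array(lengths) / total
    for factor, (n_summits, excl) in sigma_factors.items():
        positions: list[tuple[str, int]] = []
        while len(positions) < n_summits:
            ri = int(rng.choice(len(lengths), p=probs))
            pos = int(rng.integers(0, lengths[ri]))
            if nap.overlaps(names[ri], pos, pos + 1) and rng.random() < excl:
                continue  # rejected: excluded from the footprint
            positions.append((names[ri], pos))
        sigma_summits[factor] = sorted(positions)
        sigma_exclusion[factor] = excl

    truth = SimulationTruth(
        nap_regions=nap, sigma_summits=sigma_summits,
        sigma_exclusion=sigma_exclusion, gene_classes=classes, seed=seed,
    )
    return assembly, genes, truth


# ---------------------------------------------------------------------------
# ChIP tracks and candidate peaks
# ---------------------------------------------------------------------------

def simulate_chip_counts(
    assembly: GenomeAssembly,
    truth: SimulationTruth,
    enrichment: float = 8.0,
    depth: float = 50.0,
    n_replicates: int = 2,
    with_control: bool = True,
    seed: int = 0,
    bin_width: int = 100,
    boundary_noise: int = 30,
    summit_jitter: int = 10,
    artifact_region: tuple[str, int, int] | None = None,
) -> ChipSimulation:
    """Poisson read-count tracks plus per-replicate candidate peak lists.

    IP bins inside the planted footprint (broad binder) or containing a
    planted summit (sigma factors) draw at rate depth*enrichment; all other
    bins, the input and the untagged control draw at rate depth. Candidate
    broad regions are the planted regions with +/- ``boundary_noise`` bp of
    uniform boundary jitter per replicate; candidate summits are the planted
    positions +/- ``summit_jitter``. When ``artifact_region`` is given, the
    artifact appears in every replicate's candidates *and* in the control, so
    the consensus stage must remove it.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    rng = np.random.default_rng(seed)
    reps = {r.name: r.length for r in assembly.replicons}

    def footprint_mask(regions: IntervalSet) -> dict[str, np.ndarray]:
        masks = {}
        for name, L in reps.items():
            nbins = -(-L // bin_width)
            mids = np.arange(nbins) * bin_width + bin_width // 2
            m = np.zeros(nbins, dtype=bool)
            for s, e in regions.arrays(name):
                m |= (mids >= s) & (mids < e)
            masks[name] = m
        return masks

    def poisson_track(rates: dict[str, np.ndarray], sample_id: str) -> BinnedTrack:
        counts = {name: rng.poisson(r).astype(float) for name, r in rates.items()}
        return BinnedTrack(counts=counts, bin_width=bin_width, sample_id=sample_id)

    def flat_rates(level: float) -> dict[str, np.ndarray]:
        return {name: np.full(-(-L // bin_width), level) for name, L in reps.items()}

    nap_mask = footprint_mask(truth.nap_regions)
    artifact_ivs = IntervalSet([artifact_region]) if artifact_region else IntervalSet()
    art_mask = footprint_mask(artifact_ivs) if artifact_region else None

    tracks: dict[str, BinnedTrack] = {}
    candidate_regions: dict[str, IntervalSet] = {}
    candidate_summits: dict[str, dict[str, SummitSet]] = {
        f: {} for f in truth.sigma_summits
    }

    for k in range(1, n_replicates + 1):
        rates = flat_rates(depth)
        for name in reps:
            rates[name] = np.where(nap_mask[name], depth * enrichment, rates[name])
            if art_mask is not None:
                rates[name] = np.where(art_mask[name], depth * enrichment, rates[name])
        tracks[f"nap_ip_rep{k}"] = poisson_track(rates, f"nap_ip_rep{k}")

        noisy = []
        for name, s, e in truth.nap_regions:
            ds = int(rng.integers(-boundary_noise, boundary_noise + 1))
            de = int(rng.integers(-boundary_noise, boundary_noise + 1))
            s2, e2 = max(0, s + ds), min(reps[name], e + de)
            if s2 < e2:
                noisy.append((name, s2, e2))
        if artifact_region:
            noisy.append(artifact_region)
        candidate_regions[f"rep{k}"] = IntervalSet(noisy).normalize()

        for factor, summits in truth.sigma_summits.items():
            rates = flat_rates(depth)
            jittered = []
            for name, pos in summits:
                j = int(rng.integers(-summit_jitter, summit_jitter + 1))
                p2 = min(max(pos + j, 0), reps[name] - 1)
                jittered.append((name, p2, float(depth * enrichment)))
                rates[name][p2 // bin_width] = depth * enrichment
            tracks[f"{factor}_ip_rep{k}"] = poisson_track(rates, f"{factor}_ip_rep{k}")
            candidate_summits[factor][f"rep{k}"] = SummitSet(
                sample_id=f"{factor}_rep{k}", summits=sorted(jittered)
            )

    tracks["input"] = poisson_track(flat_rates(depth), "input")
    control_regions = IntervalSet()
    control_summits = SummitSet(sample_id="control", summits=[])
    if with_control:
        rates = flat_rates(depth)
        if art_mask is not None:
            for name in reps:
                rates[name] = np.where(art_mask[name], depth * enrichment, rates[name])
        tracks["control"] = poisson_track(rates, "control")
        if artifact_region:
            control_regions = artifact_ivs.normalize()
            name, s, e = artifact_region
            control_summits = SummitSet(
                sample_id="control", summits=[(name, (s + e) // 2, float(depth))]
            )

    return ChipSimulation(
        tracks=tracks, candidate_regions=candidate_regions,
        control_regions=control_regions, candidate_summits=candidate_summits,
        control_summits=control_summits,
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

_CLASS_MEANS = {
    # class -> planted log2FC multipliers of `effect` for (0->1h, 1->4h, 0->4h)
    "transient": (1.0, -1.0, 0.0),
    "continuous": (1.0, 1.0, 2.0),
    "plateau": (1.0, 0.0, 1.0),
    "late": (0.0, 2.0, 2.0),
    "none": (0.0, 0.0, 0.0),
}


def simulate_expression_table(
    gene_classes: Mapping[str, str],
    effect: float = 2.0,
    fdr_alpha: float = 0.05,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> ContrastTable:
    """Planted time-course contrasts (0->1 h, 1->4 h, 0->4 h) with Gaussian noise.

    FDR columns are planted: uniform on (0, fdr_alpha) where the class mean
    for that contrast is nonzero, uniform on (0, 1) otherwise.
    """
    rng = np.random.default_rng(seed)
    genes = list(gene_classes)
    contrasts = ["t0_vs_t1", "t1_vs_t4", "t0_vs_t4"]
    data = {}
    for ci, contrast in enumerate(contrasts):
        mu = np.array([_CLASS_MEANS[gene_classes[g]][ci] * effect for g in genes])
        lfc = mu + rng.normal(0.0, noise_sd, size=len(genes)) if noise_sd > 0 else mu
        fdr = np.where(
            mu != 0,
            rng.uniform(0.0, fdr_alpha, size=len(genes)),
            rng.uniform(0.0, 1.0, size=len(genes)),
        )
        data[(contrast, "log2fc")] = lfc
        data[(contrast, "fdr")] = fdr
    frame = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    return ContrastTable(frame)


def simulate_knockout_contrast(
    occupancy_calls: Sequence[OccupancyCall],
    shift: float = 1.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> pd.Series:
    """Mutant-vs-wildtype log2FC column: the binder represses covered genes,
    so its deletion raises entirely covered genes by ``shift`` (partially
    covered by half) over Gaussian noise."""
    rng = np.random.default_rng(seed)
    mu = {"entire": shift, "partial": shift / 2, "not_bound": 0.0}
    ids = [c.feature_id for c in occupancy_calls]
    vals = np.array([mu[c.klass] for c in occupancy_calls])
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=len(vals))
    return pd.Series(vals, index=pd.Index(ids, name="gene_id"), name="mutant_vs_wt")


# ---------------------------------------------------------------------------
# 3C
# ---------------------------------------------------------------------------

DEFAULT_PLANTED_IF = {
    "locus_a": 1.0, "locus_b": 0.60, "locus_c": 0.35, "locus_d": 0.20,
    "locus_e": 0.12, "locus_f": 0.08, "locus_g": 0.05,
}


def simulate_3c(
    planted_if: Mapping[str, float] = DEFAULT_PLANTED_IF,
    efficiency: float = 1.9,
    ct_noise_sd: float = 0.15,
    n_replicates: int = 3,
    dilution_steps: int = 5,
    dilution_factor: float = 10.0,
    seed: int = 0,
    samples: Sequence[str] = ("wt",),
    bait_locus_id: str = "bait",
    base_ct: float = 20.0,
) -> CtTable:
    """Render planted interaction frequencies as qPCR Ct observations.

    Calibration series per locus: Ct(c) = Ct0 - log(c)/log(efficiency) for
    relative concentrations ``dilution_factor**-i``. Sample Ct values encode
    planted_if x (per-replicate bait quantity), plus Gaussian measurement
    noise on each assayed locus; the bait fragment itself is recorded per
    (sample, replicate) as the internal control, and its variability is
    carried entirely by the per-replicate bait quantity (which normalization
    removes) rather than by additional measurement noise. With zero noise,
    curve inversion recovers planted_if exactly.
    """
    if efficiency <= 1:
        raise ValueError("efficiency must exceed 1")
    if any(v <= 0 for v in planted_if.values()):
        raise ValueError("planted interaction frequencies must be positive")
    rng = np.random.default_rng(seed)
    loci = list(planted_if) + [bait_locus_id]
    ct0 = {loc: base_ct + float(rng.uniform(-1.0, 1.0)) for loc in loci}
    log_eff = np.log10(efficiency)

    cal_rows = []
    for loc in loci:
        for i in range(dilution_steps):
            conc = dilution_factor ** (-i)
            cal_rows.append({
                "locus_id": loc, "relative_concentration": conc,
                "ct": ct0[loc] - np.log10(conc) / log_eff,
            })

    sample_rows = []
    for sample in samples:
        for rep in range(1, n_replicates + 1):
            bait_q = float(np.exp(rng.normal(0.0, 0.2)))
            for loc in loci:
                abundance = bait_q * (1.0 if loc == bait_locus_id else planted_if[loc])
                ct = ct0[loc] - np.log10(abundance) / log_eff
                if ct_noise_sd > 0 and loc != bait_locus_id:
                    ct += float(rng.normal(0.0, ct_noise_sd))
                sample_rows.append({"locus_id": loc, "sample_id": sample,
                                    "replicate": rep, "ct": ct})

    return CtTable(
        samples=pd.DataFrame(sample_rows),
        calibration=pd.DataFrame(cal_rows),
        bait_locus_id=bait_locus_id,
    )


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_simulation(
    outdir: str | Path,
    assembly: GenomeAssembly,
    genes: Sequence[GeneAnnotation],
    truth: SimulationTruth,
    chip: ChipSimulation,
    expression: ContrastTable,
    ct_table: CtTable,
) -> dict[str, Path]:
    """Emit the full synthetic study as FASTA/GFF3/bedGraph/BED/TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lengths = {r.name: r.length for r in assembly.replicons}
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fasta"
    write_fasta(assembly, paths["genome"])
    paths["annotations"] = outdir / "genes.gff3"
    write_gff3(genes, paths["annotations"])

    for sample_id, track in chip.tracks.items():
        p = outdir / f"{sample_id}.bedgraph"
        write_bedgraph(track, p, lengths)
        paths[sample_id] = p
    for rep, ivs in chip.candidate_regions.items():
        p = outdir / f"broad_{rep}.bed"
        write_bed3(ivs, p)
        paths[f"broad_{rep}"] = p
    write_bed3(chip.control_regions, outdir / "broad_control.bed")
    paths["broad_control"] = outdir / "broad_control.bed"
    for factor, by_rep in chip.candidate_summits.items():
        for rep, sset in by_rep.items():
            p = outdir / f"summits_{factor}_{rep}.bed"
            with open(p, "w") as fh:
                for name, pos, score in sset.summits:
                    fh.write(f"{name}\t{pos}\t{pos + 1}\t{factor}\t{score:.6g}\n")
            paths[f"summits_{factor}_{rep}"] = p

    paths["expression"] = outdir / "contrasts.tsv"
    expression.to_tsv(paths["expression"])
    paths["ct_samples"] = outdir / "ct_samples.tsv"
    paths["ct_calibration"] = outdir / "ct_calibration.tsv"
    ct_table.to_tsv(paths["ct_samples"], paths["ct_calibration"])

    truth_df = pd.DataFrame(
        {"gene_id": list(truth.gene_classes),
         "class": list(truth.gene_classes.values())}
    )
    paths["truth_classes"] = outdir / "truth_gene_classes.tsv"
    truth_df.to_csv(paths["truth_classes"], sep="\t", index=False)
    paths["truth_regions"] = outdir / "truth_nap_regions.bed"
    write_bed3(truth.nap_regions, paths["truth_regions"])
    return paths
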