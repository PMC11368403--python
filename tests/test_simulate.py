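import numpy as np
import pytest

from napscape import simulate as sim
from napscape.consensus import intersect_broad, merge_summits
from napscape.signal import binding_signal


class TestSimulateGenome:
    def test_tract_gc_realized(self):
        assembly, _, truth = sim.simulate_genome(
            n_replicons=1, lengths=(50_000,), background_gc=0.5,
            at_tracts=[(5000, 0.3)], n_genes=50, seed=1,
            sigma_factors={},
        )
        ((rep, s, e),) = list(truth.nap_regions)
        tract = assembly[rep].sequence[s:e]
        gc = sum(c in "GC" for c in tract) / len(tract)
        assert gc == pytest.approx(0.3, abs=0.03)

    def test_no_genes(self):
        _, genes, _ = sim.simulate_genome(
            n_replicons=1, lengths=(20_000,), at_tracts=[(2000, 0.3)],
            n_genes=0, seed=1, sigma_factors={})
        assert genes == []

    def test_same_seed_identical_output(self):
        a1 = sim.simulate_genome(seed=5)
        a2 = sim.simulate_genome(seed=5)
        assert [r.sequence for r in a1[0].replicons] == [
            r.sequence for r in a2[0].replicons]
        assert a1[1] == a2[1]
        assert list(a1[2].nap_regions) == list(a2[2].nap_regions)
        assert a1[2].sigma_summits == a2[2].sigma_summits
        assert a1[2].gene_classes == a2[2].gene_classes

    def test_oversized_tract_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            sim.simulate_genome(n_replicons=1, lengths=(10_000,),
                                at_tracts=[(20_000, 0.3)], n_genes=0, seed=1)

    def test_truth_invariants(self):
        assembly, genes, truth = sim.simulate_genome(seed=2)
        lengths = {r.name: r.length for r in assembly.replicons}
        for rep, s, e in truth.nap_regions:
            assert 0 <= s < e <= lengths[rep]
        ids = {g.gene_id for g in genes}
        assert set(truth.gene_classes) <= ids
        # IS genes preferentially inside AT tracts
        is_genes = [g for g in genes if g.is_insertion_sequence]
        in_rate = np.mean([
            truth.nap_regions.covered_bp(g.replicon, g.start, g.end) > 0
            for g in is_genes])
        bg_rate = np.mean([
            truth.nap_regions.covered_bp(g.replicon, g.start, g.end) > 0
            for g in genes])
        assert in_rate > bg_rate

    def test_tu_grouping(self):
        _, genes, _ = sim.simulate_genome(seed=3)
        sizes = {}
        for g in genes:
            sizes[g.tu_id] = sizes.get(g.tu_id, 0) + 1
        assert max(sizes.values()) <= 7
        assert min(sizes.values()) >= 1


class TestSimulateChip:
    def test_null_enrichment_flat_ratio(self):
        assembly, _, truth = sim.simulate_genome(
            n_replicons=1, lengths=(100_000,), at_tracts=[(5000, 0.3)],
            n_genes=0, seed=4, sigma_factors={})
        chip = sim.simulate_chip_counts(assembly, truth, enrichment=1.0,
                                        depth=50, seed=5)
        s = binding_signal(chip.tracks["nap_ip_rep1"], chip.tracks["input"])
        mids = (s.defined["start"] + 50).to_numpy()
        in_fp = np.array([truth.nap_regions.overlaps("chr", m, m + 1) for m in mids])
        assert s.defined["value"].to_numpy()[in_fp].mean() == pytest.approx(1.0, abs=0.05)

    def test_enrichment_recovered_on_small_footprint(self):
        # One 5 kb tract on 500 kb: footprint fraction f ~ 0.01, so the
        # library normalization deflates the planted 8x only to ~8/1.07.
        assembly, _, truth = sim.simulate_genome(
            n_replicons=1, lengths=(500_000,), at_tracts=[(5000, 0.3)],
            n_genes=0, seed=6, sigma_factors={})
        chip = sim.simulate_chip_counts(assembly, truth, enrichment=8.0,
                                        depth=50, seed=7)
        s = binding_signal(chip.tracks["nap_ip_rep1"], chip.tracks["input"])
        mids = (s.defined["start"] + 50).to_numpy()
        in_fp = np.array([truth.nap_regions.overlaps("chr", m, m + 1) for m in mids])
        mean_fp = s.defined["value"].to_numpy()[in_fp].mean()
        assert mean_fp == pytest.approx(8.0, rel=0.10)

    def test_depth_must_be_positive(self):
        assembly, _, truth = sim.simulate_genome(
            n_replicons=1, lengths=(20_000,), at_tracts=[(2000, 0.3)],
            n_genes=0, seed=1, sigma_factors={})
        with pytest.raises(ValueError, match="depth"):
            sim.simulate_chip_counts(assembly, truth, depth=0)

    def test_control_artifact_removed_by_consensus(self):
        assembly, _, truth = sim.simulate_genome(
            n_replicons=1, lengths=(100_000,), at_tracts=[(5000, 0.3)],
            n_genes=0, seed=8, sigma_factors={"SigE": (20, 0.5)})
        artifact = ("chr", 60_000, 61_000)
        chip = sim.simulate_chip_counts(assembly, truth, seed=9,
                                        artifact_region=artifact)
        # the artifact is present in each replicate's candidates...
        for rep in ("rep1", "rep2"):
            assert chip.candidate_regions[rep].overlaps("chr", 60_000, 61_000)
        # ...but the control carries it too, so consensus drops it
        regions = intersect_broad(chip.candidate_regions["rep1"],
                                  chip.candidate_regions["rep2"],
                                  chip.control_regions)
        assert not regions.overlaps("chr", 60_000, 61_000)
        cons = merge_summits(chip.candidate_summits["SigE"]["rep1"],
                             chip.candidate_summits["SigE"]["rep2"],
                             chip.control_summits)
        assert all(not (60_000 <= p <= 61_000) for p in cons.positions("chr"))

    def test_determinism(self):
        assembly, _, truth = sim.simulate_genome(
            n_replicons=1, lengths=(50_000,), at_tracts=[(3000, 0.3)],
            n_genes=0, seed=10, sigma_factors={})
        c1 = sim.simulate_chip_counts(assembly, truth, seed=11)
        c2 = sim.simulate_chip_counts(assembly, truth, seed=11)
        for k in c1.tracks:
            assert np.array_equal(c1.tracks[k].counts["chr"],
                                  c2.tracks[k].counts["chr"])
        assert list(c1.candidate_regions["rep1"]) == list(c2.candidate_regions["rep1"])


class TestWriteSimulation:
    def test_emitted_files_reload_to_equal_objects(self, tmp_path):
        from napscape.dynamics import ContrastTable
        from napscape.genome import read_annotations, read_bed3, read_fasta
        from napscape.signal import read_bedgraph
        from napscape.threec import CtTable

        assembly, genes, truth = sim.simulate_genome(
            n_replicons=1, lengths=(30_000,), at_tracts=[(3000, 0.3)],
            n_genes=30, seed=12, sigma_factors={"SigE": (5, 0.5)})
        chip = sim.simulate_chip_counts(assembly, truth, seed=13)
        expr = sim.simulate_expression_table(truth.gene_classes, seed=14)
        ct = sim.simulate_3c(seed=15)
        paths = sim.write_simulation(tmp_path, assembly, genes, truth, chip,
                                     expr, ct)

        asm2 = read_fasta(paths["genome"])
        assert [r.sequence for r in asm2.replicons] == [
            r.sequence for r in assembly.replicons]
        assert read_annotations(paths["annotations"]) == genes
        assert read_bed3(paths["truth_regions"]) == truth.nap_regions
        t2 = read_bedgraph(paths["input"])
        assert np.allclose(t2.counts["chr"], chip.tracks["input"].counts["chr"])
        assert t2.total_count == chip.tracks["input"].total_count
        back = ContrastTable.from_tsv(paths["expression"])
        assert np.allclose(back.frame.to_numpy(), expr.frame.to_numpy())
        ct2 = CtTable.from_tsv(paths["ct_samples"], paths["ct_calibration"],
                               "bait")
        assert np.allclose(ct2.samples["ct"], ct.samples["ct"])
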