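"""Scanning, gene assignment, operon chaining, consistency check, assembly."""

import numpy as np
import pytest

import regulonkit as rk
from regulonkit.genome_io import Gene, Genome, OrthologyMap
from regulonkit.regulon_scan import (
    ScanConfig,
    TranscriptionUnit,
    _attach_sites_to_tus,
)
from regulonkit.synthetic_data import markov_sequence

SITE = rk.ZUR_TRAINING_SITES[0]


def brute_force_scan(model, sequence, threshold):
    """Oracle: score every window on both strands via the per-site scorer."""
    W = model.width
    hits = []
    for i in range(len(sequence) - W + 1):
        window = sequence[i : i + W]
        zf = model.score_value(window)
        zr = model.score_value(rk.revcomp(window))
        if model.palindromic:
            if zf >= threshold:
                hits.append((i, "+", zf))
        else:
            if zf >= threshold:
                hits.append((i, "+", zf))
            if zr >= threshold:
                hits.append((i, "-", zr))
    return hits


class TestScanSequence:
    def test_single_planted_site_found_at_exact_position(self, zur_model):
        rng = np.random.default_rng(2)
        flank = markov_sequence(rng, 20, 0.5, 0.0)
        genome = Genome("g", flank + SITE + flank, [])
        sites = rk.scan_sequence(zur_model, genome)
        assert len(sites) == 1
        assert sites[0].position == 20
        assert sites[0].sequence == SITE

    def test_all_n_sequence_yields_no_sites(self, zur_model):
        genome = Genome("g", "N" * 500, [])
        assert rk.scan_sequence(zur_model, genome) == []

    def test_matches_brute_force_enumeration_on_random_sequences(self, zur_model):
        rng = np.random.default_rng(17)
        # permissive threshold so some hits exist
        threshold = zur_model.threshold - 12.0
        for _ in range(100):
            seq = markov_sequence(rng, 2000, 0.54, 0.1)
            genome = Genome("g", seq, [])
            got = [(s.position, s.strand, s.z) for s in rk.scan_sequence(zur_model, genome, threshold)]
            expected = brute_force_scan(zur_model, seq, threshold)
            assert [(p, st) for p, st, _ in got] == [(p, st) for p, st, _ in expected]
            assert np.allclose([z for _, _, z in got], [z for _, _, z in expected], atol=1e-9)

    def test_raising_threshold_never_adds_sites(self, zur_model):
        rng = np.random.default_rng(6)
        genome = Genome("g", markov_sequence(rng, 5000, 0.54, 0.1), [])
        low = {(s.position, s.strand) for s in rk.scan_sequence(zur_model, genome, 10.0)}
        high = {(s.position, s.strand) for s in rk.scan_sequence(zur_model, genome, 15.0)}
        assert high <= low

    def test_palindromic_scan_is_strand_invariant(self, zur_model):
        rng = np.random.default_rng(8)
        seq = markov_sequence(rng, 3000, 0.54, 0.1)
        threshold = zur_model.threshold - 10.0
        fwd = rk.scan_sequence(zur_model, Genome("g", seq, []), threshold)
        rev = rk.scan_sequence(zur_model, Genome("g", rk.revcomp(seq), []), threshold)
        n = len(seq)
        mirrored = sorted(n - 21 - s.position for s in rev)
        assert mirrored == [s.position for s in fwd]

    def test_unset_threshold_rejected(self, zur_model):
        model = rk.build_motif(rk.ZUR_TRAINING_SITES, palindromic=True)
        with pytest.raises(ValueError, match="threshold"):
            rk.scan_sequence(model, Genome("g", "ACGT" * 100, []))


class TestAssignSites:
    def _site(self, genome, pos):
        return rk.SiteInstance(genome.genome_id, pos, "+", genome.sequence[pos : pos + 21], 30.0)

    def test_divergent_pair_shares_one_centred_site(self):
        rng = np.random.default_rng(4)
        seq = markov_sequence(rng, 1500, 0.5, 0.0)
        # genes [100,600) '-' and [629,1129) '+': 29-bp shared gap
        genome = Genome("g", seq, [Gene("left", 100, 600, "-"), Gene("right", 629, 1129, "+")])
        site = self._site(genome, 604)  # centre 614, inside both windows
        kept = rk.assign_sites_to_genes([site], genome)
        assert set(kept[0].assigned_genes) == {"left", "right"}

    def test_site_far_upstream_is_dropped(self):
        rng = np.random.default_rng(4)
        genome = Genome("g", markov_sequence(rng, 1500, 0.5, 0.0), [Gene("x", 800, 1300, "+")])
        site = self._site(genome, 290)  # centre 300, 500 bp upstream of start
        assert rk.assign_sites_to_genes([site], genome) == []

    def test_offset_sign_is_upstream_negative_in_gene_orientation(self):
        rng = np.random.default_rng(4)
        genome = Genome("g", markov_sequence(rng, 1000, 0.5, 0.0),
                        [Gene("f", 500, 900, "+"), ])
        site = self._site(genome, 440)  # centre 450 -> offset -50
        kept = rk.assign_sites_to_genes([site], genome)
        assert kept[0].assigned_genes["f"] == -50


class TestTranscriptionUnits:
    def _genome(self, genes):
        length = max(g.end for g in genes) + 100
        return Genome("g", "A" * length, genes)

    def test_codirectional_small_gaps_chain_into_one_tu(self):
        genes = [Gene("a", 100, 400, "+"), Gene("b", 410, 700, "+"), Gene("c", 720, 1000, "+")]
        tus = rk.build_transcription_units(self._genome(genes), operon_gap=100)
        assert len(tus) == 1 and tus[0].gene_ids == ["a", "b", "c"]

    def test_convergent_genes_split(self):
        genes = [Gene("a", 100, 400, "+"), Gene("b", 410, 700, "-")]
        tus = rk.build_transcription_units(self._genome(genes), operon_gap=100)
        assert len(tus) == 2

    def test_large_gap_splits_chain(self):
        genes = [Gene("a", 100, 400, "+"), Gene("b", 410, 700, "+"), Gene("c", 850, 1000, "+")]
        tus = rk.build_transcription_units(self._genome(genes), operon_gap=100)
        assert sorted(len(t.gene_ids) for t in tus) == [1, 2]

    def test_reverse_strand_tu_listed_in_transcription_order(self):
        genes = [Gene("a", 100, 400, "-"), Gene("b", 410, 700, "-")]
        tus = rk.build_transcription_units(self._genome(genes), operon_gap=100)
        assert tus[0].gene_ids == ["b", "a"]  # transcription right-to-left

    def test_every_gene_in_exactly_one_tu(self):
        rng = np.random.default_rng(12)
        genes, pos = [], 50
        for i in range(30):
            length = int(rng.integers(200, 600))
            genes.append(Gene(f"g{i}", pos, pos + length, rng.choice(["+", "-"])))
            pos += length + int(rng.integers(5, 300))
        tus = rk.build_transcription_units(self._genome(genes), operon_gap=100)
        seen = [g for tu in tus for g in tu.gene_ids]
        assert sorted(seen) == sorted(g.gene_id for g in genes)


class TestConsistencyFilter:
    def _tu(self, genome_id, gene_id, with_site):
        tu = TranscriptionUnit(f"{genome_id}:{gene_id}", [gene_id], "+")
        if with_site:
            site = rk.SiteInstance(genome_id, 0, "+", "A" * 21, 30.0)
            site.assigned_genes[gene_id] = -50
            tu.sites = [site]
        return tu

    def test_min_support_zero_is_identity_on_site_bearing_tus(self):
        orth = OrthologyMap({"F": {"g1": {"a"}, "g2": {"b"}}})
        cands = {"g1": [self._tu("g1", "a", True)], "g2": [self._tu("g2", "b", True)]}
        out = rk.consistency_filter(cands, orth, min_support=0)
        assert len(out["g1"]) == 1 and len(out["g2"]) == 1

    def test_other_genome_counting_in_three_genome_toy_panel(self):
        # family F has candidate sites in genomes 1 and 2, none in genome 3:
        # each carrier is supported by exactly ONE other genome
        orth = OrthologyMap({"F": {"g1": {"a"}, "g2": {"b"}, "g3": {"c"}}})
        cands = {
            "g1": [self._tu("g1", "a", True)],
            "g2": [self._tu("g2", "b", True)],
            "g3": [self._tu("g3", "c", False)],
        }
        at_k1 = rk.consistency_filter(cands, orth, min_support=1)
        assert len(at_k1["g1"]) == 1 and len(at_k1["g2"]) == 1 and len(at_k1["g3"]) == 0
        at_k2 = rk.consistency_filter(cands, orth, min_support=2)
        assert len(at_k2["g1"]) == 0 and len(at_k2["g2"]) == 0

    def test_filter_removes_false_positives_but_keeps_true_tus(self, zur_model):
        genomes, orth, truth = rk.simulate_panel(rk.PanelConfig(seed=77, n_genomes=10))
        cands = {}
        rng = np.random.default_rng(77)
        n_fp = 0
        for genome_id, genome in genomes.items():
            sites = rk.scan_sequence(zur_model, genome)
            sites = rk.assign_sites_to_genes(sites, genome)
            units = rk.build_transcription_units(genome)
            _attach_sites_to_tus(units, sites)
            # inject sparse uniform-random false-positive candidates on
            # background genes (independent across genomes and families)
            bg = [tu for tu in units if not tu.sites and rng.random() < 0.05]
            for tu in bg:
                fp = rk.SiteInstance(genome_id, 0, "+", "A" * 21, 30.0)
                fp.assigned_genes[tu.gene_ids[0]] = -50
                tu.sites = [fp]
                n_fp += 1
            cands[genome_id] = units
        out = rk.consistency_filter(cands, orth, min_support=2)
        kept = {(g, tu.tu_id) for g, units in out.items() for tu in units}
        true_tu_count = sum(len(v) for v in truth.regulon_tus.values())
        fp_kept = 0
        true_kept = 0
        for genome_id, units in out.items():
            for tu in units:
                if set(tu.gene_ids) <= set(truth.regulon_members.get(genome_id, [])):
                    true_kept += 1
                else:
                    fp_kept += 1
        assert n_fp > 0
        assert fp_kept <= 0.1 * n_fp
        assert true_kept >= 0.9 * true_tu_count

    def test_raising_min_support_never_adds_tus(self):
        orth = OrthologyMap({"F": {f"g{i}": {f"x{i}"} for i in range(4)}})
        cands = {f"g{i}": [self._tu(f"g{i}", f"x{i}", i < 3)] for i in range(4)}
        prev = None
        for k in (0, 1, 2, 3):
            out = rk.consistency_filter(cands, orth, min_support=k)
            kept = {(g, tu.tu_id) for g, units in out.items() for tu in units}
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestAssembleRegulon:
    def test_published_layout_yields_five_tus_nine_genes(self, zur_model, table1_fixture):
        genome, truth = table1_fixture
        df = rk.assemble_regulon(zur_model, {genome.genome_id: genome}, None)
        assert len(df) == 9
        assert df["tu_id"].nunique() == 5
        assert set(df["gene_id"]) == {g.gene_id for g in genome.genes}

    def test_every_member_traces_to_a_site_via_its_tu(self, zur_model, table1_fixture):
        genome, _ = table1_fixture
        df = rk.assemble_regulon(zur_model, {genome.genome_id: genome}, None)
        assert (df.groupby("tu_id")["evidence"].apply(lambda e: (e == "direct_site").any())).all()

    def test_no_sites_above_threshold_gives_empty_table(self, zur_model):
        rng = np.random.default_rng(5)
        genome = Genome("g", markov_sequence(rng, 3000, 0.54, 0.1),
                        [Gene("a", 1000, 1600, "+")])
        df = rk.assemble_regulon(zur_model, {"g": genome}, None)
        assert df.empty

    def test_synthetic_panel_recovery_matches_ground_truth(self, zur_model):
        genomes, orth, truth = rk.simulate_panel(rk.PanelConfig(seed=101))
        df = rk.assemble_regulon(zur_model, genomes, orth)
        pred = {(r.genome_id, r.gene_id) for r in df.itertuples()}
        true = {(g, gid) for g, genes in truth.regulon_members.items() for gid in genes}
        tp = len(pred & true)
        assert tp / len(true) >= 0.9
        assert tp / len(pred) >= 0.9
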