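import numpy as np
import pytest

from mitoscreen.annotate import (annotate_genome, call_pseudogene,
                                 detect_split_gene, find_orfs,
                                 junction_support, merge_edit_sites,
                                 observe_edit_sites, predict_edit_sites)
from mitoscreen.io import Feature, Genome, revcomp
from mitoscreen.simulate import (STOP_CODONS, SimConfig,
                                 build_recipient_genome,
                                 simulate_reference_set,
                                 simulate_transcript_reads, translate)


class TestFindOrfs:
    def test_minimal_orf(self):
        orfs = find_orfs(Genome(id="t", sequence="ATGAAATAA"), min_aa=1)
        assert len(orfs) == 1
        f = orfs[0]
        assert f.intervals == [(0, 9)] and f.strand == "+"

    def test_no_atg_no_orfs(self):
        # TAA-only landscape without any ATG (also none on the minus strand)
        assert find_orfs(Genome(id="t", sequence="TTTTAATTTTAA"), 1) == []

    def test_matches_exhaustive_frame_enumeration(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), 5000))
        got = set()
        for f in find_orfs(Genome(id="x", sequence=seq), min_aa=10):
            L = int(f.qualifiers["length_nt"])
            start = (f.intervals[0][0] if f.strand == "+"
                     else len(seq) - f.intervals[-1][1])
            got.add((f.strand, start, start + L))
        want = set()
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            for frame in range(3):
                start = None
                for i in range(frame, len(s) - 2, 3):
                    c = s[i:i + 3]
                    if start is None and c == "ATG":
                        start = i
                    elif start is not None and c in STOP_CODONS:
                        if i + 3 - start >= 33:
                            want.add((strand, start, i + 3))
                        start = None
        assert got == want

    def test_circular_orf_across_origin(self):
        core = "ATGAAAGGG"
        g = Genome(id="c", sequence="CCC" + "TAA" + "T" * 10 + core[:-3],
                   circular=False)
        # linear: ORF must not wrap; circular: it can
        seq = core[3:] + "TAATTTTTTT" + "ATG"
        lin = find_orfs(Genome(id="l", sequence=seq), 1)
        circ = find_orfs(Genome(id="c", sequence=seq, circular=True), 1)
        assert any(f.qualifiers.get("wraps_origin") == "yes" for f in circ)
        assert not any(f.qualifiers.get("wraps_origin") == "yes" for f in lin)


@pytest.fixture(scope="module")
def annotated(structured_bundle):
    cfg, panel, g, truth = structured_bundle
    ref_cds = {gene: panel.gene_sequences["Order_1|taxon_1"][gene]
               for gene, t in panel.gene_types.items() if t == "CDS"}
    return cfg, panel, g, truth, ref_cds, annotate_genome(g, ref_cds)


class TestAnnotateGenome:
    def test_planted_intact_genes_recovered(self, annotated):
        cfg, panel, g, truth, ref_cds, models = annotated
        planted = {f.gene: f for f in truth.gene_features}
        for gene, m in models.items():
            if gene in cfg.missing_genes or gene == cfg.transsplice_gene:
                continue
            assert m.completeness == "intact", gene
            f = planted[gene]
            assert m.exon_loci[0][0] == f.intervals[0]
            assert m.exon_loci[0][1] == f.strand
            assert m.coding_length == len(ref_cds[gene])

    def test_missing_gene_absent(self, annotated):
        cfg, panel, g, truth, ref_cds, models = annotated
        for gene in cfg.missing_genes:
            assert models[gene].completeness == "absent"

    def test_split_gene_fragmented_multiple_loci(self, annotated):
        cfg, panel, g, truth, ref_cds, models = annotated
        m = models[cfg.transsplice_gene]
        assert m.completeness == "fragmented"
        assert len(m.exon_loci) == 3


class TestCallPseudogene:
    def _intact_model(self, seed=33):
        cfg = SimConfig(seed=seed, genome_length_bp=9_000, n_genes=3,
                        include_rrn=False)
        panel = simulate_reference_set(cfg)
        g, truth = build_recipient_genome(cfg, panel)
        f = next(f for f in truth.gene_features if f.type == "CDS")
        from mitoscreen.annotate import GeneModel
        model = GeneModel(gene=f.gene, exon_loci=[(f.intervals[0], f.strand)],
                          completeness="intact",
                          coding_length=f.span_bp())
        return g, f, model

    def test_intact_gene_unchanged(self):
        g, f, model = self._intact_model()
        out = call_pseudogene(model, g)
        assert out.completeness == "intact" and not out.defects

    def test_single_base_insertion_is_frameshift(self):
        g, f, model = self._intact_model()
        s, e = f.intervals[0]
        mutated = g.sequence[:s + 30] + "A" + g.sequence[s + 30:]
        g2 = Genome(id="m", sequence=mutated)
        model.exon_loci = [((s, e + 1), f.strand)]
        out = call_pseudogene(model, g2)
        assert out.completeness == "pseudogene"
        assert any(k == "frameshift" for k, _ in out.defects)

    def test_internal_stop_detected(self):
        g, f, model = self._intact_model()
        s, e = f.intervals[0]
        cds = f.extract(g)
        cds = cds[:60] + "TAA" + cds[63:]  # stop at codon 20
        placed = revcomp(cds) if f.strand == "-" else cds
        g2 = Genome(id="m", sequence=g.sequence[:s] + placed + g.sequence[e:])
        out = call_pseudogene(model, g2)
        assert out.completeness == "pseudogene"
        assert ("internal_stop", 60) in out.defects

    def test_never_fires_on_planted_intact_cds_many_seeds(self):
        # sweep: conceptual translation of every planted intact gene is clean
        for seed in range(100):
            cfg = SimConfig(seed=seed, genome_length_bp=8_000, n_genes=3,
                            include_rrn=False)
            panel = simulate_reference_set(cfg)
            g, truth = build_recipient_genome(cfg, panel)
            for f in truth.gene_features:
                if f.type != "CDS":
                    continue
                prot = translate(f.extract(g))
                assert "*" not in prot[:-1], (seed, f.gene)


class TestDetectSplitGene:
    def test_three_locus_layout_trans_trans(self, structured_bundle):
        cfg, panel, g, truth = structured_bundle
        ref = panel.gene_sequences["Order_1|taxon_1"][cfg.transsplice_gene]
        m = detect_split_gene(cfg.transsplice_gene, ref, g,
                              min_separation_bp=1500)
        assert m.intron_layout == ["trans", "trans"]
        assert any("within-exon split at junction 1" in n for n in m.notes)
        truth_ivs = sorted(iv for _, iv, _ in
                           truth.true_transsplice_layout["pieces"])
        got = sorted(iv for iv, _ in m.exon_loci)
        for (gs, ge), (ts, te) in zip(got, truth_ivs):
            # local alignments may trim a few diverged bases off piece edges
            assert abs(gs - ts) <= 12 and abs(ge - te) <= 12

    def test_intact_gene_reported_intact(self, structured_bundle):
        cfg, panel, g, truth = structured_bundle
        ref = panel.gene_sequences["Order_1|taxon_1"]["atp1"]
        m = detect_split_gene("atp1", ref, g)
        assert m.completeness == "intact"
        assert m.intron_layout == []

    def test_opposite_strand_piece_forces_trans_at_any_distance(self):
        rng = np.random.default_rng(44)
        ref = "ATG" + "".join(rng.choice(list("ACGT"), 597))
        left, right = ref[:300], ref[300:]
        filler = "".join(rng.choice(list("ACGT"), 200))
        seq = ("".join(rng.choice(list("ACGT"), 500)) + left + filler
               + revcomp(right) + "".join(rng.choice(list("ACGT"), 500)))
        m = detect_split_gene("nad1", ref, Genome(id="x", sequence=seq),
                              min_separation_bp=5000)
        assert m.intron_layout == ["trans"]

    def test_contig_break_between_pieces_forces_trans(self):
        rng = np.random.default_rng(45)
        ref = "ATG" + "".join(rng.choice(list("ACGT"), 597))
        seq = ("".join(rng.choice(list("ACGT"), 300)) + ref[:300]
               + "".join(rng.choice(list("ACGT"), 100)) + ref[300:]
               + "".join(rng.choice(list("ACGT"), 300)))
        g_cis = Genome(id="x", sequence=seq)
        g_brk = Genome(id="x", sequence=seq, contig_breaks=[650])
        assert detect_split_gene("g", ref, g_cis).intron_layout == ["cis"]
        assert detect_split_gene("g", ref, g_brk).intron_layout == ["trans"]


@pytest.fixture(scope="module")
def transcript_data(structured_bundle):
    cfg, panel, g, truth = structured_bundle
    reads = simulate_transcript_reads(g, truth, cfg)
    return cfg, panel, g, truth, reads


class TestJunctionSupport:
    def _split_model(self, cfg, panel, g, truth):
        ts = truth.true_transsplice_layout
        from mitoscreen.annotate import GeneModel
        return GeneModel(gene=ts["gene"],
                         exon_loci=[(iv, st) for _, iv, st in ts["pieces"]],
                         intron_layout=["trans", "trans"],
                         completeness="fragmented")

    def test_transspliced_junction_supported_orphan_junction_not(
            self, transcript_data):
        cfg, panel, g, truth, reads = transcript_data
        model = self._split_model(cfg, panel, g, truth)
        recs = junction_support(model, g, reads)
        j1, j2 = recs  # junction 1: x1a|x1b (orphan); junction 2: x1b|x2
        assert j1["n_pairs"] == 0 and j1["n_split_reads"] == 0
        assert j2["n_pairs"] + j2["n_split_reads"] >= 1

    def test_genomic_reads_give_no_junction_support(self, transcript_data):
        cfg, panel, g, truth, reads = transcript_data
        from mitoscreen.io import ReadRecord
        model = self._split_model(cfg, panel, g, truth)
        genomic = [ReadRecord(id=f"g{i}", sequence=g.sequence[i:i + 150])
                   for i in range(0, len(g) - 150, 500)]
        recs = junction_support(model, g, genomic)
        assert all(r["n_pairs"] == 0 and r["n_split_reads"] == 0
                   for r in recs)

    def test_shuffled_reads_negative_control(self, transcript_data):
        cfg, panel, g, truth, reads = transcript_data
        rng = np.random.default_rng(5)
        model = self._split_model(cfg, panel, g, truth)
        shuffled = []
        from mitoscreen.io import ReadRecord
        for r in reads[:200]:
            chars = list(r.sequence)
            rng.shuffle(chars)
            shuffled.append(ReadRecord(id=r.id, sequence="".join(chars),
                                       paired_with=r.paired_with))
        recs = junction_support(model, g, shuffled)
        assert all(r["n_pairs"] == 0 and r["n_split_reads"] == 0
                   for r in recs)

    def test_single_piece_model_rejected(self, transcript_data):
        cfg, panel, g, truth, reads = transcript_data
        from mitoscreen.annotate import GeneModel
        m = GeneModel(gene="x", exon_loci=[((0, 300), "+")])
        with pytest.raises(ValueError):
            junction_support(m, g, reads)


class TestEditSites:
    def test_forced_prediction_rule(self):
        # focal codon CCT (Pro); ten homologs all Leu; C2->T gives CTT (Leu)
        focal = "ATG" + "CCT" + "TAA"
        homologs = ["ML"] * 10
        sites = predict_edit_sites(focal, homologs)
        assert any(s.position == 4 and s.codon_pos == 2
                   and s.predicted_score == 1.0 for s in sites)

    def test_codon_matching_consensus_not_predicted(self):
        focal = "ATG" + "CTT" + "TAA"  # already Leu like the homologs
        homologs = ["ML"] * 10
        assert predict_edit_sites(focal, homologs) == []

    def test_simulated_sites_recall(self, structured_bundle):
        cfg, panel, g, truth = structured_bundle
        gene = truth.provenance["edit_gene"]
        feat = next(f for f in truth.gene_features if f.gene == gene)
        focal = feat.extract(g)
        homologs = [translate(panel.gene_sequences[t][gene])[:-1]
                    for t in panel.taxa]
        sites = predict_edit_sites(focal, homologs, feature=feat)
        got = {s.position for s in sites}
        want = set(truth.true_edit_sites)
        recall = len(got & want) / len(want)
        assert recall >= 0.8

    def test_observed_sites_threshold_rules(self, transcript_data):
        cfg, panel, g, truth, reads = transcript_data
        gene = truth.provenance["edit_gene"]
        feat = next(f for f in truth.gene_features if f.gene == gene)
        from mitoscreen.annotate import GeneModel
        model = GeneModel(gene=gene, exon_loci=[(feat.intervals[0],
                                                 feat.strand)])
        observed = observe_edit_sites(g, model, reads)
        got = {s.position for s in observed}
        want = set(truth.true_edit_sites)
        # all planted sites observed; no more than one spurious site
        assert want <= got
        assert len(got - want) <= 1
        for s in observed:
            assert s.observed_fraction >= 0.5

    def test_merge_status_partition(self):
        from mitoscreen.annotate import EditSite
        pred = [EditSite(position=10, codon_pos=1, predicted_score=0.9),
                EditSite(position=20, codon_pos=2, predicted_score=0.7)]
        obs = [EditSite(position=20, codon_pos=2, observed_fraction=0.95,
                        status="observed_only"),
               EditSite(position=30, codon_pos=3, observed_fraction=0.8,
                        status="observed_only")]
        merged = merge_edit_sites(pred, obs)
        status = {s.position: s.status for s in merged}
        assert status == {10: "predicted_only", 20: "both",
                          30: "observed_only"}
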