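"""Plastid-to-mitogenome transfer detection and the order-level HGT screens.

Three complementary screens:

* ``plastid_hit_screen`` finds mitogenome regions similar to reference
  plastomes (plastid-derived transfer candidates, MTPT), excluding the
  ribosomal genes and atp1 whose plastid homology is ancient;
* ``classify_transfer`` assigns each region one of four putative origins -
  homology (ancient similarity), intracellular (own-lineage plastome to
  mitogenome), HGT_candidate (foreign origin) or mitogenome (ordinary
  mitochondrial sequence that happens to resemble the plastome);
* ``intergenic_order_screen`` searches reference mitogenomes grouped by
  order against the assembly and flags long tracts matched by a foreign
  order but not by the focal order;
* ``nuclear_copy_search`` looks for nuclear copies of genes missing from
  the mitogenome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Feature, Genome
from .search import (Hit, SearchParams, coverage_fraction, filter_hits,
                     local_search, near_top_filter)
from .simulate import STOP_CODONS, translate

# mitochondrial genes with well-known plastid homologs (ancient similarity)
PLASTID_HOMOLOG_GENES = {
    "nad5": "ndhF", "nad1": "ndhA", "nad2": "ndhB", "nad4": "ndhD",
    "atp1": "atpA", "rrn18": "rrn16", "rrn26": "rrn23",
}


@dataclass
class OrderHitTrack:
    """Filtered hits of one reference order along the assembly."""

    order_name: str
    hits: list = field(default_factory=list)
    covered_bp: int = 0


@dataclass
class TransferCall:
    """One classified plastome-hit region or HGT-candidate tract."""

    region: tuple[int, int]
    length_bp: int
    identity_range: tuple[float, float]
    category: str  # homology|intracellular|HGT_candidate|mitogenome|withheld
    evidence: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("a TransferCall requires non-empty evidence")


# ---------------------------------------------------------------------------
# plastome hits


def plastid_hit_screen(mito: Genome, plastome_refs: list[Genome],
                       mito_features: list[Feature],
                       p: SearchParams | None = None,
                       merge_gap_bp: int = 100) -> list[dict]:
    """Regions of the mitogenome hit by reference plastomes.

    Hits overlapping annotated rRNA genes or atp1 are excluded; the rest
    are merged into regions separated by < ``merge_gap_bp``.  Each region
    records its span, length and identity range.
    """
    p = p or SearchParams()
    excluded = []
    for f in mito_features:
        if f.type == "rRNA" or f.gene.startswith("rrn") or f.gene == "atp1":
            excluded.extend(f.intervals)

    def is_excluded(h: Hit) -> bool:
        return any(min(h.s_end, e) - max(h.s_start, s) > 0
                   for s, e in excluded)

    all_hits = []
    for ref in plastome_refs:
        for h in local_search(ref, mito, p):
            if not is_excluded(h):
                all_hits.append(h)
    all_hits.sort(key=lambda h: h.s_start)
    regions = []
    for h in all_hits:
        if regions and h.s_start - regions[-1]["end"] < merge_gap_bp:
            r = regions[-1]
            r["end"] = max(r["end"], h.s_end)
            r["hits"].append(h)
        else:
            regions.append({"start": h.s_start, "end": h.s_end, "hits": [h]})
    for r in regions:
        idents = [h.identity_percent for h in r["hits"]]
        r["length_bp"] = r["end"] - r["start"]
        r["identity_range"] = (min(idents), max(idents))
        r["plastid_queries"] = sorted({h.query_id for h in r["hits"]})
    return regions


def plastid_gene_status(gene_ref_cds: str, own_plastome: Genome,
                        p: SearchParams | None = None) -> str:
    """Is this plastid gene present, pseudogenized or absent in a plastome?"""
    p = p or SearchParams(min_score=40)
    hits = local_search(gene_ref_cds, own_plastome, p)
    if not hits:
        return "absent"
    top = hits[0]
    if (top.q_end - top.q_start) < 0.9 * len(gene_ref_cds):
        return "pseudogene"
    seq = own_plastome.sequence[top.s_start:top.s_end]
    if top.strand == "-":
        from .io import revcomp
        seq = revcomp(seq)
    frame = top.q_start % 3
    trim = (3 - frame) % 3
    seq = seq[trim:]
    seq = seq[: len(seq) - len(seq) % 3]
    prot = translate(seq)
    if "*" in prot[:-1]:
        return "pseudogene"
    return "present"


def identity_to_genomes(region_seq: str, genomes: list[Genome],
                        p: SearchParams | None = None) -> float:
    """Best identity of a region against a genome set, requiring the match
    to cover >= 90% of the region."""
    p = p or SearchParams()
    best = 0.0
    for g in genomes:
        for h in local_search(region_seq, g, p):
            if (h.q_end - h.q_start) >= 0.9 * len(region_seq):
                best = max(best, h.identity_percent)
    return best


def classify_transfer(region: dict, placement, own_plastome: Genome | None,
                      related_mitos: list[Genome],
                      annotations: list[Feature],
                      mito: Genome | None = None,
                      matched_plastid_gene: str | None = None,
                      matched_plastid_gene_ref: str | None = None,
                      mitogenome_identity_bound: float = 98.0) -> TransferCall:
    """Four-way origin call for one plastome-hit region.

    Decision cascade: (i) >= 98% identical to related reference mitogenomes
    -> mitogenome; (ii) region overlaps a mitochondrial gene with a known
    plastid homolog -> homology; (iii) phylogenetic placement with the
    own-lineage plastome -> intracellular; (iv) placement with a distant
    lineage, or the matched plastid gene absent/pseudogenized in the own
    plastome -> HGT_candidate.  Unresolved placements fall back to the
    lowest-commitment applicable category with an "unresolved" code.
    """
    s, e = region["start"], region["end"]
    ident_range = region.get("identity_range", (0.0, 0.0))
    evidence: list[str] = []

    if mito is not None and related_mitos:
        rel = identity_to_genomes(mito.sequence[s:e], related_mitos)
        if rel >= mitogenome_identity_bound:
            evidence.append(f"{rel:.1f}% identical to related mitogenomes")
            return TransferCall((s, e), e - s, ident_range, "mitogenome",
                                evidence)

    for f in annotations:
        if f.gene in PLASTID_HOMOLOG_GENES and \
                any(min(e, fe) - max(s, fs) > 0 for fs, fe in f.intervals):
            evidence.append(
                f"overlaps {f.gene} (plastid homolog "
                f"{PLASTID_HOMOLOG_GENES[f.gene]})")
            return TransferCall((s, e), e - s, ident_range, "homology",
                                evidence)

    if matched_plastid_gene and own_plastome is not None \
            and matched_plastid_gene_ref:
        status = plastid_gene_status(matched_plastid_gene_ref, own_plastome)
        if status != "present":
            evidence.append(
                f"matched plastid gene {matched_plastid_gene} {status} "
                "in own plastome")
            return TransferCall((s, e), e - s, ident_range, "HGT_candidate",
                                evidence)

    if placement is None:
        return TransferCall((s, e), e - s, ident_range, "withheld",
                            ["no placement"])
    verdict = getattr(placement, "verdict", placement)
    if verdict == "vertical":
        evidence.append("placement groups with own-lineage plastome")
        return TransferCall((s, e), e - s, ident_range, "intracellular",
                            evidence)
    if verdict == "hgt_candidate":
        sister = getattr(placement, "sister_clade", "distant lineage")
        evidence.append(f"placement groups with {sister}")
        return TransferCall((s, e), e - s, ident_range, "HGT_candidate",
                            evidence)
    evidence.append("unresolved placement")
    return TransferCall((s, e), e - s, ident_range, "intracellular", evidence)


def place_region(region_seq: str, labeled_sources: dict[str, Genome],
                 own_label: str, seed: int = 0, n_reps: int = 200):
    """Phylogenetic placement of a region among candidate source genomes.

    The region plus the best-matching segment of each labelled source genome
    are aligned (mafft) and a bootstrapped distance tree built; the verdict
    says whether the region groups with ``own_label`` (vertical ->
    intracellular origin) or with a foreign source (hgt_candidate).
    Returns None when fewer than three sources yield a usable segment.
    """
    from .annotate import _mafft_align
    from .io import revcomp
    from .phylo import MSA, bootstrap_support, grouping_test, mask_columns

    p = SearchParams(min_score=40)
    segs = {"region": region_seq}
    for label, g in labeled_sources.items():
        hits = local_search(region_seq, g, p)
        if not hits:
            continue
        h = hits[0]
        seg = g.sequence[h.s_start:h.s_end]
        if h.strand == "-":
            seg = revcomp(seg)
        segs[label] = seg
    if own_label not in segs or len(segs) < 4:
        return None
    labels = list(segs)
    aligned = _mafft_align([segs[k] for k in labels])
    msa = mask_columns(MSA(taxa=labels, rows=aligned, name="region_placement"))
    tree = bootstrap_support(msa, n_reps=n_reps, seed=seed)
    groups = {lab: {lab} for lab in labels if lab != "region"}
    return grouping_test(tree, {"region"}, own_label, groups,
                         threshold=80, gene="region")


# ---------------------------------------------------------------------------
# order-level intergenic screen


def intergenic_order_screen(mito: Genome,
                            ref_mitos_by_order: dict[str, list[Genome]],
                            focal_order: str,
                            p: SearchParams | None = None,
                            min_len_bp: int = 250,
                            min_identity_percent: float = 80.0,
                            min_candidate_bp: int = 500):
    """Per-order hit tracks plus >= ``min_candidate_bp`` foreign tracts.

    Every reference mitogenome is searched against the assembly; hits below
    250 bp / 80% identity are removed and the display filter collapses
    dominated hits.  A candidate is a contiguous >= 500 bp stretch of a
    non-focal order's hit that the focal order's coverage mask leaves
    uncovered.  Returns (tracks, candidates, candidate_percent).
    """
    if focal_order not in ref_mitos_by_order:
        raise ValueError(f"focal order {focal_order!r} missing from references")
    p = p or SearchParams()
    n = len(mito)
    hits_by_order: dict[str, list[Hit]] = {}
    for order, refs in ref_mitos_by_order.items():
        hits = []
        for ref in refs:
            hits.extend(local_search(ref, mito, p))
        hits = filter_hits(hits, min_len_bp, min_identity_percent)
        hits_by_order[order] = hits

    focal_mask = np.zeros(n, bool)
    for h in hits_by_order[focal_order]:
        focal_mask[max(0, h.s_start):min(n, h.s_end)] = True

    tracks = []
    for order, hits in hits_by_order.items():
        shown = near_top_filter(hits)
        mask = np.zeros(n, bool)
        for h in shown:
            mask[max(0, h.s_start):min(n, h.s_end)] = True
        tracks.append(OrderHitTrack(order_name=order, hits=shown,
                                    covered_bp=int(mask.sum())))

    cand_mask = np.zeros(n, bool)
    candidates = []
    for order, hits in hits_by_order.items():
        if order == focal_order:
            continue
        for h in hits:
            uncovered = ~focal_mask[h.s_start:h.s_end]
            # contiguous escape runs
            run = 0
            run_start = None
            for i, u in enumerate(list(uncovered) + [False]):
                if u:
                    if run == 0:
                        run_start = i
                    run += 1
                else:
                    if run >= min_candidate_bp:
                        a = h.s_start + run_start
                        b = a + run
                        candidates.append(TransferCall(
                            (a, b), b - a,
                            (h.identity_percent, h.identity_percent),
                            "HGT_candidate",
                            [f"hit by {order} ({h.query_id}), "
                             f"not covered by {focal_order}"]))
                        cand_mask[a:b] = True
                    run = 0
    candidate_percent = 100.0 * float(cand_mask.sum()) / n
    # merge duplicate candidate regions from multiple refs of one order
    merged: list[TransferCall] = []
    for c in sorted(candidates, key=lambda c: c.region):
        if merged and c.region[0] < merged[-1].region[1]:
            last = merged[-1]
            a = last.region[0]
            b = max(last.region[1], c.region[1])
            last.region = (a, b)
            last.length_bp = b - a
            last.identity_range = (min(last.identity_range[0],
                                       c.identity_range[0]),
                                   max(last.identity_range[1],
                                       c.identity_range[1]))
            last.evidence = sorted(set(last.evidence) | set(c.evidence))
        else:
            merged.append(c)
    return tracks, merged, candidate_percent


# ---------------------------------------------------------------------------
# nuclear copies of missing genes


def nuclear_copy_search(missing_genes: dict[str, str],
                        nuclear: list[Genome],
                        p: SearchParams | None = None,
                        min_identity_percent: float = 50.0) -> list[dict]:
    """Best nuclear locus per missing mitochondrial gene.

    Reports, per gene: whether a copy was found (>= 50% identity), its
    length, identity, whether its reading frame is intact and whether a
    start codon could be determined.
    """
    p = p or SearchParams(min_score=40)
    out = []
    for gene, ref in missing_genes.items():
        best = None
        for ng in nuclear:
            for h in local_search(ref, ng, p):
                if h.identity_percent < min_identity_percent:
                    continue
                if best is None or h.score > best[0].score:
                    best = (h, ng)
        rec = {"gene": gene, "found": best is not None,
               "copy_length_bp": 0, "identity_percent": None,
               "orf_intact": None, "has_start": None}
        if best:
            h, ng = best
            seq = ng.sequence[h.s_start:h.s_end]
            if h.strand == "-":
                from .io import revcomp
                seq = revcomp(seq)
            frame = h.q_start % 3
            trim = (3 - frame) % 3
            coding = seq[trim:]
            coding = coding[: len(coding) - len(coding) % 3]
            prot = translate(coding)
            internal = prot[:-1] if prot.endswith("*") else prot
            rec["copy_length_bp"] = h.s_end - h.s_start
            rec["identity_percent"] = h.identity_percent
            rec["orf_intact"] = "*" not in internal
            rec["has_start"] = (h.q_start == 0
                                and seq[:3] == "ATG")
        out.append(rec)
    return out


def nuclear_mito_coverage(mito: Genome, nuclear: list[Genome],
                          p: SearchParams | None = None,
                          min_len_bp: int = 250,
                          min_identity_percent: float = 80.0) -> float:
    """Fraction of the mitogenome covered by nuclear-genome hits."""
    p = p or SearchParams()
    hits = []
    for ng in nuclear:
        hits.extend(local_search(ng, mito, p))
    hits = filter_hits(hits, min_len_bp, min_identity_percent)
    return coverage_fraction(hits, mito)


def write_transfer_calls_tsv(calls: list[TransferCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tlength_bp\tidentity_range\tcategory\tnote\n")
        for c in calls:
            fh.write("\t".join([
                str(c.region[0] + 1), str(c.region[1]), str(c.length_bp),
                f"{c.identity_range[0]:.0f}-{c.identity_range[1]:.0f}",
                c.category, "; ".join(c.evidence)]) + "\n")
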