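"""Similarity-based gene annotation and structural/expression evidence calls.

Genes are located by searching reference CDS against the genome and chaining
colinear hits; disabled copies (frameshifts, internal stops) are flagged as
pseudogenes; split genes are classified into cis/trans intron layouts; and
transcript reads provide junction support and observed C-to-U editing sites
to compare against conservation-based predictions.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import Feature, Genome, ReadRecord, revcomp
from .search import SearchParams, local_search, pairwise_local
from .simulate import CODON_TABLE, STOP_CODONS, translate

COL_MATCH, COL_MISMATCH, COL_GAP_Q, COL_GAP_S = 0, 1, 2, 3


@dataclass
class GeneModel:
    """One gene's best-supported structure on a genome."""

    gene: str
    exon_loci: list = field(default_factory=list)   # [((start, end), strand)]
    intron_layout: list = field(default_factory=list)  # "cis" | "trans"
    completeness: str = "absent"  # intact|fragmented|pseudogene|absent
    coding_length: int = 0
    defects: list = field(default_factory=list)     # (kind, cds_position)
    junction_ref_gaps: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def spliced(self, g: Genome) -> str:
        parts = []
        for (s, e), strand in self.exon_loci:
            part = g.sequence[s:e]
            parts.append(revcomp(part) if strand == "-" else part)
        return "".join(parts)


@dataclass
class EditSite:
    """A (putative) C-to-U editing site on the coding strand."""

    position: int            # 0-based genome coordinate
    codon_pos: int           # 1..3
    predicted_score: float | None = None
    observed_fraction: float | None = None
    status: str = "predicted_only"  # predicted_only|observed_only|both


# ---------------------------------------------------------------------------
# ORF finding


def find_orfs(g: Genome, min_aa: int = 30) -> list[Feature]:
    """ATG..stop ORFs in all six frames (origin-crossing for circular)."""
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    n = len(g)
    out = []
    seen = set()
    for strand in "+-":
        seq = g.sequence if strand == "+" else revcomp(g.sequence)
        scan = seq + seq[: n - 1] if g.circular else seq
        for frame in range(3):
            start = None
            i = frame
            while i + 3 <= len(scan):
                codon = scan[i:i + 3]
                if start is None:
                    if codon == "ATG" and i < n:  # starts within first copy
                        start = i
                elif codon in STOP_CODONS:
                    length = i + 3 - start
                    if length >= 3 * (min_aa + 1):
                        key = (strand, start % n, length)
                        if key not in seen:
                            seen.add(key)
                            ivs, wrap = _orf_intervals(start, i + 3, n, strand)
                            out.append(Feature(
                                gene=f"orf_{strand}{start % n + 1}",
                                type="other", intervals=ivs, strand=strand,
                                qualifiers={"orf": "yes", "length_nt": str(length),
                                            **({"wraps_origin": "yes"} if wrap else {})}))
                    start = None
                i += 3
    out.sort(key=lambda f: (f.start, f.gene))
    return out


def _orf_intervals(start, end, n, strand):
    """Map ORF coords on the (possibly doubled) scanned strand to forward
    genome intervals."""
    wrap = end > n
    if strand == "+":
        if not wrap:
            return [(start, end)], False
        return [(start, n), (0, end - n)], True
    # minus strand: scanned sequence is the reverse complement
    if not wrap:
        return [(n - end, n - start)], False
    return [(0, n - start), (2 * n - end, n)], True


# ---------------------------------------------------------------------------
# gene annotation


def default_annotation_params() -> SearchParams:
    return SearchParams(min_score=40, min_len_bp=50)


def _chain_hits(hits, max_join_gap=30):
    """Merge query-colinear hits on one strand/diagonal into pieces.

    Returns pieces sorted by reference coordinate, each
    (q_start, q_end, s_start, s_end, strand).
    """
    pieces = []
    for h in sorted(hits, key=lambda h: h.q_start):
        merged = False
        for pc in pieces:
            if pc[4] != h.strand:
                continue
            qgap = h.q_start - pc[1]
            if not -10 <= qgap <= max_join_gap:
                continue
            if h.strand == "+":
                sgap = h.s_start - pc[3]
                if -10 <= sgap <= max_join_gap + 10 and abs(sgap - qgap) <= 20:
                    pc[1] = max(pc[1], h.q_end)
                    pc[3] = max(pc[3], h.s_end)
                    merged = True
                    break
            else:
                sgap = pc[2] - h.s_end
                if -10 <= sgap <= max_join_gap + 10 and abs(sgap - qgap) <= 20:
                    pc[1] = max(pc[1], h.q_end)
                    pc[2] = min(pc[2], h.s_start)
                    merged = True
                    break
        if not merged:
            pieces.append([h.q_start, h.q_end, h.s_start, h.s_end, h.strand])
    # keep the best piece per query region (drop sub-pieces of other copies)
    pieces.sort(key=lambda pc: (pc[0], -(pc[1] - pc[0])))
    kept = []
    for pc in pieces:
        if any(pc[0] >= k[0] and pc[1] <= k[1] for k in kept):
            continue
        kept.append(pc)
    kept.sort(key=lambda pc: pc[0])
    return kept


def annotate_genome(g: Genome, ref_cds: dict[str, str],
                    ref_proteins: dict[str, str] | None = None,
                    p: SearchParams | None = None,
                    max_intron_bp: int = 5000) -> dict[str, GeneModel]:
    """Annotate every reference gene on the genome by hit chaining.

    A gene is *intact* when a single locus (or a cis-intron chain) covers
    >= 95% of the reference and conceptual translation is clean; broken
    copies become *fragmented* models; disabling defects turn the call into
    *pseudogene*; genes with no passing hit are *absent*.
    """
    p = p or default_annotation_params()
    models: dict[str, GeneModel] = {}
    for gene, ref in ref_cds.items():
        hits = local_search(ref, g, p)
        model = GeneModel(gene=gene)
        if not hits:
            models[gene] = model
            continue
        pieces = _chain_hits(hits)
        cov = sum(q1 - q0 for q0, q1, *_ in pieces) / len(ref)
        model.exon_loci = [((s0, s1), strand)
                           for _, _, s0, s1, strand in pieces]
        model.coding_length = sum(s1 - s0 for (s0, s1), _ in model.exon_loci)
        for i in range(len(pieces) - 1):
            q0a, q1a, s0a, s1a, sta = pieces[i]
            q0b, q1b, s0b, s1b, stb = pieces[i + 1]
            model.junction_ref_gaps.append(max(0, q0b - q1a))
            if sta != stb:
                model.intron_layout.append("trans")
            else:
                gap = (s0b - s1a) if sta == "+" else (s0a - s1b)
                ordered = gap >= -10
                model.intron_layout.append(
                    "cis" if (ordered and gap <= max_intron_bp) else "trans")
        if len(pieces) == 1 or all(x == "cis" for x in model.intron_layout):
            model.completeness = "intact" if cov >= 0.95 else "fragmented"
            if cov < 0.95:
                model.notes.append(f"partial: {cov:.0%} of reference")
        else:
            model.completeness = "fragmented"
            model.notes.append("pieces on separate loci")
        if model.completeness == "intact":
            model = call_pseudogene(model, g)
        models[gene] = model
    return models


def call_pseudogene(model: GeneModel, g: Genome) -> GeneModel:
    """Flag disabling defects: net frameshift or internal stop codons."""
    if not model.exon_loci:
        return model
    cds = model.spliced(g)
    if len(cds) % 3 != 0:
        model.defects.append(("frameshift", len(cds) % 3))
    prot = translate(cds)
    internal = prot[:-1] if prot.endswith("*") else prot
    for i, aa in enumerate(internal):
        if aa == "*":
            model.defects.append(("internal_stop", 3 * i))
    if model.defects:
        model.completeness = "pseudogene"
    return model


def detect_split_gene(gene: str, intronless_ref_cds: str, g: Genome,
                      p: SearchParams | None = None,
                      min_separation_bp: int = 5000,
                      abut_tolerance_bp: int = 10) -> GeneModel:
    """Classify a gene's pieces into a cis/trans intron layout.

    Pieces are hits to an intron-less reference CDS ordered by reference
    coordinate.  Adjacent pieces on the same strand, in genomic order and
    within ``min_separation_bp`` are cis; greater separation, strand change
    or a contig break between them forces trans.  Pieces that abut on the
    reference (no reference gap beyond ``abut_tolerance_bp``, which absorbs
    terminal mismatches trimmed off local alignments) additionally flag a
    within-exon split.
    """
    p = p or default_annotation_params()
    hits = local_search(intronless_ref_cds, g, p)
    model = GeneModel(gene=gene)
    if not hits:
        return model
    pieces = _chain_hits(hits)
    model.exon_loci = [((s0, s1), strand) for _, _, s0, s1, strand in pieces]
    model.coding_length = sum(s1 - s0 for (s0, s1), _ in model.exon_loci)
    if len(pieces) < 2:
        cov = (pieces[0][1] - pieces[0][0]) / len(intronless_ref_cds)
        model.completeness = "intact" if cov >= 0.95 else "fragmented"
        return model
    model.completeness = "fragmented"
    breaks = set(g.contig_breaks)
    for i in range(len(pieces) - 1):
        q0a, q1a, s0a, s1a, sta = pieces[i]
        q0b, q1b, s0b, s1b, stb = pieces[i + 1]
        ref_gap = max(0, q0b - q1a)
        model.junction_ref_gaps.append(ref_gap)
        lo = min(s1a, s1b)
        hi = max(s0a, s0b)
        crosses_break = any(lo <= br < hi for br in breaks)
        if sta != stb or crosses_break:
            model.intron_layout.append("trans")
        else:
            gap = (s0b - s1a) if sta == "+" else (s0a - s1b)
            ordered = gap >= -10
            model.intron_layout.append(
                "cis" if ordered and gap <= min_separation_bp else "trans")
        if ref_gap <= abut_tolerance_bp:
            model.notes.append(f"within-exon split at junction {i + 1}")
    return model


# ---------------------------------------------------------------------------
# transcript evidence


def _map_read(read_seq: str, model_seq: str, min_identity: float = 90.0):
    """Best local alignment of a read (either orientation) onto a model.

    Returns (s_start, s_end, per-model-position base list) or None.
    """
    best = None
    for orient, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        res = pairwise_local(seq, model_seq)
        if res is None:
            continue
        if best is None or res[0] > best[1][0]:
            best = (seq, res)
    if best is None:
        return None
    seq, (score, qb, qe, sb, se, nmatch, ncols, cols) = best
    if ncols == 0 or 100.0 * nmatch / ncols < min_identity:
        return None
    if ncols < 30:
        return None
    calls = {}
    qpos, spos = qb, sb
    for c in cols:
        if c in (COL_MATCH, COL_MISMATCH):
            calls[spos] = seq[qpos]
            qpos += 1
            spos += 1
        elif c == COL_GAP_Q:   # model base skipped by the read
            spos += 1
        else:                  # read insertion
            qpos += 1
    return sb, se, calls


def junction_support(model: GeneModel, g: Genome, reads: list[ReadRecord],
                     min_anchor_bp: int = 30,
                     min_identity: float = 90.0) -> list[dict]:
    """Count read pairs and split reads supporting each inter-piece junction.

    Reads are mapped to the spliced model (pieces concatenated in reference
    order); a split read crosses a junction with >= 20 aligned bp on each
    side, and a pair supports a junction when its mates anchor
    (>= ``min_anchor_bp``) in pieces on opposite sides.
    """
    if len(model.exon_loci) < 2:
        raise ValueError("junction support needs a model with >= 2 pieces")
    mseq = model.spliced(g)
    bounds = []
    off = 0
    for (s, e), _ in model.exon_loci[:-1]:
        off += e - s
        bounds.append(off)

    piece_of = {}
    spans = {}
    for read in reads:
        m = _map_read(read.sequence, mseq, min_identity)
        if m is None:
            continue
        sb, se, _ = m
        spans[read.id] = (sb, se)
        touched = []
        lo = 0
        for i, _ in enumerate(model.exon_loci):
            hi = bounds[i] if i < len(bounds) else len(mseq)
            if min(se, hi) - max(sb, lo) >= min_anchor_bp:
                touched.append(i)
            lo = hi
        piece_of[read.id] = touched

    out = []
    for j, b in enumerate(bounds):
        n_split = sum(1 for sb, se in spans.values()
                      if sb <= b - 20 and se >= b + 20)
        n_pairs = 0
        seen = set()
        for read in reads:
            if read.paired_with is None or read.id in seen:
                continue
            mate = read.paired_with
            seen.add(mate)
            p1 = piece_of.get(read.id)
            p2 = piece_of.get(mate)
            if not p1 or not p2:
                continue
            if (any(i <= j for i in p1) and any(i > j for i in p2)) or \
               (any(i <= j for i in p2) and any(i > j for i in p1)):
                n_pairs += 1
        rec = {"junction": j + 1, "n_pairs": n_pairs, "n_split_reads": n_split}
        if not spans:
            rec["flag"] = "low_coverage"
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# RNA editing


def predict_edit_sites(focal_cds: str, homolog_proteins: list[str],
                       feature: Feature | None = None,
                       min_score: float = 0.5,
                       aligned: bool | None = None) -> list[EditSite]:
    """Conservation-restoration scoring of candidate C-to-U sites.

    For each genomic C, the site's score is the fraction of non-gap homolog
    residues matching the residue produced by editing that C to U; a site is
    predicted when the score reaches ``min_score`` *and* the edit changes
    the encoded residue.  This is a deliberate surrogate scorer: it shares
    only the decision threshold with dedicated editing predictors.
    """
    prot = translate(focal_cds)
    if prot.endswith("*"):
        prot = prot[:-1]
    if aligned is None:
        aligned = all(len(h) == len(prot) for h in homolog_proteins)
    if not aligned:
        aln = _mafft_align([prot] + list(homolog_proteins))
        focal_aln, homolog_aln = aln[0], aln[1:]
        col_of = {}
        ci = 0
        for col, aa in enumerate(focal_aln):
            if aa != "-":
                col_of[ci] = col
                ci += 1
        homolog_col = lambda ci: [h[col_of[ci]] for h in homolog_aln]  # noqa: E731
    else:
        homolog_col = lambda ci: [h[ci] for h in homolog_proteins]  # noqa: E731

    sites = []
    for ci in range(len(prot)):
        codon = focal_cds[3 * ci:3 * ci + 3]
        for off in range(3):
            if codon[off] != "C":
                continue
            edited = codon[:off] + "T" + codon[off + 1:]
            aa_old = CODON_TABLE.get(codon)
            aa_new = CODON_TABLE.get(edited)
            if aa_new is None or aa_new in ("*",) or aa_new == aa_old:
                continue
            col = [aa for aa in homolog_col(ci) if aa != "-"]
            if not col:
                continue  # all-gap column: unscorable
            score = sum(1 for aa in col if aa == aa_new) / len(col)
            if score >= min_score:
                pos = 3 * ci + off
                if feature is not None:
                    from .simulate import _cds_pos_to_genome
                    pos = _cds_pos_to_genome(feature, pos)
                sites.append(EditSite(position=pos, codon_pos=off + 1,
                                      predicted_score=score,
                                      status="predicted_only"))
    return sites


def _mafft_align(proteins: list[str]) -> list[str]:
    with tempfile.TemporaryDirectory() as td:
        fin = Path(td) / "in.faa"
        fin.write_text("".join(f">s{i}\n{p}\n" for i, p in enumerate(proteins)))
        res = subprocess.run(["mafft", "--quiet", "--anysymbol", str(fin)],
                             capture_output=True, text=True, check=True)
        seqs = []
        for block in res.stdout.split(">")[1:]:
            lines = block.splitlines()
            seqs.append("".join(lines[1:]).upper())
        return seqs


def observe_edit_sites(g: Genome, model: GeneModel, reads: list[ReadRecord],
                       min_cov: int = 5, min_fraction: float = 0.5,
                       min_identity: float = 90.0) -> list[EditSite]:
    """Call observed C-to-U sites from mapped transcript reads.

    A site is observed when the genomic base is C on the coding strand,
    coverage >= ``min_cov`` and the T fraction >= ``min_fraction``.
    """
    mseq = model.spliced(g)
    cov = np.zeros(len(mseq), int)
    tcount = np.zeros(len(mseq), int)
    for read in reads:
        m = _map_read(read.sequence, mseq, min_identity)
        if m is None:
            continue
        _, _, calls = m
        for spos, base in calls.items():
            cov[spos] += 1
            if base == "T":
                tcount[spos] += 1
    # model position -> genome coordinate
    gmap = []
    for (s, e), strand in model.exon_loci:
        if strand == "+":
            gmap.extend(range(s, e))
        else:
            gmap.extend(range(e - 1, s - 1, -1))
    out = []
    for i, base in enumerate(mseq):
        if base != "C":
            continue
        if cov[i] >= min_cov and tcount[i] / max(1, cov[i]) >= min_fraction:
            out.append(EditSite(position=gmap[i], codon_pos=i % 3 + 1,
                                observed_fraction=float(tcount[i] / cov[i]),
                                status="observed_only"))
    return out


def merge_edit_sites(predicted: list[EditSite],
                     observed: list[EditSite]) -> list[EditSite]:
    """Partition sites into predicted_only / observed_only / both."""
    by_pos: dict[int, EditSite] = {}
    for s in predicted:
        by_pos[s.position] = EditSite(position=s.position,
                                      codon_pos=s.codon_pos,
                                      predicted_score=s.predicted_score,
                                      status="predicted_only")
    for s in observed:
        if s.position in by_pos:
            e = by_pos[s.position]
            e.observed_fraction = s.observed_fraction
            e.status = "both"
        else:
            by_pos[s.position] = s
    return sorted(by_pos.values(), key=lambda s: s.position)


def write_edit_sites_tsv(sites: list[EditSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tcodon_pos\tpredicted_score\tobserved_fraction"
                 "\tstatus\n")
        for s in sites:
            fh.write("\t".join([
                str(s.position + 1), str(s.codon_pos),
                f"{s.predicted_score:.2f}" if s.predicted_score is not None
                else "NA",
                f"{s.observed_fraction:.2f}" if s.observed_fraction is not None
                else "NA",
                s.status]) + "\n")
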