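"""Ground-truthed synthetic organelle data.

The generator emulates the statistical structure the analysis assumes: an
order-level reference phylogeny of mitogenomes evolved under Jukes-Cantor,
a recipient mitogenome carrying a standard angiosperm gene set in random
intergenic scaffold, planted dispersed repeats at controlled identity,
plastid-derived inserts (MTPT), foreign tracts copied from a donor order
(HGT), long reads spanning repeats with a controllable crossover fraction,
and paired transcript reads with C-to-U edits and a trans-spliced gene.

Design choices baked in here:

* substitution-only evolution inside genes (codon structure stays intact,
  internal stop codons are never introduced along the panel); indels exist
  only implicitly through layout differences;
* each order carries its own random intergenic scaffold, so intergenic DNA
  is homologous within an order and unrelated between orders - exactly the
  situation the order-level intergenic HGT screen relies on;
* planted repeat copies get mismatched immediate flanking bases, so copy
  boundaries are sharply defined and recoverable to the base;
* all randomness flows from ``SimConfig.seed`` through per-stage
  ``numpy.random.default_rng`` streams, making every output reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import Feature, Genome, ReadRecord, revcomp

# canonical angiosperm mitochondrial protein genes, used in declaration order
MITO_GENES = [
    "atp1", "cox1", "nad4", "ccmFc", "cob", "atp6", "nad7", "cox2",
    "matR", "rps3", "nad2", "ccmB", "atp9", "nad5", "cox3", "rps4",
    "nad9", "mttB", "rps12", "nad3",
]
RRNA_GENES = ["rrn18", "rrn26"]
PLASTID_GENES = ["rbcL", "psbA", "psbB", "ndhB", "matK"]

STOP_CODONS = {"TAA", "TAG", "TGA"}

CODON_TABLE = {}


def _build_codon_table():
    from Bio.Data.CodonTable import unambiguous_dna_by_id
    t = unambiguous_dna_by_id[1]  # plant mitochondria use the standard code
    for codon, aa in t.forward_table.items():
        CODON_TABLE[codon] = aa
    for codon in t.stop_codons:
        CODON_TABLE[codon] = "*"


_build_codon_table()


def translate(cds: str) -> str:
    return "".join(CODON_TABLE.get(cds[i:i + 3], "X")
                   for i in range(0, len(cds) - len(cds) % 3, 3))


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``repeat_spec`` entries are (length_bp, identity_percent, n_copies) with
    an optional fourth element ``"inverted"``.  ``mtpt_spec`` entries are
    (donor, length_bp) with donor one of {"self_plastome",
    "foreign_plastome"}.  ``hgt_spec`` entries are (donor_order, length_bp,
    contains_gene).
    """

    seed: int = 0
    n_orders: int = 4
    taxa_per_order: int = 2
    subst_rate_per_branch: float = 0.05
    genome_length_bp: int = 12_000
    repeat_spec: list = field(default_factory=list)
    mtpt_spec: list = field(default_factory=list)
    hgt_spec: list = field(default_factory=list)
    recomb_fraction: float = 0.0
    long_read_length_mean: int = 2_000
    long_read_error: float = 0.03
    transcript_edit_sites: list = field(default_factory=list)
    transsplice_gene: str | None = None

    # generator composition (defaults are the package's study conditions)
    n_genes: int = 10
    gene_length_codons: tuple = (100, 250)
    include_rrn: bool = True
    include_outgroup: bool = True
    focal_order: str = "Order_1"
    n_focal_taxa: int = 2
    missing_genes: list = field(default_factory=list)
    nuclear_copy_spec: list = field(default_factory=list)  # (gene, ident%, intact)
    own_plastome_missing_genes: list = field(default_factory=list)
    n_edit_sites: int = 0
    edit_gene: str | None = None
    n_long_reads: int = 0
    spanning_reads_per_repeat: int = 0
    long_read_anchor_bp: int = 150
    transcript_depth: int = 30
    transcript_read_len: int = 100
    transcript_insert: int = 260
    transcript_error: float = 0.005
    plastome_length_bp: int = 6_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.recomb_fraction <= 1.0:
            raise ValueError("recomb_fraction must lie in [0, 1]")
        for name in ("genome_length_bp", "long_read_length_mean",
                     "plastome_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TruthSet:
    """Everything that was planted, for recovery checks."""

    planted_repeats: list = field(default_factory=list)      # Feature per copy
    repeat_pairs: list = field(default_factory=list)         # dicts per pair
    planted_mtpts: list = field(default_factory=list)        # Feature (+donor)
    planted_hgt: list = field(default_factory=list)          # Feature (+donor_order)
    true_recomb_fraction: dict = field(default_factory=dict)
    true_edit_sites: list = field(default_factory=list)      # genome positions
    true_transsplice_layout: dict | None = None
    gene_features: list = field(default_factory=list)
    missing_genes: list = field(default_factory=list)
    focal_gene_sequences: dict = field(default_factory=dict)  # taxon -> gene -> CDS
    hgt_genes: dict = field(default_factory=dict)             # gene -> donor order
    nuclear_copies: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# random-sequence and evolution primitives

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


def _rand_dna(rng, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _rand_cds(rng, n_codons: int) -> str:
    codons = []
    while len(codons) < n_codons - 2:
        c = _rand_dna(rng, 3)
        if c not in STOP_CODONS:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def jc_diff_probability(rate: float) -> float:
    """Probability a site differs after `rate` expected substitutions/site."""
    return 0.75 * (1.0 - math.exp(-4.0 * rate / 3.0))


def _substitute(seq: str, positions, rng) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for p in positions:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


def evolve(seq: str, rate: float, rng) -> str:
    """One Jukes-Cantor branch: per-site substitution to a uniform other base."""
    p = jc_diff_probability(rate)
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    return _substitute(seq, hits, rng)


def evolve_cds(seq: str, rate: float, rng) -> str:
    """JC branch constrained to keep the reading frame stop-free.

    Substitutions that would create an internal stop codon are re-drawn
    (and dropped if no non-stop alternative exists); the terminal stop
    codon is left untouched.
    """
    p = jc_diff_probability(rate)
    arr = bytearray(seq.encode())
    n = len(seq) - 3  # protect the terminal stop
    hits = np.nonzero(rng.random(n) < p)[0]
    for pos in hits:
        old = arr[pos]
        alts = [b for b in b"ACGT" if b != old]
        rng.shuffle(alts)
        for b in alts:
            arr[pos] = b
            c0 = 3 * (pos // 3)
            codon = arr[c0:c0 + 3].decode()
            if codon not in STOP_CODONS:
                break
        else:
            arr[pos] = old
    return arr.decode()


def mutate_to_identity(seq: str, identity_percent: float, rng,
                       protect_frame: bool = False) -> str:
    """Substitute an exact count of positions to hit a target identity."""
    n = len(seq)
    k = int(round(n * (100.0 - identity_percent) / 100.0))
    if k == 0:
        return seq
    if not protect_frame:
        pos = rng.choice(n, size=k, replace=False)
        return _substitute(seq, pos, rng)
    arr = bytearray(seq.encode())
    candidates = list(rng.permutation(max(0, n - 3)))
    changed = 0
    for pos in candidates:
        if changed >= k:
            break
        old = arr[pos]
        alts = [b for b in b"ACGT" if b != old]
        rng.shuffle(alts)
        for b in alts:
            arr[pos] = b
            c0 = 3 * (pos // 3)
            if arr[c0:c0 + 3].decode() not in STOP_CODONS:
                changed += 1
                break
        else:
            arr[pos] = old
    return arr.decode()


# ---------------------------------------------------------------------------
# reference panel

@dataclass
class ReferencePanel:
    """Order-labelled reference phylogeny plus per-taxon gene sets.

    ``gene_sequences[taxon][gene]`` are leaf CDS/rRNA sequences.  The panel
    also keeps the ancestral sequences and per-order intergenic scaffolds
    needed to graft a recipient lineage and to assemble full reference
    mitogenomes and plastomes for the screening stages.
    """

    cfg: SimConfig
    newick: str
    taxa: list
    orders: list
    order_of: dict
    gene_order: list                    # [(gene, strand), ...] shared layout
    gene_types: dict                    # gene -> "CDS" | "rRNA"
    gene_sequences: dict                # taxon -> gene -> seq
    midpoint_sequences: dict            # order -> gene -> seq (taxon_1 midpoint)
    order_scaffold: dict                # order -> scaffold DNA
    taxon_scaffold: dict                # taxon -> scaffold DNA
    plastome_genes: dict                # order -> gene -> seq
    plastome_scaffold: dict             # order -> DNA
    provenance: dict

    def ref_mitogenome(self, taxon: str) -> Genome:
        g, _ = _assemble(f"{taxon}|mito", self.gene_order, self.gene_types,
                         self.gene_sequences[taxon], self.taxon_scaffold[taxon],
                         self.cfg.genome_length_bp)
        return g

    def plastome(self, order: str, missing: list | None = None,
                 label: str | None = None) -> Genome:
        genes = {g: s for g, s in self.plastome_genes[order].items()
                 if g not in (missing or [])}
        order_list = [(g, "+") for g in PLASTID_GENES if g in genes]
        types = {g: "CDS" for g in genes}
        g, _ = _assemble(label or f"{order}|plastome", order_list, types, genes,
                         self.plastome_scaffold[order],
                         self.cfg.plastome_length_bp)
        return g


def _spacer_lengths(spacer_total, n_spacers, slots, rng):
    """Split intergenic length into spacers, reserving room for plants.

    Each entry of ``slots`` is the length of a tract that must later fit
    inside a single spacer; oversized spacers are positioned by ``rng``.
    """
    min_sp = 20
    if not slots:
        base = spacer_total // n_spacers
        lens = [base] * n_spacers
        lens[-1] += spacer_total - base * n_spacers
        return lens
    need = [L + 80 for L in slots]
    if sum(need) + n_spacers * min_sp > spacer_total:
        raise ValueError("requested insertions exceed genome length")
    lens = [min_sp] * n_spacers
    idxs = (list(rng.permutation(n_spacers)) if rng is not None
            else list(range(n_spacers)))
    for i, nd in enumerate(sorted(need, reverse=True)):
        lens[idxs[i % n_spacers]] += nd
    leftover = spacer_total - sum(lens)
    per = leftover // n_spacers
    lens = [x + per for x in lens]
    lens[-1] += spacer_total - sum(lens)
    return lens


def _assemble(gid, gene_order, gene_types, gene_seqs, scaffold, total_len,
              circular=False, slots=None, rng=None):
    """Interleave genes with scaffold spacers into a Genome + features.

    Spacer content is consumed sequentially from the scaffold so that
    intergenic homology is preserved across taxa sharing a scaffold lineage.
    """
    present = [(g, s) for g, s in gene_order if g in gene_seqs]
    gene_total = sum(len(gene_seqs[g]) for g, _ in present)
    n_spacers = len(present) + 1
    spacer_total = total_len - gene_total
    if spacer_total < n_spacers * 20:
        raise ValueError("genome_length_bp too small for the configured genes")
    lens = _spacer_lengths(spacer_total, n_spacers, slots or [], rng)
    while len(scaffold) < spacer_total:
        scaffold = scaffold + scaffold  # degenerate safety; normally ample
    parts = []
    feats = []
    pos = 0
    off = 0
    for i, (g, strand) in enumerate(present):
        parts.append(scaffold[off:off + lens[i]])
        off += lens[i]
        pos += lens[i]
        seq = gene_seqs[g]
        placed = revcomp(seq) if strand == "-" else seq
        ftype = gene_types.get(g, "CDS")
        feats.append(Feature(gene=g, type=ftype,
                             intervals=[(pos, pos + len(seq))], strand=strand))
        parts.append(placed)
        pos += len(seq)
    parts.append(scaffold[off:off + lens[-1]])
    genome = Genome(id=gid, sequence="".join(parts), circular=circular)
    return genome, feats


def simulate_reference_set(cfg: SimConfig) -> ReferencePanel:
    """Evolve a root gene set along an order-level tree (Jukes-Cantor).

    The same topology is used for every gene - the panel itself contains no
    horizontal transfer.  Taxa are labelled ``Order_k|taxon_j``; an optional
    outgroup taxon ``Outgroup|taxon_1`` attaches at the root.
    """
    if cfg.n_orders < 3:
        raise ValueError("n_orders must be >= 3")
    if cfg.taxa_per_order < 1:
        raise ValueError("taxa_per_order must be >= 1")
    rng = _rng(cfg.seed, 1)
    r = cfg.subst_rate_per_branch
    prov = {"seed": cfg.seed, "warnings": []}
    # total root-to-distant-leaf divergence 4r between orders
    if jc_diff_probability(4 * r) > 0.5:
        msg = "branch rates imply expected identity < 50% between orders"
        warnings.warn(msg)
        prov["warnings"].append(msg)

    genes = list(MITO_GENES[:cfg.n_genes])
    gene_types = {g: "CDS" for g in genes}
    if cfg.include_rrn:
        for g in RRNA_GENES:
            genes.append(g)
            gene_types[g] = "rRNA"

    root = {}
    for g in genes:
        if gene_types[g] == "CDS":
            n_codons = int(rng.integers(*cfg.gene_length_codons))
            root[g] = _rand_cds(rng, n_codons)
        else:
            root[g] = _rand_dna(rng, int(rng.integers(800, 1200)))

    def branch(seqs, rate):
        return {g: (evolve_cds(s, rate, rng) if gene_types[g] == "CDS"
                    else evolve(s, rate, rng)) for g, s in seqs.items()}

    orders = [f"Order_{k + 1}" for k in range(cfg.n_orders)]
    gene_sequences = {}
    midpoint_sequences = {}
    order_of = {}
    taxa = []
    clades = []
    for order in orders:
        anc = branch(root, r)
        # taxon_1 passes through a recorded midpoint so a recipient lineage
        # can later be grafted as its sister
        mid = branch(anc, r / 2)
        midpoint_sequences[order] = mid
        names = [f"{order}|taxon_{j + 1}" for j in range(cfg.taxa_per_order)]
        tips = []
        for j, name in enumerate(names):
            if j == 0:
                gene_sequences[name] = branch(mid, r / 2)
            else:
                gene_sequences[name] = branch(anc, r)
            order_of[name] = order
            taxa.append(name)
            tips.append(f"{name}:{r:g}")
        if len(tips) == 1:
            clades.append(tips[0])
        else:
            clades.append(f"({','.join(tips)}):{r:g}")
    if cfg.include_outgroup:
        name = "Outgroup|taxon_1"
        gene_sequences[name] = branch(root, 2 * r)
        order_of[name] = "Outgroup"
        taxa.append(name)
        clades.append(f"{name}:{2 * r:g}")
    newick = f"({','.join(clades)});"

    # shared mitogenome layout: gene order and strands drawn once
    layout_genes = list(genes)
    rng.shuffle(layout_genes)
    gene_order = [(g, "+" if rng.random() < 0.5 else "-") for g in layout_genes]

    order_scaffold = {o: _rand_dna(rng, cfg.genome_length_bp) for o in orders}
    order_scaffold["Outgroup"] = _rand_dna(rng, cfg.genome_length_bp)
    taxon_scaffold = {}
    for t in taxa:
        o = order_of[t]
        taxon_scaffold[t] = evolve(order_scaffold[o], r / 2, rng)

    # plastid panel: one plastome lineage per order
    plast_root = {g: _rand_cds(rng, int(rng.integers(150, 350)))
                  for g in PLASTID_GENES}
    plastome_genes = {}
    plastome_scaffold = {}
    for o in orders:
        plastome_genes[o] = {g: evolve_cds(s, r, rng)
                             for g, s in plast_root.items()}
        plastome_scaffold[o] = _rand_dna(rng, cfg.plastome_length_bp)

    return ReferencePanel(
        cfg=cfg, newick=newick, taxa=taxa, orders=orders, order_of=order_of,
        gene_order=gene_order, gene_types=gene_types,
        gene_sequences=gene_sequences, midpoint_sequences=midpoint_sequences,
        order_scaffold=order_scaffold, taxon_scaffold=taxon_scaffold,
        plastome_genes=plastome_genes, plastome_scaffold=plastome_scaffold,
        provenance=prov)


# ---------------------------------------------------------------------------
# recipient genome


def _cds_pos_to_genome(feat: Feature, c: int) -> int:
    """Map a 0-based coding-strand CDS offset to a genome coordinate."""
    lengths = [e - s for s, e in feat.intervals]
    if feat.strand == "+":
        for (s, e), L in zip(feat.intervals, lengths):
            if c < L:
                return s + c
            c -= L
    else:
        for (s, e), L in zip(reversed(feat.intervals),
                             reversed(lengths)) if feat.qualifiers.get("trans") != "yes" \
                else zip(feat.intervals, lengths):
            if c < L:
                return e - 1 - c
            c -= L
    raise IndexError("CDS offset beyond feature")


def build_recipient_genome(cfg: SimConfig,
                           panel: ReferencePanel) -> tuple[Genome, TruthSet]:
    """Assemble the focal (recipient) mitogenome and record all planted truth.

    The recipient lineage grafts as sister to ``focal_order|taxon_1``; genes
    listed in ``hgt_spec`` with ``contains_gene`` instead descend from the
    donor order (an ancestral transfer shared by all focal taxa).  Repeats,
    MTPT inserts and gene-free HGT tracts replace intergenic scaffold
    segments, so the configured genome length is preserved exactly.
    """
    rng = _rng(cfg.seed, 2)
    r = cfg.subst_rate_per_branch
    truth = TruthSet(missing_genes=list(cfg.missing_genes),
                     provenance={"seed": cfg.seed, "config": repr(cfg)})

    focal = cfg.focal_order
    if focal not in panel.orders:
        raise ValueError(f"focal order {focal!r} not in panel")
    known = set(panel.gene_types)
    for name, genes in (("missing_genes", cfg.missing_genes),
                        ("nuclear_copy_spec", [e[0] for e in cfg.nuclear_copy_spec])):
        unknown = [g for g in genes if g not in known]
        if unknown:
            raise ValueError(f"{name} references genes not in the panel: "
                             f"{unknown}")
    mid = panel.midpoint_sequences[focal]

    # ancestral recipient gene set, with per-gene HGT replacement
    hgt_gene_assignments = {}
    gene_hgt_entries = [e for e in cfg.hgt_spec if len(e) >= 3 and e[2]]
    cds_genes = [g for g, t in panel.gene_types.items() if t == "CDS"]
    for donor_order, length_bp, _ in gene_hgt_entries:
        if donor_order not in panel.orders or donor_order == focal:
            raise ValueError(f"bad HGT donor order {donor_order!r}")
        free = [g for g in cds_genes
                if g not in hgt_gene_assignments
                and g != cfg.transsplice_gene and g not in cfg.missing_genes]
        gene = min(free, key=lambda g: abs(len(mid[g]) - length_bp))
        hgt_gene_assignments[gene] = donor_order
    truth.hgt_genes = dict(hgt_gene_assignments)

    def recip_branch(source, rate):
        return {g: (evolve_cds(s, rate, rng)
                    if panel.gene_types[g] == "CDS" else evolve(s, rate, rng))
                for g, s in source.items()}

    anc_sources = {}
    for g in panel.gene_types:
        if g in hgt_gene_assignments:
            anc_sources[g] = panel.midpoint_sequences[hgt_gene_assignments[g]][g]
        else:
            anc_sources[g] = mid[g]
    recip_anc = recip_branch(anc_sources, r / 4)

    focal_taxa = [f"Focal|sp{j + 1}" for j in range(cfg.n_focal_taxa)]
    for t in focal_taxa:
        truth.focal_gene_sequences[t] = recip_branch(recip_anc, r / 4)
    recipient_genes = dict(truth.focal_gene_sequences[focal_taxa[0]])

    for g in cfg.missing_genes:
        recipient_genes.pop(g, None)

    # --- RNA edit sites: plant pre-edited (genomic C) codons --------------
    edit_gene = cfg.edit_gene
    if cfg.n_edit_sites and edit_gene is None:
        edit_gene = next(g for g in cds_genes if g in recipient_genes
                         and g != cfg.transsplice_gene)
    edit_cds_positions = []
    if cfg.n_edit_sites:
        cds = bytearray(recipient_genes[edit_gene].encode())
        panel_prot = [translate(panel.gene_sequences[t][edit_gene])
                      for t in panel.taxa]
        candidates = []
        for ci in range(1, len(cds) // 3 - 1):
            codon = cds[3 * ci:3 * ci + 3].decode()
            aa = CODON_TABLE.get(codon)
            if len({p[ci] for p in panel_prot}) != 1 or panel_prot[0][ci] != aa:
                continue
            for off in range(3):
                if codon[off] != "T":
                    continue
                pre = codon[:off] + "C" + codon[off + 1:]
                if pre in STOP_CODONS:
                    continue
                if CODON_TABLE[pre] == aa:
                    continue  # the edit must change the residue
                candidates.append((3 * ci + off, pre, ci))
                break
        rng.shuffle(candidates)
        for pos, pre, ci in candidates[:cfg.n_edit_sites]:
            cds[3 * ci:3 * ci + 3] = pre.encode()
            edit_cds_positions.append(pos)
        if len(edit_cds_positions) < cfg.n_edit_sites:
            warnings.warn("fewer conserved codons than requested edit sites")
        recipient_genes[edit_gene] = cds.decode()
        edit_cds_positions.sort()

    # --- trans-splice layout: split one gene into three loci --------------
    ts_pieces = {}
    layout = [(g, s) for g, s in panel.gene_order if g in recipient_genes]
    if cfg.transsplice_gene:
        tg = cfg.transsplice_gene
        if tg not in recipient_genes:
            raise ValueError(f"trans-splice gene {tg!r} not present")
        cds = recipient_genes.pop(tg)
        if len(cds) < 240:
            raise ValueError("trans-splice gene too short to split")
        third = len(cds) // 3 // 3 * 3
        a_end = 2 * third          # exon1a: large 5' portion of exon 1
        b_end = a_end + max(60, third // 2) // 3 * 3  # exon1b: 3' end of exon 1
        ts_pieces = {f"{tg}_x1a": cds[:a_end],
                     f"{tg}_x1b": cds[a_end:b_end],
                     f"{tg}_x2": cds[b_end:]}
        recipient_genes.update(ts_pieces)
        idx = next(i for i, (g, _) in enumerate(layout) if g == tg)
        strand = layout[idx][1]
        layout[idx] = (f"{tg}_x1a", strand)
        # remotely located pieces; the last one on the opposite strand
        layout.insert(min(idx + max(3, len(layout) // 2), len(layout)),
                      (f"{tg}_x1b", strand))
        layout.append((f"{tg}_x2", "-" if strand == "+" else "+"))

    gtypes = dict(panel.gene_types)
    for piece in ts_pieces:
        gtypes[piece] = "CDS"

    plant_slots = []
    for entry in cfg.repeat_spec:
        plant_slots += [entry[0]] * entry[2]
    plant_slots += [L for _, L in cfg.mtpt_spec]
    plant_slots += [e[1] for e in cfg.hgt_spec if not (len(e) >= 3 and e[2])]

    genome, feats = _assemble("recipient|mito", layout, gtypes,
                              recipient_genes,
                              evolve(panel.order_scaffold[focal], r / 2, rng),
                              cfg.genome_length_bp, circular=False,
                              slots=plant_slots, rng=rng)
    seq = bytearray(genome.sequence.encode())
    feat_by_gene = {f.gene: f for f in feats}

    # free spacer intervals available for planting; keep plants clear of the
    # genome ends so flanking anchors always exist for long reads
    edge = 400
    spacers = []
    prev = 0
    for f in sorted(feats, key=lambda f: f.start):
        if f.start - prev > 0:
            spacers.append([max(prev, edge), min(f.start, len(seq) - edge)])
        prev = f.end
    if len(seq) - prev > 0:
        spacers.append([max(prev, edge), len(seq) - edge])
    spacers = [s for s in spacers if s[1] - s[0] > 0]

    def carve(length, margin=30):
        """Take a [start, end) slot out of the best-fitting free spacer."""
        fits = [i for i, (a, b) in enumerate(spacers)
                if b - a >= length + 2 * margin]
        if not fits:
            raise ValueError(
                f"requested insertions exceed available intergenic space "
                f"({length} bp needed)")
        i = min(fits, key=lambda j: spacers[j][1] - spacers[j][0])
        a, b = spacers[i]
        start = int(rng.integers(a + margin, b - margin - length + 1))
        spacers.pop(i)
        if start - a >= 60:
            spacers.append([a, start])
        if b - (start + length) >= 60:
            spacers.append([start + length, b])
        return start

    # --- dispersed repeats -------------------------------------------------
    for ri, entry in enumerate(cfg.repeat_spec):
        L, ident, ncopies = entry[0], entry[1], entry[2]
        inverted = len(entry) > 3 and entry[3] == "inverted"
        source = _rand_dna(rng, L)
        copies = []
        for ci in range(ncopies):
            cseq = source if ci == 0 else mutate_to_identity(source, ident, rng)
            if inverted and ci > 0:
                cseq = revcomp(cseq)
            start = carve(L)
            seq[start:start + L] = cseq.encode()
            copies.append((start, start + L))
        # sharpen copy boundaries: the immediately flanking bases must differ
        # between copies (orientation-aware, so alignments cannot extend past
        # the planted edges by chance)
        comp = dict(zip(b"ACGT", b"TGCA"))

        def _fix(pos, forbidden):
            if seq[pos] in forbidden:
                seq[pos] = next(x for x in b"ACGT" if x not in forbidden)

        # three mismatched bases per edge: a single mismatch is cheaper than
        # a short chance-match run, so alignments could still creep past it
        for j in range(1, len(copies)):
            sj, ej = copies[j]
            for t in range(3):
                left_forbid, right_forbid = set(), set()
                for i in range(j):
                    si, ei = copies[i]
                    pair_inverted = inverted and (i == 0) != (j == 0)
                    if not pair_inverted:
                        left_forbid.add(seq[si - 1 - t])
                        right_forbid.add(seq[ei + t])
                    else:
                        # copy i's left flank aligns to the complement of
                        # copy j's right flank, and vice versa
                        right_forbid.add(comp[seq[si - 1 - t]])
                        left_forbid.add(comp[seq[ei + t]])
                _fix(sj - 1 - t, left_forbid)
                _fix(ej + t, right_forbid)
        rid = f"rep{ri + 1}"
        for ci, (s, e) in enumerate(copies):
            f = Feature(gene=f"{rid}_copy{chr(97 + ci)}", type="repeat",
                        intervals=[(s, e)],
                        strand="-" if (inverted and ci > 0) else "+",
                        qualifiers={"repeat_id": rid,
                                    "identity": f"{ident:g}"})
            truth.planted_repeats.append(f)
        truth.repeat_pairs.append({
            "id": rid, "copies": copies, "length_bp": L,
            "identity_percent": float(ident),
            "strand_relation": "inverted" if inverted else "direct"})
        truth.true_recomb_fraction[rid] = cfg.recomb_fraction

    # --- MTPT inserts ------------------------------------------------------
    own_plastome = panel.plastome(focal, missing=cfg.own_plastome_missing_genes,
                                  label="recipient|plastome")
    for mi, (donor, L) in enumerate(cfg.mtpt_spec):
        if donor == "self_plastome":
            src_genome = own_plastome
            donor_label = "self_plastome"
        elif donor == "foreign_plastome":
            donor_order = panel.orders[-1]
            src_genome = panel.plastome(donor_order)
            donor_label = f"foreign_plastome:{donor_order}"
        else:
            raise ValueError(f"unknown MTPT donor {donor!r}")
        off = int(rng.integers(0, len(src_genome) - L))
        tract = src_genome.sequence[off:off + L]
        tract = mutate_to_identity(tract, 98.0, rng)
        start = carve(L)
        seq[start:start + L] = tract.encode()
        truth.planted_mtpts.append(Feature(
            gene=f"mtpt{mi + 1}", type="other", intervals=[(start, start + L)],
            strand="+", qualifiers={"donor": donor_label,
                                    "source_offset": str(off)}))

    # --- gene-free HGT tracts ---------------------------------------------
    for hi, entry in enumerate(e for e in cfg.hgt_spec
                               if not (len(e) >= 3 and e[2])):
        donor_order, L = entry[0], entry[1]
        if donor_order not in panel.orders or donor_order == focal:
            raise ValueError(f"bad HGT donor order {donor_order!r}")
        donor_taxon = f"{donor_order}|taxon_1"
        dg = panel.ref_mitogenome(donor_taxon)
        dfeats = sorted(_features_of_ref(panel, donor_taxon),
                        key=lambda f: f.start)
        dspacers = []
        prev = 0
        for f in dfeats:
            if f.start - prev >= L + 20:
                dspacers.append((prev, f.start))
            prev = f.end
        if len(dg) - prev >= L + 20:
            dspacers.append((prev, len(dg)))
        if not dspacers:
            raise ValueError("no donor intergenic tract long enough")
        a, b = dspacers[int(rng.integers(len(dspacers)))]
        off = int(rng.integers(a, b - L + 1))
        tract = mutate_to_identity(dg.sequence[off:off + L], 98.0, rng)
        start = carve(L)
        seq[start:start + L] = tract.encode()
        truth.planted_hgt.append(Feature(
            gene=f"hgt{hi + 1}", type="other", intervals=[(start, start + L)],
            strand="+", qualifiers={"donor_order": donor_order,
                                    "contains_gene": "no"}))

    genome = Genome(id=genome.id, sequence=seq.decode(), circular=False)

    # genic HGT tracts are the gene intervals themselves
    for gene, donor_order in hgt_gene_assignments.items():
        if gene in feat_by_gene:
            f = feat_by_gene[gene]
            truth.planted_hgt.append(Feature(
                gene=f"hgt_{gene}", type="other", intervals=list(f.intervals),
                strand=f.strand, qualifiers={"donor_order": donor_order,
                                             "contains_gene": "yes"}))

    truth.gene_features = feats
    if cfg.transsplice_gene:
        tg = cfg.transsplice_gene
        pieces = [feat_by_gene[f"{tg}_x1a"], feat_by_gene[f"{tg}_x1b"],
                  feat_by_gene[f"{tg}_x2"]]
        truth.true_transsplice_layout = {
            "gene": tg,
            "pieces": [(p.gene, p.intervals[0], p.strand) for p in pieces],
            "mature_pieces": [f"{tg}_x1b", f"{tg}_x2"],
            "orphan_piece": f"{tg}_x1a",
        }
    if edit_cds_positions:
        ef = feat_by_gene[edit_gene]
        for c in edit_cds_positions:
            gpos = _cds_pos_to_genome(ef, c)
            truth.true_edit_sites.append(gpos)
        truth.provenance["edit_gene"] = edit_gene
        truth.provenance["edit_cds_positions"] = list(edit_cds_positions)
    return genome, truth


def _features_of_ref(panel: ReferencePanel, taxon: str) -> list[Feature]:
    _, feats = _assemble(f"{taxon}|mito", panel.gene_order, panel.gene_types,
                         panel.gene_sequences[taxon],
                         panel.taxon_scaffold[taxon],
                         panel.cfg.genome_length_bp)
    return feats


def simulate_nuclear_genome(cfg: SimConfig, panel: ReferencePanel,
                            truth: TruthSet) -> Genome:
    """A nuclear contig carrying diverged copies of configured genes.

    ``nuclear_copy_spec`` entries are (gene, identity_percent, intact); a
    non-intact copy gets an internal stop codon planted mid-gene.
    """
    rng = _rng(cfg.seed, 3)
    mid = panel.midpoint_sequences[cfg.focal_order]
    n = max(20_000, cfg.genome_length_bp)
    seq = bytearray(_rand_dna(rng, n).encode())
    pos = 1_000
    for gene, ident, intact in cfg.nuclear_copy_spec:
        src = mid[gene]
        copy = mutate_to_identity(src, ident, rng, protect_frame=True)
        if not intact:
            c = len(copy) // 2 // 3 * 3
            copy = copy[:c] + "TAA" + copy[c + 3:]
        seq[pos:pos + len(copy)] = copy.encode()
        truth.nuclear_copies.append({
            "gene": gene, "start": pos, "end": pos + len(copy),
            "identity_percent": float(ident), "intact": bool(intact)})
        pos += len(copy) + 2_000
        if pos > n - 3_000:
            raise ValueError("nuclear contig too small for configured copies")
    return Genome(id="recipient|nuclear", sequence=seq.decode())


# ---------------------------------------------------------------------------
# long reads


def simulate_long_reads(g: Genome, truth: TruthSet,
                        cfg: SimConfig) -> list[ReadRecord]:
    """Long reads with controllable repeat-crossover fraction.

    Reads that fully span a planted repeat copy plus ``long_read_anchor_bp``
    on both sides become, with probability ``recomb_fraction``, crossover
    products: the left flank and repeat prefix come from one copy, the
    remainder continues from the other copy's genomic context.  Truth labels
    are stored in the read id (``phase=AA/AB/BA/BB`` and crossover offset).
    """
    rng = _rng(cfg.seed, 4)
    anchor = cfg.long_read_anchor_bp
    pairs = [p for p in truth.repeat_pairs
             if p["strand_relation"] == "direct" and len(p["copies"]) == 2]
    if cfg.recomb_fraction > 0 and not any(
            p["length_bp"] >= 500 for p in pairs):
        warnings.warn("recomb_fraction > 0 with no >=500 bp direct repeat")
    reads: list[ReadRecord] = []

    def emit(start, length, idx):
        end = min(start + length, len(g))
        start = max(0, start)
        if end - start < 200:
            return
        # does this read span a repeat copy with anchors on both sides?
        phase = "-"
        rid = "-"
        xo = -1
        raw = None
        for p in pairs:
            for ci, (cs, ce) in enumerate(p["copies"]):
                if start <= cs - anchor and end >= ce + anchor:
                    rid = p["id"]
                    other = p["copies"][1 - ci]
                    me, ot = "AB"[ci], "AB"[1 - ci]
                    if rng.random() < cfg.recomb_fraction:
                        xo = int(rng.integers(1, p["length_bp"]))
                        left = g.sequence[start:cs + xo]
                        rem = end - (cs + xo)
                        o_from = other[0] + xo
                        right = g.sequence[o_from:o_from + rem]
                        raw = left + right
                        phase = me + ot
                    else:
                        phase = me + me
                    break
            if phase != "-":
                break
        if raw is None:
            raw = g.sequence[start:end]
        if len(raw) < 200:
            return
        err = np.nonzero(rng.random(len(raw)) < cfg.long_read_error)[0]
        raw = _substitute(raw, err, rng)
        name = f"lr{idx}|repeat={rid}|phase={phase}|xo={xo}"
        reads.append(ReadRecord(id=name, sequence=raw))

    idx = 0
    for _ in range(cfg.n_long_reads):
        L = max(300, int(rng.normal(cfg.long_read_length_mean,
                                    0.1 * cfg.long_read_length_mean)))
        start = int(rng.integers(0, max(1, len(g) - 200)))
        emit(start, L, idx)
        idx += 1
    for p in pairs:
        need = max(0, p["length_bp"] + 2 * anchor + 100)
        for ci, (cs, ce) in enumerate(p["copies"]):
            for _ in range(cfg.spanning_reads_per_repeat // max(1, len(p["copies"]))):
                L = max(need + 100,
                        int(rng.normal(cfg.long_read_length_mean,
                                       0.1 * cfg.long_read_length_mean)))
                lo = max(0, ce + anchor - L)
                hi = cs - anchor
                if hi <= lo:
                    warnings.warn(f"repeat {p['id']} unassessable: reads too "
                                  "short for repeat plus anchors")
                    continue
                start = int(rng.integers(lo, hi + 1))
                emit(start, L, idx)
                idx += 1
    return reads


# ---------------------------------------------------------------------------
# transcript reads


def simulate_transcript_reads(g: Genome, truth: TruthSet,
                              cfg: SimConfig) -> list[ReadRecord]:
    """Paired mRNA reads: mature spliced transcripts with C->T edits.

    For the trans-spliced gene the mature transcript joins the 3' piece of
    exon 1 to exon 2; the orphan 5' portion of exon 1 is transcribed as a
    separate unit, so no fragment ever bridges the two portions of exon 1.
    """
    rng = _rng(cfg.seed, 5)
    edit_positions = set(truth.true_edit_sites) | set(cfg.transcript_edit_sites)
    feats = {f.gene: f for f in truth.gene_features}
    for gpos in edit_positions:
        owner = next((f for f in truth.gene_features
                      if any(s <= gpos < e for s, e in f.intervals)), None)
        if owner is None:
            raise ValueError(f"edit site {gpos} outside every gene")
        base = g.sequence[gpos]
        coding = base if owner.strand == "+" else revcomp(base)
        if coding != "C":
            raise ValueError(f"edit site {gpos} is not a C on the coding strand")

    units: list[tuple[str, str, list[tuple[str, int, int, str]]]] = []

    def unit_of(piece_names, label):
        segs = []
        for name in piece_names:
            f = feats[name]
            s, e = f.intervals[0]
            segs.append((name, s, e, f.strand))
        tx = ""
        for name, s, e, strand in segs:
            part = g.sequence[s:e]
            tx += revcomp(part) if strand == "-" else part
        # apply C->T edits in transcript coordinates
        tlist = list(tx)
        off = 0
        for name, s, e, strand in segs:
            L = e - s
            for gpos in edit_positions:
                if s <= gpos < e:
                    tpos = off + (gpos - s if strand == "+" else e - 1 - gpos)
                    if tlist[tpos] == "C":
                        tlist[tpos] = "T"
            off += L
        units.append((label, "".join(tlist), segs))

    ts = truth.true_transsplice_layout
    skip = set()
    if ts:
        unit_of(ts["mature_pieces"], f"{ts['gene']}|mature")
        unit_of([ts["orphan_piece"]], f"{ts['gene']}|orphan")
        skip = {name for name, _, _ in
                [(p[0], 0, 0) for p in ts["pieces"]]}
    for f in truth.gene_features:
        if f.type != "CDS" or f.gene in skip:
            continue
        unit_of([f.gene], f.gene)

    reads: list[ReadRecord] = []
    rl = cfg.transcript_read_len
    idx = 0
    for label, tx, _ in units:
        if len(tx) < rl + 10:
            continue
        n_frags = max(1, cfg.transcript_depth * len(tx) // (2 * rl))
        hi = min(len(tx), cfg.transcript_insert + 50)
        lo = min(rl, hi)
        for _ in range(n_frags):
            ins = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, len(tx) - ins + 1))
            frag = tx[start:start + ins]
            r1 = frag[:rl]
            r2 = revcomp(frag[-rl:])
            e1 = np.nonzero(rng.random(len(r1)) < cfg.transcript_error)[0]
            e2 = np.nonzero(rng.random(len(r2)) < cfg.transcript_error)[0]
            r1 = _substitute(r1, e1, rng)
            r2 = _substitute(r2, e2, rng)
            n1 = f"tr{idx}|{label}/1"
            n2 = f"tr{idx}|{label}/2"
            reads.append(ReadRecord(id=n1, sequence=r1, paired_with=n2))
            reads.append(ReadRecord(id=n2, sequence=r2, paired_with=n1))
            idx += 1
    return reads
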