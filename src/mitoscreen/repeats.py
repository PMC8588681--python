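"""Dispersed and tandem repeat detection, and the long-read recombination proxy.

Dispersed repeats come from a self-search of the genome (trivial self-hit
removed, symmetric duplicates collapsed).  Recombinational activity across a
long repeat is estimated from long reads that span the full repeat plus an
anchor on both sides: each flank is phased to the repeat copy it matches
best, and the fraction of spanning reads whose two flanks phase to
*different* copies is the crossover (activity) estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import Feature, Genome, ReadRecord, revcomp
from .search import Hit, SearchParams, encode, local_search, pairwise_local


@dataclass
class RepeatPair:
    """Two copies of a dispersed repeat within one genome."""

    repeat_id: str
    copy_a: tuple[int, int]
    copy_b: tuple[int, int]
    length_bp: int
    identity_percent: float
    strand_relation: str  # "direct" | "inverted"

    def intervals(self) -> list[tuple[int, int]]:
        return [self.copy_a, self.copy_b]


@dataclass
class RepeatActivity:
    """Per-repeat long-read phasing summary (recombination proxy)."""

    repeat_id: str
    n_spanning_reads: int
    n_sampled: int
    n_congruent: int
    n_incongruent: int
    n_ambiguous: int
    activity_percent: float | None
    flags: list[str] = field(default_factory=list)


@dataclass
class TandemParams:
    """Tandem-array scoring constants (match, mismatch, indel, Pm, Pi,
    min score, max period) following the conventional 2 7 7 80 10 50 500
    setting vector."""

    match: int = 2
    mismatch_penalty: int = 7
    indel_penalty: int = 7
    match_probability: int = 80
    indel_probability: int = 10
    min_score: int = 50
    max_period: int = 500


# ---------------------------------------------------------------------------
# dispersed repeats


def default_repeat_params() -> SearchParams:
    return SearchParams(min_len_bp=50, min_identity_percent=90.0)


def dispersed_repeats(g: Genome, p: SearchParams | None = None) -> list[RepeatPair]:
    """Self-search the genome and report repeat copy pairs.

    Circular genomes are searched on a doubled sequence and hits are
    canonicalized back to the original coordinates; the trivial full-length
    self-hit and (a,b)/(b,a) mirror duplicates are removed, and pairs whose
    copies overlap each other (tandem arrays) are left to tandem_repeats.
    """
    p = p or default_repeat_params()
    n = len(g)
    seq = g.sequence + g.sequence if g.circular else g.sequence
    work = Genome(id=g.id, sequence=seq, circular=False)
    hits = local_search(work, work, p)

    pairs: dict[tuple, tuple[float, RepeatPair]] = {}
    for h in hits:
        a = (h.q_start, h.q_end)
        b = (h.s_start, h.s_end)
        if h.strand == "+" and a == b:
            continue  # trivial self-identity
        if g.circular:
            # discard duplicates living entirely in the appended copy
            if a[0] >= n and b[0] >= n:
                continue
            a = (a[0] % n, a[1] - (a[0] - a[0] % n))
            b = (b[0] % n, b[1] - (b[0] - b[0] % n))
            a, b = tuple(a), tuple(b)
        if min(a[1], b[1]) - max(a[0], b[0]) > 0:
            continue  # self-overlapping (tandem-like)
        key = (min(a, b), max(a, b), h.strand)
        prev = pairs.get(key)
        if prev is None or h.score > prev[0]:
            ca, cb = sorted([a, b])
            pairs[key] = (h.score, RepeatPair(
                repeat_id="", copy_a=ca, copy_b=cb, length_bp=h.length_bp,
                identity_percent=h.identity_percent,
                strand_relation="direct" if h.strand == "+" else "inverted"))
    out = [rp for _, rp in sorted(pairs.values(),
                                  key=lambda t: (-t[0], t[1].copy_a))]
    for i, rp in enumerate(out):
        rp.repeat_id = f"R{i + 1}"
    return out


def repeat_content(pairs: list[RepeatPair], g: Genome) -> float:
    """Percent of genome positions inside the union of all repeat copies."""
    mask = np.zeros(len(g), bool)
    for rp in pairs:
        for s, e in rp.intervals():
            mask[max(0, s):min(len(g), e)] = True
    return 100.0 * float(mask.sum()) / len(g)


def long_repeats(pairs: list[RepeatPair], min_len_bp: int = 500,
                 min_identity_percent: float = 90.0) -> list[RepeatPair]:
    """Strictly longer than ``min_len_bp`` and above ``min_identity``;
    overlapping qualifying pairs reduced to a non-overlapping set by
    descending length."""
    qual = [rp for rp in pairs
            if rp.length_bp > min_len_bp
            and rp.identity_percent > min_identity_percent]
    qual.sort(key=lambda rp: (-rp.length_bp, rp.copy_a))
    kept: list[RepeatPair] = []
    for rp in qual:
        clash = any(
            min(e1, e2) - max(s1, s2) > 0
            for (s1, e1) in rp.intervals()
            for k in kept for (s2, e2) in k.intervals())
        if not clash:
            kept.append(rp)
    return kept


# ---------------------------------------------------------------------------
# tandem repeats


def _consensus_score(seg: np.ndarray, period: int, tp: TandemParams):
    """Score a candidate array against its per-phase majority consensus and
    trim it to the best-scoring subsegment (Kadane)."""
    L = len(seg)
    cons = np.empty(period, np.int8)
    for off in range(period):
        ph = seg[off::period]
        ph = ph[ph < 4]
        cons[off] = np.bincount(ph, minlength=4).argmax() if len(ph) else 4
    is_match = seg == cons[np.arange(L) % period]
    per_pos = np.where(is_match, tp.match, -tp.mismatch_penalty)
    best = run = 0
    best_lo = best_hi = lo = 0
    for i, v in enumerate(per_pos):
        if run <= 0:
            run = 0
            lo = i
        run += v
        if run > best:
            best = run
            best_lo, best_hi = lo, i + 1
    if best_hi <= best_lo:
        return 0, 0.0, 0, 0
    m = int(is_match[best_lo:best_hi].sum())
    identity = 100.0 * m / (best_hi - best_lo)
    return int(best), identity, best_lo, best_hi


def tandem_repeats(g: Genome, tp: TandemParams | None = None) -> list[Feature]:
    """Detect tandem arrays by lag-match statistics plus consensus scoring.

    For each candidate period ``p`` <= max_period, stretches where
    ``seq[i] == seq[i+p]`` at a rate consistent with the configured match
    probability are proposed as arrays, scored against their per-phase
    majority consensus with (+match, -mismatch_penalty), and reported when
    the score reaches ``min_score``.  Overlapping reports are merged to the
    best-scoring (ties favour the shorter period).  Indels are not modelled
    in the scoring; the indel constants are retained for interface parity
    with the conventional setting vector.
    """
    tp = tp or TandemParams()
    s = encode(g.sequence)
    n = len(s)
    # adjacent copies each ~Pm identical to the consensus match each other at
    # ~Pm^2; the proposal threshold sits slightly below that so marginal
    # arrays still surface (the consensus score gate keeps precision)
    thresh = max(0.45, (tp.match_probability / 100.0) ** 2 - 0.12)
    cands = []
    for p in range(1, min(tp.max_period, n // 2) + 1):
        eq = (s[p:] == s[:-p]) & (s[p:] < 4)
        w = max(p, 12)
        if len(eq) < w:
            continue
        cs = np.concatenate(([0], np.cumsum(eq)))
        frac = (cs[w:] - cs[:-w]) / w
        hot = frac >= thresh
        if not hot.any():
            continue
        d = np.diff(hot.astype(np.int8))
        starts = list(np.nonzero(d == 1)[0] + 1)
        ends = list(np.nonzero(d == -1)[0] + 1)
        if hot[0]:
            starts.insert(0, 0)
        if hot[-1]:
            ends.append(len(hot))
        # merge hot runs separated by small gaps (divergent copies fragment
        # the lag-match signal), then score and trim each merged region
        merged = []
        for a, b in zip(starts, ends):
            if merged and a - merged[-1][1] <= w + p:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        for a, b in merged:
            lo = a
            hi = min(n, b + w + p)
            if hi - lo < max(2 * p, 30):
                continue
            score, ident, t0, t1 = _consensus_score(s[lo:hi], p, tp)
            # < 2.5 copies is a simple duplication, not a tandem array, and
            # a few-copy consensus overfits long periods
            if score >= tp.min_score and (t1 - t0) >= max(2.5 * p, 30):
                cands.append((score, p, lo + t0, lo + t1, ident))
    # single-linkage overlap groups; within each group report the smallest
    # period whose score is competitive (>= 0.6 of the group's best) - a
    # period multiple of a true array scores about as well as the true
    # period, while an unrelated small period scores below min_score
    cands.sort(key=lambda c: (c[2], c[3]))
    groups: list[list[tuple]] = []
    cur_end = -1
    for c in cands:
        if groups and c[2] < cur_end:
            groups[-1].append(c)
            cur_end = max(cur_end, c[3])
        else:
            groups.append([c])
            cur_end = c[3]
    kept: list[tuple] = []
    for grp in groups:
        best = max(c[0] for c in grp)
        competitive = [c for c in grp if c[0] >= max(tp.min_score, 0.6 * best)]
        kept.append(min(competitive, key=lambda c: (c[1], -c[0])))
    feats = []
    for i, (score, p, lo, hi, ident) in enumerate(sorted(kept,
                                                         key=lambda c: c[2])):
        feats.append(Feature(
            gene=f"tandem{i + 1}", type="repeat", intervals=[(lo, hi)],
            strand="+",
            qualifiers={"period": str(p),
                        "copies": f"{(hi - lo) / p:.1f}",
                        "identity": f"{ident:.1f}",
                        "score": str(score)}))
    return feats


def tandem_content(feats: list[Feature], g: Genome) -> float:
    mask = np.zeros(len(g), bool)
    for f in feats:
        for s, e in f.intervals:
            mask[s:e] = True
    return 100.0 * float(mask.sum()) / len(g)


# ---------------------------------------------------------------------------
# recombination proxy


def _flank_identity(segment: str, flank: str) -> float:
    """Percent of the segment's bases matched in a local alignment to flank."""
    if not segment or not flank:
        return 0.0
    res = pairwise_local(segment, flank)
    if res is None:
        return 0.0
    _, _, _, _, _, nmatch, _, _ = res
    return 100.0 * nmatch / len(segment)


def repeat_activity(r: RepeatPair, reads: list[ReadRecord], g: Genome,
                    anchor_bp: int = 100, sample_cap: int = 50,
                    seed: int = 0,
                    ambiguity_margin: float = 2.0) -> RepeatActivity:
    """Phase long-read flanks across a repeat and estimate crossover activity.

    A read is *spanning* iff it covers the full repeat plus >= ``anchor_bp``
    on both sides.  Each side is assigned to copy A or B by higher flank
    identity (difference >= ``ambiguity_margin`` points, else ambiguous);
    activity is the percentage of classified reads whose sides disagree.
    Up to ``sample_cap`` spanning reads are sampled without replacement.
    """
    (a0, a1), (b0, b1) = r.copy_a, r.copy_b
    probe = g.sequence[a0:a1]
    flanks = {
        "A": (g.sequence[max(0, a0 - anchor_bp):a0], g.sequence[a1:a1 + anchor_bp]),
        "B": (g.sequence[max(0, b0 - anchor_bp):b0], g.sequence[b1:b1 + anchor_bp]),
    }
    if r.strand_relation == "inverted":
        left, right = flanks["B"]
        flanks["B"] = (revcomp(right), revcomp(left))
    params = SearchParams(min_score=40)

    spanning = []
    for read in reads:
        if len(read.sequence) < len(probe) + 2 * anchor_bp:
            continue
        hits = local_search(probe, read.sequence, params)
        if not hits:
            continue
        h = max(hits, key=lambda x: x.score)
        if h.q_end - h.q_start < 0.9 * len(probe):
            continue
        seq = read.sequence
        s0, s1 = h.s_start, h.s_end
        if h.strand == "-":
            seq = revcomp(seq)
            s0, s1 = len(seq) - h.s_end, len(seq) - h.s_start
        left = seq[:s0]
        right = seq[s1:]
        if len(left) >= anchor_bp and len(right) >= anchor_bp:
            spanning.append((read.id, left[-anchor_bp:], right[:anchor_bp]))

    act = RepeatActivity(repeat_id=r.repeat_id, n_spanning_reads=len(spanning),
                         n_sampled=0, n_congruent=0, n_incongruent=0,
                         n_ambiguous=0, activity_percent=None)
    if not spanning:
        act.flags.append("no_spanning_reads")
        warnings.warn(f"repeat {r.repeat_id}: no spanning reads; "
                      "activity undefined")
        return act
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 11])
    if len(spanning) > sample_cap:
        idx = sorted(rng.choice(len(spanning), size=sample_cap, replace=False))
        spanning = [spanning[i] for i in idx]
    act.n_sampled = len(spanning)

    for _, left, right in spanning:
        sides = []
        for seg, which in ((left, 0), (right, 1)):
            ida = _flank_identity(seg, flanks["A"][which])
            idb = _flank_identity(seg, flanks["B"][which])
            if abs(ida - idb) < ambiguity_margin:
                sides.append(None)
            else:
                sides.append("A" if ida > idb else "B")
        if sides[0] is None or sides[1] is None:
            act.n_ambiguous += 1
        elif sides[0] == sides[1]:
            act.n_congruent += 1
        else:
            act.n_incongruent += 1
    classified = act.n_congruent + act.n_incongruent
    if classified:
        act.activity_percent = 100.0 * act.n_incongruent / classified
    else:
        act.flags.append("all_ambiguous")
    return act


def write_activity_tsv(acts: list[RepeatActivity], pairs: list[RepeatPair],
                       path) -> None:
    by_id = {p.repeat_id: p for p in pairs}
    cols = ["repeat_id", "length_bp", "identity_percent", "n_spanning",
            "n_sampled", "n_congruent", "n_incongruent", "n_ambiguous",
            "activity_percent", "flags"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in acts:
            rp = by_id.get(a.repeat_id)
            fh.write("\t".join(map(str, [
                a.repeat_id,
                rp.length_bp if rp else ".",
                f"{rp.identity_percent:.1f}" if rp else ".",
                a.n_spanning_reads, a.n_sampled, a.n_congruent,
                a.n_incongruent, a.n_ambiguous,
                f"{a.activity_percent:.1f}" if a.activity_percent is not None
                else "NA",
                ",".join(a.flags) or "."])) + "\n")
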