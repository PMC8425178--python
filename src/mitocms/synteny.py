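"""Syntenic decomposition of a circular genome pair and unique-region extraction.

The sterile (CMS) genome is taken as the query and the fertile maintainer as
the subject. Maximal exact matches seed strand-wise collinear chains; chains
become syntenic blocks classified as collinear / inversion / translocation /
tran+inver; the complement of the blocks on the CMS circle yields the
CMS-unique regions, which can then be attributed to candidate donor genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import intervals as iv
from .align import infix_identity
from .genome import MitoGenome, revcomp

DEFAULT_K = 21
DEFAULT_MAX_GAP = 2000
DEFAULT_MIN_BLOCK = 1000
DEFAULT_MIN_UNIQUE = 1000
# adjacent anchors in a chain may shift diagonal by at most this much, so a
# chain cannot hop between loci via a short distant homolog (e.g. a second
# copy of a tRNA) that happens to sit within max_gap on both genomes
DEFAULT_MAX_DRIFT = 100

_ROMAN = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
          (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
          (5, "V"), (4, "IV"), (1, "I")]


def roman(n: int) -> str:
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


@dataclass
class Anchor:
    """A maximal exact match: query[qpos:qpos+length] equals the subject
    window (reverse-complemented for strand '-')."""

    qpos: int
    spos: int
    length: int
    strand: str = "+"


@dataclass
class SyntenyBlock:
    q_interval: tuple[int, int]
    s_interval: tuple[int, int]
    strand: str
    identity: float
    n_anchors: int
    matched: int = 0
    label: str = ""
    rearrangement_class: str = ""
    q_id: str | None = None
    s_id: str | None = None

    @property
    def q_len(self) -> int:
        return self.q_interval[1] - self.q_interval[0]

    @property
    def s_len(self) -> int:
        return self.s_interval[1] - self.s_interval[0]


@dataclass
class DonorHit:
    donor_id: str
    identity: float
    matches: int
    donor_interval: tuple[int, int]
    strand: str


@dataclass
class UniqueRegion:
    start: int
    end: int
    label: str = ""
    donor_hits: list[DonorHit] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _merged_runs(hits: set[tuple[int, int]]):
    """Collapse co-diagonal k-mer hits into maximal runs."""
    for q, j in sorted(hits):
        if (q - 1, j - 1) in hits:
            continue
        length = 1
        while (q + length, j + length) in hits:
            length += 1
        yield q, j, length


def find_anchors(query: MitoGenome, subject: MitoGenome,
                 k: int = DEFAULT_K) -> list[Anchor]:
    """All maximal exact matches >= k between the genomes, both strands.

    Circularity of the subject is handled by scanning it doubled; anchor
    subject starts are reported in [0, L) and may extend past L. Anchors that
    duplicate (modulo L) a longer co-diagonal anchor are removed.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    qseq, sseq = query.seq, subject.seq
    if k > len(qseq) or k > len(sseq):
        warnings.warn("k exceeds a genome length; no anchors")
        return []
    Ls = len(sseq)
    text = sseq + sseq if subject.circular else sseq
    index: dict[str, list[int]] = {}
    for j in range(len(text) - k + 1):
        index.setdefault(text[j : j + k], []).append(j)

    anchors: list[Anchor] = []
    n_text = len(text)
    for strand in "+-":
        q = qseq if strand == "+" else revcomp(qseq)
        hits: set[tuple[int, int]] = set()
        for i in range(len(q) - k + 1):
            for j in index.get(q[i : i + k], ()):
                hits.add((i, j))
        for qi, j, nk in _merged_runs(hits):
            length = nk + k - 1
            if strand == "+":
                qpos, spos = qi, j
            else:
                # map back from the reverse-complemented query coordinates
                qpos = len(qseq) - (qi + length)
                spos = j
            anchors.append(Anchor(qpos=qpos, spos=spos, length=length,
                                  strand=strand))
    if subject.circular:
        anchors = _dedupe_circular(anchors, Ls)
    anchors.sort(key=lambda a: (a.qpos, a.spos, a.strand))
    return anchors


def _dedupe_circular(anchors: list[Anchor], Ls: int) -> list[Anchor]:
    """Drop second-copy duplicates and mod-L-contained fragments."""
    kept: list[Anchor] = []
    groups: dict[tuple, list[Anchor]] = {}
    for a in anchors:
        if a.spos >= Ls:
            continue
        if a.strand == "+":
            key = ("+", (a.spos - a.qpos) % Ls)
        else:
            key = ("-", (a.spos + a.length + a.qpos) % Ls)
        groups.setdefault(key, []).append(a)
    for group in groups.values():
        group.sort(key=lambda a: (-a.length, a.qpos))
        chosen: list[Anchor] = []
        for a in group:
            contained = any(
                (a.qpos >= b.qpos and a.qpos + a.length <= b.qpos + b.length)
                for b in chosen
            )
            if not contained:
                chosen.append(a)
        kept.extend(chosen)
    return kept


def _chain_dp(anchors: list[Anchor], max_gap: int, min_matched: int = 0,
              max_drift: int = DEFAULT_MAX_DRIFT, overlap_slack: int = 50):
    """Best-first extraction of collinear chains (classic sparse chaining DP).

    Extraction stops once the best remaining chain holds fewer than
    ``min_matched`` exactly matching bases; such chains cannot form a block.
    """
    chains: list[list[Anchor]] = []
    remaining = sorted(anchors, key=lambda a: (a.qpos, a.spos))
    while remaining:
        n = len(remaining)
        score = [a.length for a in remaining]
        parent = [-1] * n
        for i in range(n):
            ai = remaining[i]
            for j in range(i):
                aj = remaining[j]
                dq = ai.qpos - (aj.qpos + aj.length)
                if dq > max_gap:
                    continue
                if dq < -overlap_slack:
                    continue
                if ai.strand == "+":
                    ds = ai.spos - (aj.spos + aj.length)
                else:
                    ds = aj.spos - (ai.spos + ai.length)
                if ds > max_gap or ds < -overlap_slack:
                    continue
                if abs(dq - ds) > max_drift:
                    continue
                cand = score[j] + ai.length
                if cand > score[i]:
                    score[i] = cand
                    parent[i] = j
        best = int(np.argmax(score))
        if score[best] < min_matched:
            break
        chain_idx = []
        i = best
        while i != -1:
            chain_idx.append(i)
            i = parent[i]
        chain_idx.reverse()
        chains.append([remaining[i] for i in chain_idx])
        used = set(chain_idx)
        remaining = [a for i, a in enumerate(remaining) if i not in used]
    return chains


def _block_from_chain(chain: list[Anchor]) -> SyntenyBlock:
    strand = chain[0].strand
    qs = min(a.qpos for a in chain)
    qe = max(a.qpos + a.length for a in chain)
    ss = min(a.spos for a in chain)
    se = max(a.spos + a.length for a in chain)
    matched = sum(a.length for a in chain)
    span = (qe - qs + se - ss) / 2
    identity = min(1.0, matched / span) if span else 0.0
    return SyntenyBlock(q_interval=(qs, qe), s_interval=(ss, se), strand=strand,
                        identity=identity, n_anchors=len(chain), matched=matched)


def _try_wrap_merge(blocks: list[SyntenyBlock], Lq: int, Ls: int,
                    max_gap: int,
                    max_drift: int = DEFAULT_MAX_DRIFT) -> list[SyntenyBlock]:
    """Merge block pairs that continue each other across either origin."""
    merged = True
    blocks = list(blocks)
    while merged:
        merged = False
        for i, a in enumerate(blocks):
            for j, b in enumerate(blocks):
                if i == j or a.strand != b.strand:
                    continue
                qgap = (b.q_interval[0] - a.q_interval[1]) % Lq
                if a.strand == "+":
                    sgap = (b.s_interval[0] - a.s_interval[1]) % Ls
                else:
                    sgap = (a.s_interval[0] - b.s_interval[1]) % Ls
                q_wraps = (a.q_interval[1] >= Lq
                           or a.q_interval[1] % Lq > b.q_interval[0])
                if a.strand == "+":
                    s_wraps = (a.s_interval[1] >= Ls
                               or a.s_interval[1] % Ls > b.s_interval[0])
                else:
                    s_wraps = (b.s_interval[1] >= Ls
                               or b.s_interval[1] % Ls > a.s_interval[0])
                if qgap > max_gap or sgap > max_gap:
                    continue
                if abs(qgap - sgap) > max_drift:
                    continue
                if not (q_wraps or s_wraps):
                    continue  # linear continuation is the chainer's job
                new_qlen = a.q_len + qgap + b.q_len
                new_slen = a.s_len + sgap + b.s_len
                if new_qlen > Lq or new_slen > Ls:
                    continue
                qs = a.q_interval[0]
                if a.strand == "+":
                    ss = a.s_interval[0]
                else:
                    ss = b.s_interval[0]
                blocks[i] = SyntenyBlock(
                    q_interval=(qs, qs + new_qlen),
                    s_interval=(ss, ss + new_slen),
                    strand=a.strand,
                    identity=min(1.0, (a.matched + b.matched) /
                                 ((new_qlen + new_slen) / 2)),
                    n_anchors=a.n_anchors + b.n_anchors,
                    matched=a.matched + b.matched,
                )
                del blocks[j]
                merged = True
                break
            if merged:
                break
    return blocks


def _trim_overlaps(blocks: list[SyntenyBlock], Lq: int, Ls: int,
                   min_block: int) -> list[SyntenyBlock]:
    """No base of either genome may be claimed twice: higher-scoring block wins."""
    order = sorted(blocks, key=lambda b: (-b.matched, b.strand != "+",
                                          b.q_interval[0]))
    claimed_q = np.zeros(Lq, dtype=bool)
    claimed_s = np.zeros(Ls, dtype=bool)
    out: list[SyntenyBlock] = []
    for blk in order:
        qs, qe = blk.q_interval
        ss, se = blk.s_interval
        lt = 0
        while lt < qe - qs and claimed_q[(qs + lt) % Lq]:
            lt += 1
        rt = 0
        while rt < qe - qs - lt and claimed_q[(qe - 1 - rt) % Lq]:
            rt += 1
        if blk.strand == "+":
            ss, se = ss + lt, se - rt
        else:
            ss, se = ss + rt, se - lt
        qs, qe = qs + lt, qe - rt
        if qe - qs < min_block or se - ss <= 0:
            continue
        lt = 0
        while lt < se - ss and claimed_s[(ss + lt) % Ls]:
            lt += 1
        rt = 0
        while rt < se - ss - lt and claimed_s[(se - 1 - rt) % Ls]:
            rt += 1
        if blk.strand == "+":
            qs, qe = qs + lt, qe - rt
        else:
            qs, qe = qs + rt, qe - lt
        ss, se = ss + lt, se - rt
        if qe - qs < min_block or se - ss < min_block:
            continue
        for a, b in iv.linear_parts(qs, qe, Lq):
            claimed_q[a:b] = True
        for a, b in iv.linear_parts(ss, se, Ls):
            claimed_s[a:b] = True
        blk.q_interval, blk.s_interval = (qs, qe), (ss, se)
        out.append(blk)
    return out


def chain_anchors(anchors: list[Anchor], max_gap: int = DEFAULT_MAX_GAP,
                  min_block: int = DEFAULT_MIN_BLOCK,
                  query: MitoGenome | None = None,
                  subject: MitoGenome | None = None,
                  max_drift: int = DEFAULT_MAX_DRIFT) -> list[SyntenyBlock]:
    """Chain anchors into non-overlapping syntenic blocks.

    When the genomes are supplied, chains continuing across either circular
    origin are merged (interval end > length convention) and genome ids are
    stamped onto the blocks. Chains are kept down to two k-mers of matched
    sequence before that merge, so a block cut by an arbitrary origin
    placement can be reassembled; the min_block / matched-bases thresholds
    are enforced afterwards.
    """
    if not anchors:
        return []
    min_matched = max(1, min_block // 2)
    circular = (query is not None and subject is not None
                and query.circular and subject.circular)
    keep = min(42, min_matched) if circular else min_matched
    blocks: list[SyntenyBlock] = []
    for strand in "+-":
        sub = [a for a in anchors if a.strand == strand]
        if not sub:
            continue
        for chain in _chain_dp(sub, max_gap, min_matched=keep,
                               max_drift=max_drift):
            blocks.append(_block_from_chain(chain))
    if query is not None and subject is not None:
        Lq, Ls = len(query.seq), len(subject.seq)
        if circular:
            blocks = _try_wrap_merge(blocks, Lq, Ls, max_gap,
                                     max_drift=max_drift)
        blocks = [b for b in blocks if b.matched >= min_matched]
        blocks = _trim_overlaps(blocks, Lq, Ls, min_block)
        for blk in blocks:
            blk.q_id, blk.s_id = query.id, subject.id
    else:
        blocks = [b for b in blocks
                  if max(b.q_len, b.s_len) >= min_block
                  and b.matched >= min_matched]
    blocks.sort(key=lambda b: (b.q_interval, b.s_interval))
    return blocks


def _weighted_circular_lis(ranks: list[int], weights: list[int]) -> set[int]:
    """Max-weight subset in increasing rank order, allowing one global
    circular rotation of either the position order or the rank order."""
    n = len(ranks)
    best_set: set[int] = set()
    best_w = -1
    for rot in range(n):
        order = list(range(rot, n)) + list(range(rot))
        for roff in range(n):
            vals = [(ranks[i] - roff) % n for i in order]
            w = [weights[i] for i in order]
            dp = list(w)
            parent = [-1] * n
            for i in range(n):
                for j in range(i):
                    if vals[j] < vals[i] and dp[j] + w[i] > dp[i]:
                        dp[i] = dp[j] + w[i]
                        parent[i] = j
            i = int(np.argmax(dp))
            if dp[i] > best_w:
                best_w = dp[i]
                members = set()
                while i != -1:
                    members.add(order[i])
                    i = parent[i]
                best_set = members
    return best_set


def classify_blocks(blocks: list[SyntenyBlock]) -> list[SyntenyBlock]:
    """Label blocks 1..n in maintainer order and classify rearrangements.

    A block whose rank order agrees on both genomes (up to one circular
    rotation) is collinear (+) or an inversion (-); order-breaking blocks are
    translocations (+) or tran+inver (-). Membership in the order-consistent
    set is decided by a length-weighted circular longest-increasing-
    subsequence, so large conserved blocks define the frame of reference.
    """
    if not blocks:
        return []
    blocks = sorted(blocks, key=lambda b: b.q_interval)
    s_order = sorted(range(len(blocks)), key=lambda i: blocks[i].s_interval)
    rank = [0] * len(blocks)
    for r, i in enumerate(s_order):
        rank[i] = r
        blocks[i].label = f"block {r + 1}"
    weights = [b.q_len for b in blocks]
    in_frame = _weighted_circular_lis(rank, weights)
    for i, blk in enumerate(blocks):
        ordered = i in in_frame
        if ordered:
            blk.rearrangement_class = "collinear" if blk.strand == "+" else "inversion"
        else:
            blk.rearrangement_class = ("translocation" if blk.strand == "+"
                                       else "tran_inver")
    return blocks


def _side_intervals(blocks: list[SyntenyBlock], genome: MitoGenome):
    if not blocks:
        return []
    if blocks[0].q_id == genome.id:
        return [b.q_interval for b in blocks]
    if blocks[0].s_id == genome.id:
        return [b.s_interval for b in blocks]
    raise ValueError(f"blocks were not computed for genome {genome.id!r}")


def coverage(blocks: list[SyntenyBlock], genome: MitoGenome) -> float:
    """Fraction of the genome covered by the union of its block intervals."""
    if not blocks:
        return 0.0
    L = len(genome.seq)
    return iv.union_length(_side_intervals(blocks, genome), L) / L


def unique_regions(blocks: list[SyntenyBlock], cms: MitoGenome,
                   min_unique_len: int = DEFAULT_MIN_UNIQUE) -> list[UniqueRegion]:
    """Complement of the CMS-side block union; short gaps are absorbed.

    Labels are roman numerals in genome order starting from the block
    labelled "block 1" (a canonical rotation, since the deposited circles
    start at arbitrary coordinates).
    """
    L = len(cms.seq)
    if not blocks:
        return [UniqueRegion(0, L, label="I")]
    gaps = iv.complement_intervals(_side_intervals(blocks, cms), L,
                                   circular=cms.circular)
    regions = [UniqueRegion(s, e) for s, e in gaps if e - s >= min_unique_len]
    origin = 0
    labelled = [b for b in blocks if b.label == "block 1"]
    if labelled:
        side = _side_intervals([labelled[0]], cms)
        origin = side[0][0]
    regions.sort(key=lambda r: (r.start - origin) % L)
    for i, reg in enumerate(regions):
        reg.label = roman(i + 1)
    return regions


def attribute_donor(region: UniqueRegion, cms: MitoGenome,
                    donors: list[MitoGenome], k: int = DEFAULT_K) -> list[DonorHit]:
    """Rank donor genomes by identity of the region's best placement in them.

    The whole region is aligned semi-globally into each donor (both strands,
    doubled for circularity); identity = matches / alignment columns.
    """
    if region.length < k:
        raise ValueError("region shorter than the anchor size")
    qseq = cms.fetch(region.start, region.end)
    hits: list[DonorHit] = []
    for donor in donors:
        Ld = len(donor.seq)
        text = donor.seq + donor.seq if donor.circular else donor.seq
        best = None
        for strand, q in (("+", qseq), ("-", revcomp(qseq))):
            ident, (t0, t1), matches = infix_identity(q, text)
            cand = DonorHit(donor_id=donor.id, identity=ident, matches=matches,
                            donor_interval=(t0 % Ld, t0 % Ld + (t1 - t0)),
                            strand=strand)
            if best is None or (cand.identity, cand.matches) > (best.identity,
                                                                best.matches):
                best = cand
        hits.append(best)
    hits.sort(key=lambda h: (-h.identity, -h.matches, h.donor_id))
    region.donor_hits = hits
    return hits
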