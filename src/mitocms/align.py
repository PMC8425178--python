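"""Pairwise alignment helpers with one fixed, documented scoring scheme.

All identity fractions reported by the pipeline come from alignments under
the nucleotide scheme match +2 / mismatch -3 / gap open -5 / gap extend -2,
so they are reproducible run to run. Genome-scale searches are first
localized with a fast semi-global (infix) edit-distance scan (edlib) and
with exact k-mer seeding, then rescored with the exact affine-gap dynamic
program on the localized window.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
from Bio import Align

from .genome import revcomp

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -3, -5, -2


def make_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_LOCAL = make_aligner("local")
_GLOBAL = make_aligner("global")


@dataclass
class AlignmentHit:
    score: float
    identity: float          # matches / aligned columns
    matches: int
    columns: int
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    strand: str = "+"


def _hit_from_alignment(aln, strand: str = "+") -> AlignmentHit:
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.internal_gaps
    blocks = aln.aligned
    qs, qe = int(blocks[0][0][0]), int(blocks[0][-1][1])
    ts, te = int(blocks[1][0][0]), int(blocks[1][-1][1])
    identity = counts.identities / columns if columns else 0.0
    return AlignmentHit(
        score=float(aln.score),
        identity=identity,
        matches=int(counts.identities),
        columns=int(columns),
        query_span=(qs, qe),
        target_span=(ts, te),
        strand=strand,
    )


def local_align(query: str, target: str, strand: str = "+") -> AlignmentHit | None:
    """Best Smith-Waterman alignment under the module scoring; None if score<=0."""
    if not query or not target:
        return None
    score = _LOCAL.score(query, target)
    if score <= 0:
        return None
    return _hit_from_alignment(_LOCAL.align(query, target)[0], strand)


def global_align(a: str, b: str):
    if not a or not b:
        raise ValueError("empty sequence")
    return _GLOBAL.align(a, b)[0]


class KmerIndex:
    """Exact k-mer position index over a text (used for seeding searches)."""

    def __init__(self, text: str, k: int):
        if k < 1:
            raise ValueError("k must be positive")
        self.text = text
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(text) - k + 1):
            index.setdefault(text[i : i + k], []).append(i)
        self.index = index

    def positions(self, kmer: str) -> list[int]:
        return self.index.get(kmer, [])


def _seed_windows(query: str, index: KmerIndex, margin: int) -> list[tuple[int, int]]:
    """Cluster diagonal k-mer seed hits of query in the indexed text."""
    k = index.k
    diags: set[int] = set()
    for i in range(0, len(query) - k + 1, max(1, k // 2)):
        for pos in index.positions(query[i : i + k]):
            diags.add(pos - i)
    windows: list[tuple[int, int]] = []
    for d in sorted(diags):
        s = max(0, d - margin)
        e = min(len(index.text), d + len(query) + margin)
        if windows and s <= windows[-1][1]:
            windows[-1] = (windows[-1][0], max(windows[-1][1], e))
        else:
            windows.append((s, e))
    return windows


def genome_hits(
    query: str,
    genome_seq: str,
    circular: bool = True,
    seed_k: int = 11,
    index_cache: dict | None = None,
) -> list[AlignmentHit]:
    """All locally-alignable hits of ``query`` in a genome, both strands.

    Candidate windows come from an edlib infix scan plus exact k-mer seeds;
    each window is rescored with the exact local DP so hit scores agree with
    a full dynamic-programming oracle. Target spans are reported modulo the
    genome length.
    """
    L = len(genome_seq)
    text = genome_seq + genome_seq if circular else genome_seq
    if index_cache is not None and ("idx", seed_k) in index_cache:
        index = index_cache[("idx", seed_k)]
    else:
        index = KmerIndex(text, seed_k) if len(query) >= seed_k else None
        if index_cache is not None:
            index_cache[("idx", seed_k)] = index
    hits: list[AlignmentHit] = []
    margin = max(50, len(query) // 2)
    for strand in "+-":
        q = query if strand == "+" else revcomp(query)
        windows: list[tuple[int, int]] = []
        res = edlib.align(q, text, mode="HW", task="locations")
        if res["locations"]:
            t0, t1 = res["locations"][0]
            windows.append((max(0, t0 - margin), min(len(text), t1 + 1 + margin)))
        if index is not None:
            windows.extend(_seed_windows(q, index, margin))
        # merge overlapping windows for determinism and speed
        windows.sort()
        merged: list[tuple[int, int]] = []
        for s, e in windows:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        for s, e in merged:
            hit = local_align(q, text[s:e], strand)
            if hit is None:
                continue
            ts, te = hit.target_span
            hit.target_span = ((s + ts) % L, (s + ts) % L + (te - ts))
            if strand == "-":
                qs, qe = hit.query_span
                hit.query_span = (len(query) - qe, len(query) - qs)
            hits.append(hit)
    hits.sort(key=lambda h: (-h.score, h.target_span, h.strand))
    return hits


def best_genome_hit(query: str, genome_seq: str, circular: bool = True,
                    **kw) -> AlignmentHit | None:
    hits = genome_hits(query, genome_seq, circular, **kw)
    return hits[0] if hits else None


def infix_identity(query: str, target: str) -> tuple[float, tuple[int, int], int]:
    """Identity of the best semi-global placement of query inside target.

    Returns (matches/columns, target interval, matches). The whole query is
    aligned (edlib HW mode), which is what donor attribution of a region
    copied from a donor genome calls for.
    """
    res = edlib.align(query, target, mode="HW", task="path")
    if not res["locations"]:
        return 0.0, (0, 0), 0
    t0, t1 = res["locations"][0]
    nice = edlib.getNiceAlignment(res, query, target)
    matched = nice["matched_aligned"]
    matches = matched.count("|")
    columns = len(matched)
    return (matches / columns if columns else 0.0), (t0, t1 + 1), matches
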