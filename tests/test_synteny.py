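import itertools

import numpy as np
import pytest

from mitocms.genome import MitoGenome, revcomp, rotate
from mitocms.intervals import union_length
from mitocms.simulate import simulate_donor_panel
from mitocms.synteny import (Anchor, SyntenyBlock, UniqueRegion,
                             attribute_donor, chain_anchors, classify_blocks,
                             coverage, find_anchors, unique_regions)


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


# ---------------------------------------------------------------- anchors


def test_self_match_yields_single_full_length_anchor():
    rng = np.random.default_rng(0)
    g = MitoGenome(id="g", seq=rand_seq(rng, 40), circular=False)
    anchors = find_anchors(g, g, k=15)
    full = [a for a in anchors if a.length == 40 and a.strand == "+"]
    assert len(full) == 1
    assert (full[0].qpos, full[0].spos) == (0, 0)


def test_reverse_complement_gives_minus_anchor():
    rng = np.random.default_rng(1)
    g = MitoGenome(id="g", seq=rand_seq(rng, 60), circular=False)
    rc = MitoGenome(id="rc", seq=revcomp(g.seq), circular=False)
    anchors = [a for a in find_anchors(g, rc, k=15) if a.length == 60]
    assert len(anchors) == 1
    assert anchors[0].strand == "-"
    assert (anchors[0].qpos, anchors[0].spos) == (0, 0)


def brute_force_kmer_anchors(q, s, k):
    """Exhaustive enumeration of all k-mer pairs, merged to maximal runs."""
    pairs = set()
    for strand in "+-":
        qq = q if strand == "+" else revcomp(q)
        for i in range(len(qq) - k + 1):
            for j in range(len(s) - k + 1):
                if qq[i:i + k] == s[j:j + k]:
                    pairs.add((strand, i, j))
    maximal = set()
    for strand, i, j in pairs:
        if (strand, i - 1, j - 1) in pairs:
            continue
        ln = k
        while (strand, i + ln - k + 1, j + ln - k + 1) in pairs:
            ln += 1
        if strand == "+":
            maximal.add(("+", i, j, ln))
        else:
            maximal.add(("-", len(q) - i - ln, j, ln))
    return maximal


def test_anchors_match_exhaustive_kmer_enumeration():
    rng = np.random.default_rng(7)
    shared = rand_seq(rng, 30)
    q = rand_seq(rng, 80) + shared + rand_seq(rng, 90)
    s = rand_seq(rng, 50) + shared + rand_seq(rng, 120)
    qg = MitoGenome(id="q", seq=q, circular=False)
    sg = MitoGenome(id="s", seq=s, circular=False)
    got = {(a.strand, a.qpos, a.spos, a.length)
           for a in find_anchors(qg, sg, k=15)}
    assert got == brute_force_kmer_anchors(q, s, 15)
    planted = [a for a in got if a[3] >= 30]
    assert len(planted) == 1


def test_small_k_raises_and_oversized_k_warns():
    g = MitoGenome(id="g", seq="ACGTACGTACGT", circular=False)
    with pytest.raises(ValueError):
        find_anchors(g, g, k=5)
    with pytest.warns(UserWarning):
        assert find_anchors(g, g, k=50) == []


# ---------------------------------------------------------------- chaining


def exhaustive_best_chain(anchors, max_gap, max_drift=100, slack=50):
    """Brute-force maximum-matched-bases collinear chain (DFS over all
    chains); the independent oracle for the sparse chaining DP."""
    anchors = sorted(anchors, key=lambda a: (a.qpos, a.spos))

    def compatible(x, y):
        if x.strand != y.strand:
            return False
        dq = y.qpos - (x.qpos + x.length)
        if not -slack <= dq <= max_gap:
            return False
        ds = (y.spos - (x.spos + x.length)) if x.strand == "+" \
            else (x.spos - (y.spos + y.length))
        return -slack <= ds <= max_gap and abs(dq - ds) <= max_drift

    best = 0

    def extend(last_idx, score):
        nonlocal best
        best = max(best, score)
        for j in range(last_idx + 1, len(anchors)):
            if compatible(anchors[last_idx], anchors[j]):
                extend(j, score + anchors[j].length)

    for i in range(len(anchors)):
        extend(i, anchors[i].length)
    return best


@pytest.mark.parametrize("seed", range(5))
def test_chaining_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    anchors = [
        Anchor(qpos=int(rng.integers(0, 20000)),
               spos=int(rng.integers(0, 20000)),
               length=int(rng.integers(21, 400)),
               strand="+" if rng.random() < 0.7 else "-")
        for _ in range(15)
    ]
    from mitocms.synteny import _chain_dp
    best_dp = 0
    for strand in "+-":
        sub = [a for a in anchors if a.strand == strand]
        if not sub:
            continue
        chains = _chain_dp(sub, max_gap=2000)
        if chains:
            best_dp = max(best_dp,
                          max(sum(a.length for a in c) for c in chains))
        best_oracle = exhaustive_best_chain(sub, max_gap=2000)
        first = max((sum(a.length for a in c) for c in chains), default=0)
        assert first == best_oracle


def test_single_long_anchor_becomes_identity_block():
    blocks = chain_anchors([Anchor(qpos=10, spos=50, length=1500,
                                   strand="+")])
    assert len(blocks) == 1
    blk = blocks[0]
    assert blk.q_interval == (10, 1510)
    assert blk.s_interval == (50, 1550)
    assert blk.identity == 1.0


def test_two_planted_segments_give_two_blocks():
    rng = np.random.default_rng(11)
    seg1, seg2 = rand_seq(rng, 1500), rand_seq(rng, 1500)
    q = seg1 + rand_seq(rng, 5000) + seg2
    s = rand_seq(rng, 800) + seg1 + rand_seq(rng, 2000) + seg2 \
        + rand_seq(rng, 500)
    qg = MitoGenome(id="q", seq=q, circular=False)
    sg = MitoGenome(id="s", seq=s, circular=False)
    blocks = chain_anchors(find_anchors(qg, sg), query=qg, subject=sg)
    assert len(blocks) == 2
    spans = sorted(b.q_interval for b in blocks)
    assert spans[0] == (0, 1500) and spans[1] == (6500, 8000)


def test_empty_anchor_list_gives_no_blocks():
    assert chain_anchors([]) == []


# ----------------------------------------------------- classification


def _mk_blocks(order, strands, length=2000):
    blocks = []
    pos = 0
    for rank, strand in zip(order, strands):
        blocks.append(SyntenyBlock(q_interval=(pos, pos + length),
                                   s_interval=(rank * 3000,
                                               rank * 3000 + length),
                                   strand=strand, identity=1.0, n_anchors=1,
                                   matched=length))
        pos += length + 500
    return blocks


def test_same_order_plus_strand_is_all_collinear():
    blocks = classify_blocks(_mk_blocks([0, 1, 2, 3], "++++"))
    assert all(b.rearrangement_class == "collinear" for b in blocks)
    assert [b.label for b in blocks] == [f"block {i}" for i in (1, 2, 3, 4)]


def test_minus_strand_in_order_is_inversion():
    blocks = classify_blocks(_mk_blocks([0, 1, 2, 3], "+-++"))
    assert blocks[1].rearrangement_class == "inversion"
    assert {b.rearrangement_class for i, b in enumerate(blocks) if i != 1} \
        == {"collinear"}


def test_order_breaking_blocks_are_translocations():
    # large blocks 0,2,3 define the frame; the small out-of-order block is
    # a translocation (minus strand: tran+inver)
    blocks = _mk_blocks([0, 3, 1, 2], "++++")
    for i, b in enumerate(blocks):
        if i != 1:
            b.q_interval = (b.q_interval[0], b.q_interval[0] + 5000)
    classified = classify_blocks(blocks)
    assert classified[1].rearrangement_class == "translocation"
    classified[1].strand = "-"
    assert classify_blocks(classified)[1].rearrangement_class == "tran_inver"


def test_classification_matches_simulator_truth(small_sim, small_blocks):
    _, _, _, truth = small_sim
    _, blocks, _ = small_blocks
    truth_by_dst = {t.dst[0]: t for t in truth.blocks}
    assert len(blocks) == len(truth.blocks)
    for blk in blocks:
        t = min(truth.blocks, key=lambda t: abs(t.dst[0] - blk.q_interval[0]))
        assert blk.rearrangement_class == t.rearrangement_class
        assert blk.strand == t.strand


# ----------------------------------------------------- coverage and unique


def test_coverage_trivial_cases():
    g = MitoGenome(id="g", seq="A" * 5000)
    assert coverage([], g) == 0.0
    blk = chain_anchors([Anchor(0, 0, 5000, "+")], query=g, subject=g)
    assert coverage(blk, g) == 1.0


def test_identical_genomes_have_no_unique_regions():
    rng = np.random.default_rng(23)
    g = MitoGenome(id="g", seq=rand_seq(rng, 6000))
    h = MitoGenome(id="h", seq=g.seq)
    blocks = chain_anchors(find_anchors(g, h), query=g, subject=h)
    assert unique_regions(blocks, g) == []
    assert coverage(blocks, g) == 1.0


def test_unique_regions_recover_truth(small_sim, small_blocks):
    _, _, cms, truth = small_sim
    _, blocks, regions = small_blocks
    assert len(regions) == len(truth.unique)
    for reg, t in zip(regions, truth.unique):
        assert abs(reg.start - t.start) <= 25
        assert abs(reg.end - t.end) <= 25
        assert reg.label == t.label


def test_coverage_plus_unique_complementarity(small_sim, small_blocks):
    _, _, cms, _ = small_sim
    _, blocks, _ = small_blocks
    regions0 = unique_regions(blocks, cms, min_unique_len=0)
    L = len(cms.seq)
    covered = union_length([b.q_interval for b in blocks], L)
    unique_total = sum(r.length for r in regions0)
    assert covered + unique_total == L


def test_rotation_invariance_of_coverage_and_unique_lengths(small_sim):
    # coverage and unique-region lengths are invariant up to the k-mer
    # quantization of block boundaries at the two arbitrary cut points
    _, maintainer, cms, _ = small_sim
    tol = 2 * 21
    base_blocks = classify_blocks(chain_anchors(
        find_anchors(cms, maintainer), query=cms, subject=maintainer))
    base_cov = union_length([b.q_interval for b in base_blocks],
                            len(cms.seq))
    base_unique = sorted(r.length
                         for r in unique_regions(base_blocks, cms))
    for qoff, soff in ((4321, 0), (0, 9999), (15000, 2500)):
        c2, m2 = rotate(cms, qoff), rotate(maintainer, soff)
        blocks = classify_blocks(chain_anchors(
            find_anchors(c2, m2), query=c2, subject=m2))
        cov = union_length([b.q_interval for b in blocks], len(c2.seq))
        uniq = sorted(r.length for r in unique_regions(blocks, c2))
        assert abs(cov - base_cov) <= tol
        assert len(uniq) == len(base_unique)
        assert all(abs(a - b) <= tol for a, b in zip(uniq, base_unique))


# ----------------------------------------------------- donor attribution


def test_verbatim_donor_copy_ranks_first():
    rng = np.random.default_rng(31)
    cms = MitoGenome(id="c", seq=rand_seq(rng, 8000))
    region_seq = cms.fetch(2000, 3500)
    donor1 = MitoGenome(id="d1", seq=rand_seq(rng, 1000) + region_seq
                        + rand_seq(rng, 1000))
    donor2 = MitoGenome(id="d2", seq=rand_seq(rng, 3500))
    from mitocms.synteny import UniqueRegion
    region = UniqueRegion(2000, 3500, label="I")
    hits = attribute_donor(region, cms, [donor1, donor2])
    assert hits[0].donor_id == "d1"
    assert hits[0].identity == 1.0
    assert hits[0].donor_interval == (1000, 2500)


def test_planted_substitutions_set_donor_identity():
    rng = np.random.default_rng(37)
    cms = MitoGenome(id="c", seq=rand_seq(rng, 6000))
    region_seq = list(cms.fetch(1000, 2000))
    pos = rng.choice(1000, size=5, replace=False)
    for p in pos:
        region_seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[region_seq[p]]
    donor = MitoGenome(id="d", seq=rand_seq(rng, 500)
                       + "".join(region_seq) + rand_seq(rng, 500))
    from mitocms.synteny import UniqueRegion
    region = UniqueRegion(1000, 2000, label="I")
    (hit,) = attribute_donor(region, cms, [donor])
    assert hit.identity == pytest.approx(0.995)


def test_short_region_rejected():
    from mitocms.synteny import UniqueRegion
    cms = MitoGenome(id="c", seq="ACGT" * 100)
    with pytest.raises(ValueError):
        attribute_donor(UniqueRegion(0, 10, label="I"), cms, [cms])
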