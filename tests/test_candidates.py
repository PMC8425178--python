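import numpy as np
import pytest

from mitocms.candidates import (cotranscription_units, detect_chimera,
                                is_specific, locate_vs_unique, predict_tm,
                                screen_candidates)
from mitocms.genome import GeneFeature, MitoGenome
from mitocms.orfs import OrfRecord, find_orfs
from mitocms.synteny import SyntenyBlock, UniqueRegion, chain_anchors, find_anchors


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


# ------------------------------------------------------------- hydropathy


def test_polyaspartate_has_no_tm_domain():
    assert predict_tm("D" * 200) == []


def test_hydrophobic_core_is_one_domain():
    protein = "K" * 40 + "L" * 25 + "K" * 40
    domains = predict_tm(protein)
    assert len(domains) == 1
    d = domains[0]
    assert d.start_aa <= 40 < 65 <= d.end_aa
    assert d.mean_hydropathy > 1.6


def test_two_separated_cores_stay_separate():
    protein = "K" * 30 + "L" * 25 + "K" * 20 + "L" * 25 + "K" * 30
    assert len(predict_tm(protein)) == 2


def test_appending_distant_hydrophilic_tail_changes_nothing():
    protein = "K" * 30 + "L" * 25 + "K" * 30
    base = predict_tm(protein)
    extended = predict_tm(protein + "E" * 100)
    assert [(d.start_aa, d.end_aa) for d in base] == \
        [(d.start_aa, d.end_aa) for d in extended]


def test_short_protein_warns_and_returns_empty():
    with pytest.warns(UserWarning):
        assert predict_tm("MKL") == []


def test_raising_threshold_shrinks_domains():
    protein = "K" * 30 + "L" * 25 + "K" * 20 + "A" * 25 + "K" * 30
    lo = predict_tm(protein, threshold=1.0)
    hi = predict_tm(protein, threshold=3.0)
    assert len(hi) <= len(lo)


# ------------------------------------------------------------ specificity


def _orf_on(genome, start, end, strand="+"):
    from mitocms.orfs import translate
    seq = genome.fetch(start, end)
    if strand == "-":
        from mitocms.genome import revcomp
        seq = revcomp(seq)
    return OrfRecord(genome_id=genome.id, start=start, end=end, strand=strand,
                     aa_length=(end - start) // 3 - 1,
                     protein=translate(seq)[:-1], name="orf_test")


def test_verbatim_copy_is_not_specific():
    rng = np.random.default_rng(3)
    other = MitoGenome(id="o", seq=rand_seq(rng, 5000))
    insert = other.fetch(1000, 1400)
    cms = MitoGenome(id="c", seq=rand_seq(rng, 2000) + insert
                     + rand_seq(rng, 2000))
    orf = OrfRecord(genome_id="c", start=2000, end=2400, strand="+",
                    aa_length=132, protein="M" * 132, name="x")
    assert not is_specific(orf, cms, other)


def test_foreign_sequence_is_specific():
    rng = np.random.default_rng(4)
    other = MitoGenome(id="o", seq=rand_seq(rng, 5000))
    cms = MitoGenome(id="c", seq=rand_seq(rng, 4000))
    orf = OrfRecord(genome_id="c", start=1000, end=1400, strand="+",
                    aa_length=132, protein="M" * 132, name="x")
    assert is_specific(orf, cms, other)


def test_self_specificity_is_impossible():
    rng = np.random.default_rng(5)
    g = MitoGenome(id="g", seq=rand_seq(rng, 4000))
    for orf in find_orfs(g, min_aa=30):
        assert not is_specific(orf, g, g)


# --------------------------------------------------------------- location


def _region(start, end, label="I"):
    return UniqueRegion(start, end, label=label)


def _block(q0, q1):
    return SyntenyBlock(q_interval=(q0, q1), s_interval=(q0, q1), strand="+",
                        identity=1.0, n_anchors=1, matched=q1 - q0)


def _fake_orf(start, end):
    return OrfRecord(genome_id="g", start=start, end=end, strand="+",
                     aa_length=(end - start) // 3 - 1, protein="", name="o")


def test_locations_against_margin_rules():
    L = 20000
    regions = [_region(6000, 12000)]
    blocks = [_block(0, 6000), _block(12000, 20000)]
    assert locate_vs_unique(_fake_orf(8500, 9200), regions, blocks, L)[0] \
        == "interior"
    assert locate_vs_unique(_fake_orf(6010, 6800), regions, blocks, L)[0] \
        == "left_edge"
    assert locate_vs_unique(_fake_orf(11200, 11950), regions, blocks, L)[0] \
        == "right_edge"
    assert locate_vs_unique(_fake_orf(5800, 6500), regions, blocks, L)[0] \
        == "boundary_spanning"
    assert locate_vs_unique(_fake_orf(1000, 1600), regions, blocks, L)[0] \
        == "outside"


# ---------------------------------------------------------------- chimera


def test_full_core_gene_copy_is_complete_homolog():
    rng = np.random.default_rng(6)
    gene = "ATG" + rand_seq(rng, 300) + "TAA"
    cms = MitoGenome(id="c", seq=rand_seq(rng, 500) + gene
                     + rand_seq(rng, 500))
    orf = _fake_orf(500, 500 + len(gene))
    hits = detect_chimera(orf, [("atpA", gene)], cms)
    assert len(hits) == 1
    assert hits[0].complete_homolog
    assert hits[0].orf_fraction_aligned == pytest.approx(1.0)


def test_partial_copy_is_chimeric_with_expected_fraction():
    rng = np.random.default_rng(7)
    gene = "ATG" + rand_seq(rng, 897)  # 900 bp gene
    frag = gene[:186]
    orf_nt = frag + rand_seq(rng, 276) + "TAA"  # 465 bp ORF, 40 % gene-derived
    cms = MitoGenome(id="c", seq=rand_seq(rng, 400) + orf_nt
                     + rand_seq(rng, 400))
    orf = _fake_orf(400, 400 + len(orf_nt))
    hits = detect_chimera(orf, [("atpA", gene), ("cox1", rand_seq(rng, 900))],
                          cms)
    chimeric = [h for h in hits if not h.complete_homolog]
    assert [h.core_gene for h in chimeric] == ["atpA"]
    assert chimeric[0].orf_fraction_aligned == pytest.approx(0.40, abs=0.02)
    assert chimeric[0].identity == pytest.approx(1.0, abs=0.01)


def test_empty_core_panel_is_an_error():
    with pytest.raises(ValueError):
        detect_chimera(_fake_orf(0, 300), [], MitoGenome(id="c", seq="ACGT"))


# ------------------------------------------------------- co-transcription


def test_cotranscription_clustering_and_flagging():
    orfs = [OrfRecord(genome_id="g", start=1000, end=1400, strand="+",
                      aa_length=132, protein="", name="orf138a")]
    feats = [
        GeneFeature("atp8", 1520, 1750, "+", "core_gene"),
        GeneFeature("trnfM", 1800, 1870, "+", "trna"),
        GeneFeature("cox1", 8000, 8600, "+", "core_gene"),
        GeneFeature("nad3", 1450, 1700, "-", "core_gene"),
    ]
    units = cotranscription_units(orfs, feats, L=20000, max_gap=300)
    flagged = [u for u in units if u.flagged]
    assert len(flagged) == 1
    assert flagged[0].names == ["orf138a", "atp8", "trnfM"]
    singleton = [u for u in units if u.names == ["cox1"]]
    assert singleton and not singleton[0].flagged


def test_isolated_orf_is_a_singleton_unit():
    orfs = [OrfRecord(genome_id="g", start=5000, end=5400, strand="+",
                      aa_length=132, protein="", name="solo")]
    units = cotranscription_units(orfs, [], L=20000)
    assert [u.names for u in units] == [["solo"]]


def test_minus_strand_unit_reports_five_prime_first():
    feats = [GeneFeature("a", 1000, 1200, "-", "core_gene"),
             GeneFeature("b", 1250, 1500, "-", "core_gene")]
    units = cotranscription_units([], feats, L=4000)
    assert units[0].names == ["b", "a"]  # 5' of a minus-strand unit is rightmost


# ------------------------------------------------------------- the screen


def test_screen_flags_exactly_the_planted_candidates(small_sim, small_blocks):
    _, maintainer, cms, truth = small_sim
    _, blocks, regions = small_blocks
    core = [(f.name, maintainer.fetch(f.start, f.end))
            for f in maintainer.features if f.kind == "core_gene"]
    panel_all = [(f.name, maintainer.fetch(f.start, f.end))
                 for f in maintainer.features]
    from mitocms.pipeline import annotate_core_genes
    cms_annot = MitoGenome(id=cms.id, seq=cms.seq, circular=True,
                           features=annotate_core_genes(cms, panel_all))
    reports = screen_candidates(cms_annot, maintainer, regions, blocks, core)
    specific = {r.orf.name: r for r in reports if r.specific}
    planted = {f"orf{t.aa_length}a" for t in truth.orfs}
    assert set(specific) == planted
    orf138 = specific["orf138a"]
    assert orf138.location_class == "left_edge"
    assert orf138.unique_label == "I"
    assert len(orf138.tm_domains) == 1
    assert "cotranscribed" in orf138.score_flags
    assert orf138.cotx_unit[:2] == ["orf138a", "atp8"]
    orf102 = specific["orf102a"]
    assert orf102.location_class == "interior"
    assert orf102.tm_domains == []


def test_specificity_is_monotone_in_min_identity(small_sim, small_blocks):
    """Raising the identity needed to call a fertile-genome match can only
    grow the sterile-specific set."""
    _, maintainer, cms, _ = small_sim
    from mitocms.orfs import find_orfs
    orfs = [o for o in find_orfs(cms, min_aa=100) if o.aa_length > 100]
    lo = {o.name for o in orfs if is_specific(o, cms, maintainer,
                                              min_identity=0.85)}
    hi = {o.name for o in orfs if is_specific(o, cms, maintainer,
                                              min_identity=0.999)}
    assert lo <= hi


def test_screen_against_self_yields_no_specific_orfs(small_sim):
    _, maintainer, _, _ = small_sim
    anchors = find_anchors(maintainer, maintainer)
    blocks = chain_anchors(anchors, query=maintainer, subject=maintainer)
    from mitocms.synteny import unique_regions
    regions = unique_regions(blocks, maintainer)
    core = [(f.name, maintainer.fetch(f.start, f.end))
            for f in maintainer.features if f.kind == "core_gene"]
    reports = screen_candidates(maintainer, maintainer, regions, blocks, core)
    assert sum(r.specific for r in reports) == 0
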