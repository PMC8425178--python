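"""CMS-candidate screening of called ORFs.

An ORF is a CMS candidate when it is sterile-specific (no adequate local
alignment into the fertile genome) and carries at least one corroborating
feature of known CMS factors: a predicted transmembrane segment, a chimeric
junction with a core mitochondrial gene, or membership in a co-transcription
unit with a core gene. Thresholds follow classic hydropathy settings and
wide-margin specificity defaults; all are overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import intervals as iv
from .align import KmerIndex, genome_hits, local_align
from .genome import MitoGenome, GeneFeature, revcomp
from .orfs import OrfRecord, find_orfs
from .synteny import SyntenyBlock, UniqueRegion

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

DEFAULTS = dict(
    min_aa=100,              # candidates must encode over this many residues
    spec_min_identity=0.85,
    spec_min_cov=0.5,
    tm_window=19,
    tm_threshold=1.6,
    tm_min_run=1,
    tm_merge_gap=5,
    chimera_min_identity=0.7,
    chimera_min_fraction=0.2,
    chimera_max_fraction=0.9,
    cotx_max_gap=300,
    edge_margin=100,
)


@dataclass
class TMDomain:
    start_aa: int
    end_aa: int
    mean_hydropathy: float


@dataclass
class ChimeraHit:
    core_gene: str
    orf_fraction_aligned: float
    gene_fraction_aligned: float
    identity: float
    orf_interval: tuple[int, int]
    gene_interval: tuple[int, int]
    complete_homolog: bool = False


@dataclass
class CotxUnit:
    names: list[str]
    strand: str
    flagged: bool = False  # holds >=1 candidate ORF and >=1 core gene


@dataclass
class CandidateReport:
    orf: OrfRecord
    specific: bool
    location_class: str
    unique_label: str | None
    tm_domains: list[TMDomain]
    chimera_hits: list[ChimeraHit]
    cotx_unit: list[str] = field(default_factory=list)
    score_flags: set[str] = field(default_factory=set)
    haplotype: str | None = None

    @property
    def is_candidate(self) -> bool:
        return "specific" in self.score_flags and bool(
            self.score_flags & {"tm", "chimeric", "cotranscribed"}
        )


def predict_tm(protein: str, window: int = 19, threshold: float = 1.6,
               min_run: int = 1, merge_gap: int = 5) -> list[TMDomain]:
    """Sliding-window Kyte-Doolittle scan for membrane-spanning segments.

    Maximal runs of >= min_run window positions with mean hydropathy above
    the threshold become domains; runs closer than merge_gap are merged.
    """
    protein = protein.rstrip("*")
    if len(protein) < window:
        warnings.warn("protein shorter than the hydropathy window")
        return []
    values = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in protein])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    hot = means > threshold
    runs: list[list[int]] = []
    i = 0
    n = len(hot)
    while i < n:
        if hot[i]:
            j = i
            while j < n and hot[j]:
                j += 1
            if j - i >= min_run:
                if runs and i - runs[-1][1] < merge_gap:
                    runs[-1][1] = j
                else:
                    runs.append([i, j])
            i = j
        else:
            i += 1
    domains = []
    for a, b in runs:
        # mean over the qualifying window scores, so it always clears the
        # threshold even though the domain span includes window shoulders
        domains.append(TMDomain(start_aa=a, end_aa=b + window,
                                mean_hydropathy=float(means[a:b].mean())))
    return domains


def is_specific(orf: OrfRecord, cms: MitoGenome, other: MitoGenome,
                min_identity: float = 0.85, min_cov: float = 0.5,
                index_cache: dict | None = None) -> bool:
    """True iff no local alignment of the ORF into ``other`` reaches
    ``min_identity`` over at least ``min_cov`` of the ORF length."""
    seq = orf.nt_seq(cms)
    for hit in genome_hits(seq, other.seq, circular=other.circular,
                           index_cache=index_cache):
        cov = (hit.query_span[1] - hit.query_span[0]) / len(seq)
        if hit.identity >= min_identity and cov >= min_cov:
            return False
    return True


def locate_vs_unique(orf: OrfRecord, regions: list[UniqueRegion],
                     blocks: list[SyntenyBlock], L: int,
                     edge_margin: int = 100) -> tuple[str, str | None]:
    """Classify an ORF's position relative to the CMS-unique regions."""
    orf_iv = (orf.start, orf.end)
    for reg in regions:
        ov = iv.overlap_length(orf_iv, reg.interval, L)
        if ov == 0:
            continue
        within = ov == orf.end - orf.start
        if within:
            left = (orf.start - reg.start) % L
            right = (reg.end - orf.end) % L if reg.end != orf.end else 0
            if reg.start == orf.start:
                left = 0
            if left <= edge_margin and right <= edge_margin:
                cls = "left_edge" if left <= right else "right_edge"
            elif left <= edge_margin:
                cls = "left_edge"
            elif right <= edge_margin:
                cls = "right_edge"
            else:
                cls = "interior"
            return cls, reg.label
        q_side = [b.q_interval for b in blocks]
        touches_block = any(iv.overlap_length(orf_iv, b, L) > 0 for b in q_side)
        if touches_block:
            return "boundary_spanning", reg.label
    return "outside", None


def detect_chimera(orf: OrfRecord, core_genes: list[tuple[str, str]],
                   cms: MitoGenome, min_identity: float = 0.7,
                   min_fraction: float = 0.2,
                   max_fraction: float = 0.9) -> list[ChimeraHit]:
    """Find partial (chimeric) homology of the ORF to core genes.

    Hits aligning at least ``max_fraction`` of the ORF are complete homologs
    and are flagged rather than called chimeric.
    """
    if not core_genes:
        raise ValueError("empty core-gene panel")
    seq = orf.nt_seq(cms)
    hits: list[ChimeraHit] = []
    for name, gene_seq in core_genes:
        best = None
        for strand, target in (("+", gene_seq), ("-", revcomp(gene_seq))):
            hit = local_align(seq, target, strand)
            if hit is not None and (best is None or hit.score > best.score):
                best = hit
        if best is None or best.identity < min_identity:
            continue
        orf_fraction = (best.query_span[1] - best.query_span[0]) / len(seq)
        if orf_fraction < min_fraction:
            continue
        gene_fraction = ((best.target_span[1] - best.target_span[0])
                         / len(gene_seq))
        hits.append(ChimeraHit(
            core_gene=name,
            orf_fraction_aligned=orf_fraction,
            gene_fraction_aligned=gene_fraction,
            identity=best.identity,
            orf_interval=best.query_span,
            gene_interval=best.target_span,
            complete_homolog=orf_fraction >= max_fraction,
        ))
    hits.sort(key=lambda h: (-h.orf_fraction_aligned, h.core_gene))
    return hits


def cotranscription_units(orfs: list[OrfRecord], features: list[GeneFeature],
                          L: int, max_gap: int = 300,
                          circular: bool = True) -> list[CotxUnit]:
    """Single-linkage clustering of same-strand features into putative
    polycistronic units (intergenic gap <= max_gap); each unit is reported
    5'->3'. Units joining a candidate ORF with a core gene are flagged."""
    items = [
        {"name": o.name, "start": o.start, "end": o.end, "strand": o.strand,
         "is_orf": True, "is_core": False}
        for o in orfs
    ] + [
        {"name": f.name, "start": f.start, "end": f.end, "strand": f.strand,
         "is_orf": False, "is_core": f.kind in ("core_gene", "trna")}
        for f in features
    ]
    units: list[CotxUnit] = []
    for strand in "+-":
        sub = sorted((x for x in items if x["strand"] == strand),
                     key=lambda x: (x["start"], x["end"]))
        if not sub:
            continue
        clusters = [[sub[0]]]
        for x in sub[1:]:
            gap = x["start"] - max(y["end"] for y in clusters[-1])
            if gap <= max_gap:
                clusters[-1].append(x)
            else:
                clusters.append([x])
        if circular and len(clusters) > 1:
            wrap_gap = (clusters[0][0]["start"] + L
                        - max(y["end"] for y in clusters[-1]))
            if wrap_gap <= max_gap:
                clusters[0] = clusters[-1] + clusters[0]
                clusters.pop()
        for cluster in clusters:
            ordered = sorted(cluster, key=lambda x: x["start"])
            if strand == "-":
                ordered = ordered[::-1]  # 5'->3' runs rightward->leftward
            units.append(CotxUnit(
                names=[x["name"] for x in ordered],
                strand=strand,
                flagged=any(x["is_orf"] for x in cluster)
                and any(x["is_core"] for x in cluster),
            ))
    return units


def screen_candidates(cms: MitoGenome, maintainer: MitoGenome,
                      regions: list[UniqueRegion],
                      blocks: list[SyntenyBlock],
                      core_genes: list[tuple[str, str]],
                      params: dict | None = None) -> list[CandidateReport]:
    """Run the full candidate screen over every ORF above the length cutoff."""
    p = dict(DEFAULTS)
    if params:
        p.update(params)
    L = len(cms.seq)
    orfs = [o for o in find_orfs(cms, min_aa=p["min_aa"])
            if o.aa_length > p["min_aa"]]
    units = cotranscription_units(orfs, cms.features, L,
                                  max_gap=p["cotx_max_gap"],
                                  circular=cms.circular)
    unit_by_orf = {}
    for unit in units:
        for name in unit.names:
            unit_by_orf.setdefault(name, unit)
    index_cache: dict = {}
    reports: list[CandidateReport] = []
    for orf in orfs:
        specific = is_specific(orf, cms, maintainer,
                               min_identity=p["spec_min_identity"],
                               min_cov=p["spec_min_cov"],
                               index_cache=index_cache)
        loc, label = locate_vs_unique(orf, regions, blocks, L,
                                      edge_margin=p["edge_margin"])
        tm = predict_tm(orf.protein, window=p["tm_window"],
                        threshold=p["tm_threshold"], min_run=p["tm_min_run"],
                        merge_gap=p["tm_merge_gap"])
        chim = detect_chimera(orf, core_genes, cms,
                              min_identity=p["chimera_min_identity"],
                              min_fraction=p["chimera_min_fraction"],
                              max_fraction=p["chimera_max_fraction"]) \
            if core_genes else []
        unit = unit_by_orf.get(orf.name)
        cotx = unit.names if unit else [orf.name]
        flags = set()
        if specific:
            flags.add("specific")
        if tm:
            flags.add("tm")
        if any(not h.complete_homolog for h in chim):
            flags.add("chimeric")
        if unit is not None and unit.flagged:
            flags.add("cotranscribed")
        reports.append(CandidateReport(
            orf=orf, specific=specific, location_class=loc, unique_label=label,
            tm_domains=tm, chimera_hits=chim, cotx_unit=cotx,
            score_flags=flags,
        ))
    reports.sort(key=lambda r: (not r.is_candidate, not r.specific,
                                r.orf.start))
    return reports
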