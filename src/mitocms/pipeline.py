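"""End-to-end orchestration: genomes in, candidate report bundle out."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import export
from .align import genome_hits
from .candidates import DEFAULTS as CANDIDATE_DEFAULTS, screen_candidates
from .genome import (GeneFeature, MitoGenome, gc_content, read_fasta,
                     read_genbank, write_fasta)
from .intervals import overlap_length
from .haplotype import assign_haplotype
from .orfs import find_orfs
from .synteny import (DEFAULT_K, DEFAULT_MAX_GAP, DEFAULT_MIN_BLOCK,
                      DEFAULT_MIN_UNIQUE, attribute_donor, chain_anchors,
                      classify_blocks, coverage, find_anchors, unique_regions)

log = logging.getLogger("mitocms")


@dataclass
class RunConfig:
    fertile: str = ""
    sterile: str = ""
    donors: list = field(default_factory=list)
    core_panel: str | None = None
    haplotype_panel: str | None = None
    outdir: str = "mitocms_out"
    circular: bool = True
    k: int = DEFAULT_K
    max_gap: int = DEFAULT_MAX_GAP
    min_block: int = DEFAULT_MIN_BLOCK
    min_unique_len: int = DEFAULT_MIN_UNIQUE
    candidate_params: dict = field(default_factory=dict)
    haplotype_query: str | None = None  # ORF name, else nearest-length pick
    seed: int = 0
    dotplot: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        return cfg

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("outdir", None)  # where results land is not a parameter
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_genome(path, circular: bool = True) -> MitoGenome:
    path = Path(path)
    if path.suffix.lower() in (".gb", ".gbk", ".genbank", ".gbff"):
        return read_genbank(path, circular=circular)
    return read_fasta(path, circular=circular)[0]


def _dotplot(anchors, query, subject, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    matplotlib.rcParams["svg.hashsalt"] = "mitocms"  # reproducible ids
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for a in anchors:
        color = "red" if a.strand == "+" else "blue"
        if a.strand == "+":
            ax.plot([a.qpos, a.qpos + a.length], [a.spos, a.spos + a.length],
                    color=color, lw=0.8)
        else:
            ax.plot([a.qpos, a.qpos + a.length], [a.spos + a.length, a.spos],
                    color=color, lw=0.8)
    ax.set_xlabel(query.id)
    ax.set_ylabel(subject.id)
    ax.set_title("forward (red) / reverse (blue) exact anchors")
    fig.tight_layout()
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)


def annotate_core_genes(genome: MitoGenome, core_panel,
                        min_identity: float = 0.9,
                        min_cov: float = 0.9) -> list[GeneFeature]:
    """Locate core-panel genes on a genome by homology (all good copies).

    Needed when the genome arrives as plain FASTA: the co-transcription-unit
    predictor requires gene features, and a sterile genome may carry extra
    donor-derived copies of a gene (e.g. the atp8 next to orf138).
    """
    L = len(genome.seq)
    feats: list[GeneFeature] = []
    cache: dict = {}
    for name, seq in core_panel:
        for hit in genome_hits(seq, genome.seq, circular=genome.circular,
                               index_cache=cache):
            cov = (hit.query_span[1] - hit.query_span[0]) / len(seq)
            if hit.identity < min_identity or cov < min_cov:
                continue
            s, e = hit.target_span
            dup = any(f.name == name and overlap_length((f.start, f.end),
                                                        (s, e), L) > 0
                      for f in feats)
            if dup:
                continue
            kind = "trna" if name.lower().startswith("trn") else "core_gene"
            feats.append(GeneFeature(name=name, start=s, end=e,
                                     strand=hit.strand, kind=kind))
    feats.sort(key=lambda f: (f.start, f.name))
    return feats


def compare_genomes(cms: MitoGenome, maintainer: MitoGenome, config: RunConfig):
    anchors = find_anchors(cms, maintainer, k=config.k)
    blocks = chain_anchors(anchors, max_gap=config.max_gap,
                           min_block=config.min_block,
                           query=cms, subject=maintainer)
    blocks = classify_blocks(blocks)
    regions = unique_regions(blocks, cms, min_unique_len=config.min_unique_len)
    return anchors, blocks, regions


def _pick_haplotype_query(reports, panel, cms, name: str | None):
    if name:
        chosen = [r for r in reports if r.orf.name == name]
        if not chosen:
            raise ValueError(f"haplotype query ORF {name!r} not found")
        return chosen[0]
    target = sum(len(seq) for _, seq in panel) / len(panel)
    specific = [r for r in reports if r.specific] or list(reports)
    if not specific:
        return None
    return min(specific, key=lambda r: abs(r.orf.nt_length - target))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full comparison and write the report bundle.

    Returns the summary dictionary that is also written to summary.json.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        maintainer = load_genome(config.fertile, circular=config.circular)
        cms = load_genome(config.sterile, circular=config.circular)
        donors = [load_genome(p, circular=config.circular)
                  for p in config.donors]
        core_panel = []
        if config.core_panel:
            core_panel = [(g.id, g.seq)
                          for g in read_fasta(config.core_panel)]
        elif maintainer.features:
            core_panel = [(f.name, maintainer.fetch(f.start, f.end))
                          for f in maintainer.features
                          if f.kind == "core_gene"]
        hap_panel = []
        if config.haplotype_panel:
            hap_panel = [(g.id, g.seq)
                         for g in read_fasta(config.haplotype_panel)]

        if not cms.features and core_panel:
            log.info("annotating core genes on the sterile genome by homology")
            cms.features = annotate_core_genes(cms, core_panel)

        stage = "synteny"
        log.info("anchoring and chaining syntenic blocks")
        anchors, blocks, regions = compare_genomes(cms, maintainer, config)
        for region in regions:
            if donors:
                attribute_donor(region, cms, donors, k=config.k)

        stage = "orf_annotation"
        min_aa = config.candidate_params.get(
            "min_aa", CANDIDATE_DEFAULTS["min_aa"])
        orfs = find_orfs(cms, min_aa=min_aa)

        stage = "candidate_filter"
        log.info("screening %d ORFs for CMS candidacy", len(orfs))
        reports = screen_candidates(cms, maintainer, regions, blocks,
                                    core_panel, params=config.candidate_params)

        stage = "haplotyping"
        hap_call = None
        hap_query = None
        if hap_panel:
            hap_query = _pick_haplotype_query(reports, hap_panel, cms,
                                              config.haplotype_query)
            if hap_query is not None:
                hap_call = assign_haplotype(hap_query.orf.nt_seq(cms),
                                            hap_panel)
                hap_query.haplotype = hap_call.best

        stage = "report"
        summary = _write_bundle(outdir, config, maintainer, cms, donors,
                                anchors, blocks, regions, reports,
                                hap_call, hap_query)
        return summary
    except Exception:
        log.error("pipeline failed during stage %r", stage)
        (Path(config.outdir) / "INCOMPLETE").write_text(
            f"failed during stage: {stage}\n")
        raise


def _write_bundle(outdir, config, maintainer, cms, donors, anchors, blocks,
                  regions, reports, hap_call, hap_query) -> dict:
    digest = config.digest()
    stamp = dict(config_hash=digest, seed=config.seed)

    export.blocks_table(blocks).to_csv(outdir / "blocks.tsv", sep="\t",
                                       index=False)
    export.write_bed(outdir / "blocks_sterile.bed", cms,
                     [(b.q_interval[0], b.q_interval[1], b.label, b.strand)
                      for b in blocks])
    export.write_bed(outdir / "blocks_fertile.bed", maintainer,
                     [(b.s_interval[0], b.s_interval[1], b.label, b.strand)
                      for b in blocks])
    export.unique_table(regions).to_csv(outdir / "unique_regions.tsv",
                                        sep="\t", index=False)
    export.write_bed(outdir / "unique_regions.bed", cms,
                     [(r.start, r.end, f"unique_{r.label}") for r in regions])
    export.candidate_table(reports).to_csv(outdir / "candidates.tsv",
                                           sep="\t", index=False)
    (outdir / "candidates.json").write_text(export.candidates_json(reports))
    export.write_gff3(
        outdir / "candidates.gff3", cms,
        [(r.orf.start, r.orf.end, r.orf.strand, "CDS",
          {"ID": r.orf.name, "cotx_unit": "|".join(r.cotx_unit),
           "flags": ",".join(sorted(r.score_flags))})
         for r in reports])
    if hap_call is not None:
        (outdir / "haplotype.json").write_text(json.dumps(
            dict(query=hap_query.orf.name, best=hap_call.best,
                 margin=hap_call.margin,
                 distances=hap_call.distances, **stamp),
            indent=2, sort_keys=True))
        (outdir / "tree.nwk").write_text(hap_call.tree + "\n")
    if config.dotplot:
        _dotplot(anchors, cms, maintainer, outdir / "dotplot.svg")

    n_candidates = sum(r.is_candidate for r in reports)
    summary = dict(
        fertile_id=maintainer.id, sterile_id=cms.id,
        fertile_length=len(maintainer.seq), sterile_length=len(cms.seq),
        fertile_gc=round(gc_content(maintainer), 4),
        sterile_gc=round(gc_content(cms), 4),
        n_blocks=len(blocks),
        coverage_sterile=round(coverage(blocks, cms), 4),
        coverage_fertile=round(coverage(blocks, maintainer), 4),
        n_unique_regions=len(regions),
        unique_total_bp=sum(r.length for r in regions),
        n_orfs_screened=len(reports),
        n_specific_orfs=sum(r.specific for r in reports),
        n_candidates=n_candidates,
        haplotype=hap_call.best if hap_call else None,
        **stamp,
    )
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    sort_keys=True))
    lines = [
        f"mitocms run (config {digest}, seed {config.seed})",
        f"fertile {maintainer.id}: {len(maintainer.seq):,} bp, "
        f"GC {100 * summary['fertile_gc']:.2f} %",
        f"sterile {cms.id}: {len(cms.seq):,} bp, "
        f"GC {100 * summary['sterile_gc']:.2f} %",
        f"syntenic blocks: {len(blocks)} covering "
        f"{100 * summary['coverage_sterile']:.2f} % of the sterile and "
        f"{100 * summary['coverage_fertile']:.2f} % of the fertile genome",
        f"unique regions: {len(regions)} totalling "
        f"{summary['unique_total_bp']:,} bp",
        f"ORFs screened (> {CANDIDATE_DEFAULTS['min_aa']} aa): "
        f"{len(reports)}; sterile-specific: {summary['n_specific_orfs']}; "
        f"candidates: {n_candidates}",
    ]
    for r in reports:
        if r.specific:
            tm = len(r.tm_domains)
            chim = ",".join(h.core_gene for h in r.chimera_hits
                            if not h.complete_homolog) or "-"
            lines.append(
                f"  {r.orf.name}: {r.location_class}"
                f"{' ' + r.unique_label if r.unique_label else ''}, "
                f"{tm} TM domain(s), chimera {chim}, "
                f"unit {'-'.join(r.cotx_unit)}")
    if hap_call is not None:
        lines.append(f"haplotype of {hap_query.orf.name}: {hap_call.best} "
                     f"(margin {hap_call.margin:.4f} subs/site)")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    with open(outdir / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(dict(asdict(config), config_hash=digest), fh,
                       sort_keys=True)
    return summary
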