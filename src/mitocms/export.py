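"""Writers for the pipeline's tabular and annotation outputs."""

from __future__ import annotations

import json
from dataclasses import asdict

import pandas as pd

from .genome import MitoGenome
from .intervals import linear_parts


def blocks_table(blocks) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(label=b.label, q_start=b.q_interval[0], q_end=b.q_interval[1],
                 s_start=b.s_interval[0], s_end=b.s_interval[1],
                 strand=b.strand, rearrangement=b.rearrangement_class,
                 identity=round(b.identity, 4), n_anchors=b.n_anchors)
            for b in blocks
        ]
    )


def unique_table(regions) -> pd.DataFrame:
    rows = []
    for r in regions:
        top = r.donor_hits[0] if r.donor_hits else None
        rows.append(dict(
            label=r.label, start=r.start, end=r.end, length=r.length,
            top_donor=top.donor_id if top else "",
            top_identity=round(top.identity, 6) if top else "",
            donor_ranking=";".join(
                f"{h.donor_id}:{h.identity:.6f}" for h in r.donor_hits),
        ))
    return pd.DataFrame(rows)


def candidate_table(reports) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(dict(
            name=r.orf.name, start=r.orf.start, end=r.orf.end,
            strand=r.orf.strand, aa_length=r.orf.aa_length,
            specific=r.specific, location=r.location_class,
            unique_region=r.unique_label or "",
            n_tm_domains=len(r.tm_domains),
            tm_domains=";".join(f"{d.start_aa}-{d.end_aa}"
                                for d in r.tm_domains),
            chimera=";".join(
                f"{h.core_gene}({h.orf_fraction_aligned:.2f},{h.identity:.2f})"
                for h in r.chimera_hits if not h.complete_homolog),
            cotx_unit="|".join(r.cotx_unit),
            flags=",".join(sorted(r.score_flags)),
            candidate=r.is_candidate,
        ))
    return pd.DataFrame(rows)


def candidates_json(reports) -> str:
    payload = []
    for r in reports:
        d = dict(
            orf=asdict(r.orf), specific=r.specific,
            location_class=r.location_class, unique_label=r.unique_label,
            tm_domains=[asdict(t) for t in r.tm_domains],
            chimera_hits=[asdict(h) for h in r.chimera_hits],
            cotx_unit=r.cotx_unit, score_flags=sorted(r.score_flags),
            candidate=r.is_candidate, haplotype=r.haplotype,
        )
        payload.append(d)
    return json.dumps(payload, indent=2, sort_keys=True)


def write_bed(path, genome: MitoGenome, entries) -> None:
    """entries: iterable of (start, end, name[, strand]); wraps are split."""
    L = len(genome.seq)
    with open(path, "w") as fh:
        for entry in entries:
            start, end, name = entry[0], entry[1], entry[2]
            strand = entry[3] if len(entry) > 3 else "+"
            for s, e in linear_parts(start, end, L):
                fh.write(f"{genome.id}\t{s}\t{e}\t{name}\t0\t{strand}\n")


def write_gff3(path, genome: MitoGenome, records) -> None:
    """records: (start, end, strand, type, attributes-dict); 1-based output."""
    L = len(genome.seq)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {L}\n")
        for start, end, strand, ftype, attrs in records:
            attr = ";".join(f"{k}={v}" for k, v in attrs.items())
            for s, e in linear_parts(start, end, L):
                fh.write(
                    f"{genome.id}\tmitocms\t{ftype}\t{s + 1}\t{e}\t.\t"
                    f"{strand}\t.\t{attr}\n")
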