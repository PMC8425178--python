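"""Reading, writing and circular-sequence primitives for mitochondrial genomes.

Plant mitochondrial assemblies are single circular molecules with an
arbitrary start coordinate, so every primitive here is circle-aware:
coordinates are 0-based half-open, and a feature or slice may run past the
end of the sequence (``end > len``) to represent an origin-spanning interval
(always with ``end <= start + len``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# IUPAC ambiguity codes other than N collapse to N (exact-match anchoring
# downstream cannot use them).
_AMBIGUOUS = set("RYSWKMBDHV")

#: The known protein-coding / maturase gene complement of Brassica
#: mitochondria (complex I, II, IV and V subunits, cytochrome c biogenesis,
#: ribosomal proteins, matR), plus the atpA/atp1 naming alias.
CORE_GENES = frozenset(
    name.lower()
    for name in (
        "nad1 nad2 nad3 nad4 nad4L nad5 nad6 nad7 nad9 cob "
        "cox1 cox2 cox3 atp1 atp4 atp6 atp8 atp9 atpA "
        "ccmB ccmC ccmFN1 ccmFN2 ccmFC "
        "rpl2 rpl5 rpl16 rps4 rps7 rps12 rps14 matR"
    ).split()
)


@dataclass
class GeneFeature:
    """An annotated feature on a genome, 0-based half-open coordinates."""

    name: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "other"  # core_gene | orf | trna | rrna | other

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("feature end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MitoGenome:
    """A (usually circular) mitochondrial genome sequence with features."""

    id: str
    seq: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ValueError(f"bad alphabet in record {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps across the origin on circles."""
        L = len(self.seq)
        if end < start:
            raise ValueError("end < start")
        if not self.circular:
            if start < 0 or end > L:
                raise ValueError("interval outside linear genome")
            return self.seq[start:end]
        if end - start > L:
            raise ValueError("interval longer than genome")
        start %= L
        end = start + (end - start) if end - start else start
        stop = start + (end - start)
        if stop <= L:
            return self.seq[start:stop]
        return self.seq[start:] + self.seq[: stop - L]


def normalize_seq(raw: str, record_id: str) -> str:
    """Uppercase, U->T, non-N ambiguity codes -> N; reject anything else."""
    seq = str(raw).upper().replace("U", "T")
    extra = set(seq) - ALPHABET
    if extra & _AMBIGUOUS:
        warnings.warn(
            f"{record_id}: ambiguity codes {sorted(extra & _AMBIGUOUS)} mapped to N"
        )
        seq = seq.translate(str.maketrans({c: "N" for c in _AMBIGUOUS}))
        extra = set(seq) - ALPHABET
    if extra:
        raise ValueError(f"bad alphabet in record {record_id!r}: {sorted(extra)}")
    return seq


def read_fasta(path, circular: bool = True) -> list[MitoGenome]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in {path}")
    return [
        MitoGenome(id=rec.id, seq=normalize_seq(rec.seq, rec.id), circular=circular)
        for rec in records
    ]


def write_fasta(genomes, path) -> None:
    if isinstance(genomes, MitoGenome):
        genomes = [genomes]
    records = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes]
    SeqIO.write(records, str(path), "fasta")


def _feature_name(feat) -> str:
    for key in ("gene", "product", "locus_tag", "label"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return feat.type


def _feature_kind(feat, name: str) -> str:
    if feat.type == "tRNA":
        return "trna"
    if feat.type == "rRNA":
        return "rrna"
    if feat.type == "CDS":
        return "core_gene" if name.lower() in CORE_GENES else "orf"
    return "other"


def read_genbank(path, circular: bool = True) -> MitoGenome:
    """Parse a GenBank flat file into a genome with CDS/tRNA/rRNA features.

    Two-part joined locations that wrap the origin are collapsed to a single
    feature using the ``end > length`` convention.
    """
    rec = SeqIO.read(str(path), "genbank")
    if len(rec.seq) == 0:
        raise ValueError(f"{path}: missing ORIGIN sequence")
    L = len(rec.seq)
    features: list[GeneFeature] = []
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            continue
        name = _feature_name(feat)
        strand = "-" if feat.location.strand == -1 else "+"
        parts = sorted(feat.location.parts, key=lambda p: int(p.start))
        if len(parts) > 1 and int(parts[-1].end) == L and int(parts[0].start) == 0:
            # origin-spanning join: runs to the sequence end then restarts at 0
            start, end = int(parts[-1].start), L + int(parts[0].end)
        else:
            start, end = int(feat.location.start), int(feat.location.end)
        features.append(
            GeneFeature(name=name, start=start, end=end, strand=strand,
                        kind=_feature_kind(feat, name))
        )
    return MitoGenome(
        id=rec.id or rec.name,
        seq=normalize_seq(rec.seq, rec.id),
        circular=circular,
        features=features,
    )


def gc_content(genome: MitoGenome | str) -> float:
    """(G+C) / (A+C+G+T); N is excluded from the denominator."""
    seq = genome.seq if isinstance(genome, MitoGenome) else genome
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return gc / acgt


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def rotate(genome: MitoGenome, offset: int) -> MitoGenome:
    """Return the genome restarted so old position ``offset`` becomes 0."""
    if not genome.circular:
        raise ValueError("rotate requires a circular genome")
    L = len(genome.seq)
    offset %= L
    seq = genome.seq[offset:] + genome.seq[:offset]
    feats = [
        replace(f, start=(f.start - offset) % L,
                end=(f.start - offset) % L + f.length)
        for f in genome.features
    ]
    return MitoGenome(id=genome.id, seq=seq, circular=True, features=feats)
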