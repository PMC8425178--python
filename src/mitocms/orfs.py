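"""Circular-aware ORF calling on both strands.

An ORF is ATG to the first in-frame stop under the universal genetic code
(plant mitochondria translate with the standard table). On circular genomes
reading frames continue across the origin, which is handled by scanning the
doubled sequence and reporting start coordinates modulo the genome length
(the interval end may exceed the length for origin-spanning ORFs). Nested
starts sharing a stop are collapsed to the 5'-most ATG.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import MitoGenome, revcomp

_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE: dict[str, str] = {
    b1 + b2 + b3: _AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}
STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")


@dataclass
class OrfRecord:
    genome_id: str
    start: int
    end: int  # half-open; may exceed genome length for origin-spanning ORFs
    strand: str
    aa_length: int
    protein: str
    name: str = ""

    @property
    def nt_length(self) -> int:
        return self.end - self.start

    def nt_seq(self, genome: MitoGenome) -> str:
        seq = genome.fetch(self.start, self.end)
        return seq if self.strand == "+" else revcomp(seq)


def translate(seq: str) -> str:
    """Universal-code translation; stops rendered '*'; N codons give 'X'."""
    if len(seq) % 3:
        raise ValueError("sequence length not a multiple of 3")
    return "".join(
        CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, len(seq), 3)
    )


def _scan_strand(scan: str, L: int, circular: bool, min_aa: int):
    """Yield (start, nt_length) of ORFs in ``scan`` coordinates.

    ``scan`` is the doubled sequence for circular genomes. For circles only
    segments strictly between two stop codons are used (so the 5'-most-ATG
    rule is decided with the upstream stop in view); duplicates from the
    second copy are removed by the caller via modulo-L start positions.
    """
    n = len(scan)
    for frame in range(3):
        codon_starts = range(frame, n - 2, 3)
        stops = [p for p in codon_starts if scan[p : p + 3] in STOP_CODONS]
        if circular and not stops:
            continue  # stop-free frame on the whole circle: no terminated ORF
        bounds = []
        if not circular:
            prev = frame - 3  # virtual boundary before the sequence
            for s in stops:
                bounds.append((prev + 3, s))
                prev = s
        else:
            for i in range(len(stops) - 1):
                bounds.append((stops[i] + 3, stops[i + 1]))
        for seg_start, stop_pos in bounds:
            p = seg_start
            while p < stop_pos and scan[p : p + 3] != "ATG":
                p += 3
            if p >= stop_pos:
                continue
            aa_len = (stop_pos - p) // 3
            if aa_len < min_aa:
                continue
            nt_len = stop_pos + 3 - p
            if circular and nt_len > L:
                continue
            yield p, nt_len


def find_orfs(genome: MitoGenome, min_aa: int = 100,
              circular: bool | None = None) -> list[OrfRecord]:
    """All maximal ORFs of >= min_aa codons (stop excluded) on both strands."""
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    circ = genome.circular if circular is None else circular
    seq = genome.seq
    L = len(seq)
    scan_fwd = seq + seq if circ else seq
    scan_rev = revcomp(scan_fwd)
    n = len(scan_fwd)
    seen: set[tuple[int, str, int]] = set()
    records: list[OrfRecord] = []
    for strand, scan in (("+", scan_fwd), ("-", scan_rev)):
        for p, nt_len in _scan_strand(scan, L, circ, min_aa):
            if strand == "+":
                start = p
            else:
                start = n - (p + nt_len)
            if circ:
                start %= L
            key = (start, strand, nt_len)
            if key in seen:
                continue
            seen.add(key)
            end = start + nt_len
            orf_nt = genome.fetch(start, end) if circ or end <= L else seq[start:end]
            if strand == "-":
                orf_nt = revcomp(orf_nt)
            protein = translate(orf_nt)[:-1]
            records.append(
                OrfRecord(genome_id=genome.id, start=start, end=end,
                          strand=strand, aa_length=nt_len // 3 - 1,
                          protein=protein)
            )
    records.sort(key=lambda r: (r.start, r.end, r.strand))
    _assign_names(records)
    return records


def _assign_names(records: list[OrfRecord]) -> None:
    """orf{aa_length}{a,b,...}; letters follow genome position per length."""
    by_len: dict[int, int] = {}
    for rec in records:
        i = by_len.get(rec.aa_length, 0)
        by_len[rec.aa_length] = i + 1
        suffix = ""
        j = i
        while True:
            suffix = chr(ord("a") + j % 26) + suffix
            j = j // 26 - 1
            if j < 0:
                break
        rec.name = f"orf{rec.aa_length}{suffix}"
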