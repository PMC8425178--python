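# Methods

## The comparison model

Both genomes are single circular molecules with arbitrary deposited start
coordinates. All coordinates are 0-based half-open; an interval may run past
the sequence end (`end <= start + L`) to represent an origin-spanning
feature, block or ORF, so one biological object is always one record.
Because the start coordinate of a circular assembly is arbitrary, nothing
downstream may depend on it: anchors are found against the doubled subject,
ORF frames continue across the origin, blocks split by an origin are
re-merged, and the test suite checks rotation invariance explicitly rather
than assuming it. Exact invariance is impossible for anchor-based synteny —
an exact-match run cut by the origin loses up to k−1 bases on each side of
the cut, since a fragment shorter than k is no longer an anchor — so
coverage and unique-region lengths are asserted invariant to within 2k,
while the called ORF set is asserted exactly invariant.

## Synteny

Anchors are maximal exact matches of length ≥ k between the two genomes on
both strands, found by k-mer indexing and co-diagonal run merging. Chains
are built per strand with a sparse chaining DP: consecutive anchors may be
separated by at most `max_gap` on both genomes, may overlap by at most 50 bp,
and may shift diagonal by at most `max_drift`. The drift bound is what keeps
a chain from hopping between loci through a short distant homolog — e.g. a
second copy of a tRNA sitting within `max_gap` of a block junction on both
genomes — which would otherwise smear a block boundary across a unique
region. Chains are extracted best-first; blocks must span ≥ `min_block`
with at least `min_block/2` exactly matched bases (the matched-bases floor
discards "chains" of scattered coincidental k-mers whose gapped span happens
to exceed `min_block`). Before these thresholds apply, chains down to two
k-mers are kept so that wrap-merging can reassemble blocks cut by either
origin. Overlaps between blocks are resolved by trimming the lower-scoring
block (ties: plus strand, then lower query start).

Defaults: k = 21, max_gap = 2000 bp, min_block = 1000 bp, max_drift =
100 bp, min_unique_len = 1000 bp. The gap and block thresholds are sized to
resolve the smallest structures reported for real maintainer/CMS pairs
(blocks near 1.2 kb, unique regions near 1.7 kb) without fragmenting large
blocks across substitution noise; the drift bound is an order of magnitude
above plausible per-gap indel drift in organelle comparisons at ≥ 99 %
identity. Per-block identity is estimated as anchor-matched bases over the
mean block span rather than by aligning 100-kb blocks base by base; at the
≥ 99 % identities involved the two agree closely and the estimate is
deterministic and fast.

Rearrangement classes are assigned by a length-weighted circular
longest-increasing-subsequence over the blocks' order on the two circles:
blocks in the max-weight order-consistent set are collinear (+) or
inversions (−); the rest are translocations (+) or tran+inver (−). Weighting
by length makes the big conserved blocks define the frame of reference, so
a small relocated block is the translocation, not the other way round.

Unique regions are the complement of the block union on the sterile circle;
gaps shorter than `min_unique_len` are treated as within-block gaps. Labels
I, II, … follow genome order starting from "block 1" (the block that is
first on the maintainer), a canonical rotation that makes labels independent
of the deposited start coordinate. Donor attribution aligns the whole region
semi-globally (edlib infix mode, both strands, doubled donor) and reports
identity = matched columns / alignment columns; ranking is by identity, then
matched bases. Regions shorter than k are rejected.

## ORF calling and the candidate screen

ORFs are ATG → first in-frame stop under the universal code (plant
mitochondria translate with the standard table; alternative starts and RNA
editing are out of scope), on both strands, ≥ `min_aa` codons excluding the
stop; nested starts sharing a stop collapse to the 5′-most ATG. Circularity
is handled by scanning the doubled sequence, using only inter-stop segments
(so the upstream stop is always in view) and deduplicating by start modulo
L. Names are `orf{aa}{a,b,…}` with letters assigned in genome order per
length; the suffix assignment of the original annotations is not claimed,
only the naming style. The screen considers ORFs encoding **more than 100
amino acids** — the field's working definition of a CMS-candidate-sized
ORF. The census cutoff used for published "N unknown ORFs" counts is not
reproducible (the annotation tool's setting is unstated), so census counts
are reported but never asserted.

Candidate evidence per ORF:

* **Specificity** — an ORF is sterile-specific iff no local alignment into
  the fertile genome reaches ≥ 85 % identity over ≥ 50 % of the ORF.
  Candidate placements come from an edit-distance infix scan plus exact
  11-mer seeding; each window is rescored with the exact affine-gap DP
  (match +2, mismatch −3, gap open −5, extend −2 — one fixed scheme so
  identity fractions are reproducible), and scores agree with a full DP
  oracle by construction. The 0.85/0.5 defaults sit in the wide margin
  between donor-derived sequence (no homology) and shared blocks (≥ 99 %
  identity); a chimeric ORF whose 5′ part matches a core gene stays
  specific as long as the matched part covers < 50 % of it.
* **Location** — interior / left_edge / right_edge (within 100 bp of a
  region boundary) / boundary_spanning (overlaps a region and a block) /
  outside.
* **Transmembrane segments** — Kyte–Doolittle means over a 19-residue
  window; window positions above 1.6 form domains (runs closer than 5
  positions merge). This is a deliberate re-implementation of hydropathy
  scanning, not a hidden-Markov predictor; marginal helices may be called
  differently, which is why the TM counts are checked against planted truth
  (exact by construction) and against the published counts only with the
  accession data present.
* **Chimerism** — best local alignment against each core-panel gene; hits at
  ≥ 70 % identity covering 20–90 % of the ORF are chimeric; ≥ 90 % coverage
  flags a complete homolog instead. "Partial homology" is unquantified in
  the field; these bounds separate the planted 40 % junction fragment from
  both noise and full gene copies with wide margins.
* **Co-transcription units** — single-linkage clustering of same-strand
  features at intergenic gap ≤ 300 bp (operon-like spacing), reported
  5′→3′; units joining a candidate ORF to a core gene (or tRNA) are
  flagged. This is a positional prediction only; transcript evidence is out
  of scope. When the sterile genome arrives as FASTA, core genes are first
  located on it by homology (≥ 90 % identity and coverage), which also
  recovers donor-derived extra copies such as the atp8 beside orf138.

## Haplotyping

Distances are p-distances (mismatched columns / ungapped columns) after
global alignment under the same fixed scoring; assignment is nearest
neighbour with alphabetical tie-breaking and a reported margin. The tree is
neighbour joining (scikit-bio), with negative branch lengths clamped to zero
and the deficit moved to the sister edge. A likelihood tree was deliberately
not embedded: the lettered orf138 haplotypes differ by a handful of
substitutions, where nearest-neighbour assignment is method-insensitive and
a distance tree shows the same grouping. The panel is user-supplied
configuration, not embedded truth.

## The simulator

`simulate_pair` builds a fertile maintainer circle (uniform base draw at the
target GC, default 45.26 %) with planted core genes, cuts it into blocks
(default six, three large, three small), and assembles the sterile circle as
a block permutation (default: the three large blocks order-consistent, the
three small ones translocated) with donor-derived unique segments inserted
at block junctions — by default the five published sizes
6291/7056/4225/5457/1715 bp, which also fixes the sterile genome length once
the maintainer length is chosen. A maintainer-only spacer (≈ 3.7 % of the
genome, floored at 2.5 kb so the layout stays resolvable at reduced test
scale) keeps maintainer-side coverage below 1, as in real pairs. Shared
blocks receive 0.5 % substitution noise — a choice, not a published value;
real corresponding blocks are stated only to exceed 99 % identity — applied
outside planted footprints. Unique-segment GC defaults to 46.41 %, the value
that makes the full-scale sterile circle hit its published overall GC.

Planted ORFs are realized as ATG + sense codons + TAA with an immediately
upstream in-frame stop (so the called ORF is exactly the planted one).
Transmembrane segments are 25-residue runs from {L,I,V,F} (windowed
hydropathy ≥ 2.8) separated by ≥ 12 residues so no bridging window can
cross the 1.6 threshold; non-TM positions draw from strongly hydrophilic
residues so no spurious window exceeds it. Two generator invariants make
candidate recovery well-posed: (i) the hydrophilic codon alphabet cannot
terminate the +1 reading frame, so periodic Leu-Glu breakers (CTA GAA) are
written into every planted ORF to place stops in the shifted and reverse
frames, and codon draws are rejected until no alternative frame is open for
≥ 90 codons; (ii) after assembly, any unplanned ORF > 100 aa with > 40 % of
its length in unique sequence is disrupted by an in-frame stop written
outside all planted footprints. Together these guarantee the manifest lists
exactly the sterile-specific long ORFs, for any seed. The chimeric ORF is
constructed by placing the atpA copy across the maintainer cut that the
rearrangement breaks, so its 5′ 40 % is genuine shared sequence and the
remainder continues into the unique region — the same mechanism thought to
create such ORFs in vivo. Donor genomes carry copies of the realized unique
regions (with 150 bp of exact junction flank, as expected when insertion
occurred by homologous recombination) plus planted substitutions at two
rates (round(3e-4·len) and round(5e-4·len) per region), making donor ranking
deterministic and scale-free. The haplotype panel takes the planted orf138
sequence as haplotype A and adds two substitutions per letter.

All randomness flows from one named generator (`numpy.random.default_rng`,
PCG64) seeded from the config; identical configs give byte-identical
genomes, manifests and report bundles.

### What the simulator does and does not emulate

It reproduces the *structure* of a maintainer/CMS pair — block permutation,
donor insertions at junctions, candidate ORFs with the published hallmark
features, realistic sizes and GC — so it validates interval logic,
screening rules and rotation handling end to end. It does not emulate
repeat-mediated multi-mapping (large mitochondrial repeats), indels between
shared blocks, RNA editing, substoichiometric mitotypes, or biologically
realistic codon usage; passing on simulated pairs therefore demonstrates
correctness of the comparison machinery, not robustness to repeat-rich real
assemblies, for which the accession-based check (tests/test_acceptance.py,
with the deposited records placed under data/accessions/) is the relevant
evidence.

### Problem sizes

Unit and property tests run on 20 kb three-block pairs and the 50 kb
default six-block pair; `scripts/acceptance.py` runs the full pipeline at
study scale (219,962 bp maintainer, 236,648 bp sterile). These sizes keep a
complete suite run and the acceptance script each under a minute on one CPU
while preserving every structural feature of the full-scale problem.

## Numerical and degenerate-input choices

* Alignment scoring is fixed at +2/−3/−5/−2 everywhere a score matters;
  identity = matches / aligned columns (internal gaps counted).
* gc_content excludes N from the denominator and is undefined (error) on
  all-N input; ambiguity codes other than N normalize to N with a warning,
  because anchoring is exact-match.
* Empty anchor lists, empty predictions, proteins shorter than the
  hydropathy window, and self-comparisons are all legal inputs with defined
  outputs (empty lists, zero recall, empty domain list, one full-circle
  block and no unique regions respectively).
* Ties: overlap trimming prefers the higher-scoring block, then plus
  strand, then lower query start; haplotype ties resolve alphabetically
  with a warning; donor ties resolve by matched bases then id.
* evaluate_recovery matches unique regions at reciprocal overlap ≥ 0.9 and
  candidate ORFs at same-strand reciprocal overlap ≥ 0.8; boundary error is
  the mean circular distance between matched boundaries.

## Known limitations

Anchor-based boundaries are quantized by k near substitutions, so region
boundaries can be off by up to ~k−1 bp (observed mean ≤ 3 bp at 0.5 %
noise). Identity within blocks is an anchor-based estimate, slightly
underestimating identity when substitutions cluster closer than k. The
co-transcription predictor is purely positional. The hydropathy TM scan is
not a topology predictor. Multi-copy repeats are resolved
highest-score-wins, which can misassign genuinely duplicated segments.
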