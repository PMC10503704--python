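# Methods

`splicetracks` composes multi-track figures of a single genomic window:
read coverage with splice-junction arcs (sashimi panels), continuous
signal, single-cell demultiplexed coverage, read-by-read long-read rows,
Hi-C contact triangles, and gene models with genome-projected protein
domains. This note records the models and conventions behind each stage,
the defaults that matter, and what the synthetic fixtures do and do not
show.

## Coordinates and region grammar

Internally every interval is 0-based half-open, matching BAM/BED
arithmetic. User-facing region strings are 1-based inclusive
(`chr1:1,000-2,000`, optional `:+`/`:-` suffix), matching genome-browser
habit; `parse_region` is the single conversion point. Strand `"."` means
unstranded and passes every strand filter. Chromosome-name dialects
(`chr1` vs `1`) are reconciled by one alias pass — literal name, then with
the `chr` prefix added or stripped — applied wherever a file's own naming
is consulted.

## Junction extraction and the coverage engine

A splice junction is identified with the intron it removes: the reference
span of the `N` operation in a read's CIGAR, stored half-open. This makes
junction identity independent of read ends and needs no annotation, so
novel junctions count exactly like known ones. During the CIGAR walk,
`M/=/X` and `D` extend the current aligned block (a deletion does not
split coverage), `N` closes it and emits the junction, and `I/S/H/P`
consume no reference. A CIGAR whose reference walk begins or ends with `N`
is treated as malformed; the read is skipped and counted.

Per-base depth counts passing reads whose blocks cover each window
position. `library_size` is the index-reported mapped-read total of the
whole file — not the window — so RPM/RPKM are window-independent:

    rpm  = depth * 1e6 / library_size
    rpkm = depth * 1e9 / (library_size * window_length_bp)

Junction counts stay raw integers under every normalization, since arc
labels report evidence (reads), not rates. Aggregation (`mean`/`sum`)
combines depth element-wise and junction counts over the key union with
absent = 0; mean junction counts are rounded half-up for display.

Default read filters keep everything: mapq ≥ 0, duplicate-flagged reads
retained for bulk (pipelines mark duplicates deliberately), secondary and
supplementary alignments dropped.

## PSI

The percent-spliced-in of a target exon is the junction-read estimator

    psi = inclusion / (inclusion + exclusion)

where inclusion counts junction reads whose acceptor equals the exon
start or whose donor equals the exon end (a read supporting both flanks
counts on both — standard junction-PSI practice), and exclusion counts
junction reads spanning the whole exon. With no informative junctions the
value is reported as undefined (`NA`), never raised. This estimator is a
package definition and is deliberately stated here because several
equally defensible variants exist (single-flank, exon-body reads).

## Single-cell demultiplexing

Reads are routed to cell groups through a user-supplied barcode → group
table (default tags `CB`/`UB`, both configurable). Within a group, reads
sharing `(barcode, UMI, leftmost position)` collapse to one molecule
before any counting. Position is in the default key so distinct fragments
with recycled UMIs survive; `dedup_on_position=False` gives the stricter
`(barcode, UMI)` key. Deduplication runs before strand splitting — strand
never enters the key — because a molecule's strand is a property of the
surviving read, not of the duplicate set. Reads with a barcode but no UMI
are kept without dedup and counted in a warning; unlisted or untagged
barcodes are dropped and counted, so the accounting identity
`used + dropped + collapsed = passing reads` always holds and is tested.

Transcribed strand is the alignment-flag strand, inverted for
reverse-stranded libraries; unstranded libraries put everything in the
sense track.

## Long-read rows

Each passing read becomes one row: aligned blocks (clipped to the window
for display) plus its full junction chain. "Exon sort" orders rows by the
lexicographic tuple of junction coordinates, then leftmost start, then
read id, with junction-free reads after all spliced ones — so reads with
identical exon-intron structure sit adjacent and isoforms emerge as
visual bands. The key is a total order, hence a pure, idempotent
permutation.

Poly(A) length comes from a numeric tag (default `pa`; no cross-basecaller
standard exists) with an optional fallback: the terminal 3' soft-clip
when its A fraction (T for reverse-strand reads, whose stored sequence is
reference-oriented) is ≥ 0.8. Base modifications come from the standard
MM/ML tag pair; an ML byte b maps to probability (b + 0.5)/256, MM
without ML is treated as probability 1.0 with a warning, and read bases
without a genomic image (soft clips, insertions) are dropped. Default
display threshold: probability ≥ 0.5.

## Signal and contact tracks

bigWig, bedGraph, and samtools-depth TSV all reduce to a per-base array
over the window; missing data is 0, not NaN, so signal panels render like
coverage. Unsorted bedGraphs are accepted with later lines overwriting
earlier ones. Contact matrices are read from the HiCExplorer h5 layout
(interval lists + CSR triplet); the sub-matrix of bins intersecting the
window is symmetrized by the element-wise maximum of the matrix and its
transpose, which passes an already-symmetric matrix through unchanged and
completes a stored triangle. Display applies log1p scaling by default.

## Protein-domain projection

Features live in 1-based inclusive amino-acid coordinates. Amino acid k
occupies CDS nucleotides [3(k−1), 3k) along the translation walk — 5'→3'
of the mRNA, i.e. right-to-left through the CDS blocks for minus-strand
transcripts — and that interval is mapped through the ordered CDS blocks,
splitting at introns. The projection is length-preserving (3 bp per
amino acid) and round-trips: every projected base maps back into the
feature's amino-acid interval. Both properties are tested against a
per-nucleotide brute-force map.

Before projection the CDS length is validated against the protein:
`cds_length == 3 * protein_length` enables the domain track. Annotation
dialects disagree on whether the stop codon sits inside CDS lines, so the
default validation also accepts `3 * (protein_length + 1)`; `strict=True`
enforces the bare threefold rule. A failing transcript simply gets no
domain track. When several proteins map to one transcript, the first that
validates wins and the rest are logged.

Feature sources are offline-first: a transcript→protein mapping file and
a per-protein features file are the primary, fully tested path. A live
REST layer (UniProt search + EBI protein features) exists behind the same
two-method interface with on-disk caching, but no test depends on the
network.

## Intron shrinkage

The x-axis runs through a piecewise-linear, strictly increasing map.
Exonic stretches (the merged exon union of all displayed transcripts)
keep unit scale; each inter-exon gap g maps to `max(ceil(g * scale), 1)`
plot units — the floor of 1 keeps the map strictly monotone at any scale.
Flanks of the window outside the outermost exons stay at unit scale: they
are not introns, and compressing them would distort the window edges.
Default scale when shrinkage is requested: 0.05; scale 1 is the exact
identity. Distances between positions inside one exon are invariant, and
this is tested.

## Rendering and reproducibility

One matplotlib panel per track over the shared transformed axis: filled
step coverage with quadratic junction arcs (height ∝ log(count+1), label
at apex, drawn when count ≥ threshold, default 1, with the PSI value
under the track label when requested); filled signal curves; block-and-
line read rows with red poly(A) bars and blue modification dots; a
45°-rotated triangular contact heatmap; gene models with thin exons,
thicker CDS, and pink domain segments behind the CDS; translucent
highlight spans crossing all panels. Output formats: png, pdf, tiff, svg,
with figure size in inches and DPI from the figure spec. Vector output is
byte-reproducible: the SVG hash salt is fixed and date/creator metadata
pinned, so identical inputs give identical files — also across serial vs
multi-process extraction, since workers only parallelize per-track reads
and results are reassembled in meta-file order.

## Synthetic fixtures: what they show and what they don't

`splicetracks.simulate` writes toy-scale files in every supported format,
each with a manifest computed from the construction parameters (never by
re-parsing the written file): ground-truth depth arrays, junction counts,
PSI, and dedup outcomes. Reads are exact — deterministic CIGARs, no
sequencing errors, no mismatches, no soft-clip noise beyond what a test
asks for — so passing tests demonstrate that extraction, accounting, and
geometry are correct, not that the tool is robust to aligner quirks,
degenerate CIGARs in the wild, or barcode sequencing errors (barcode
error correction is explicitly out of scope). Problem sizes are chosen
small — ~100-read BAMs, 20 randomized seeds, kilobase windows — because
every oracle here is exact, so scale adds runtime without adding
evidence.

## Known limitations

- GFF3 annotation, cool/mcool contact formats, and matrix balancing are
  unsupported (h5 input is assumed balanced upstream).
- PSI uses junction evidence only; exon-body reads do not contribute.
- The live domain API layer is best-effort and uncached failures raise;
  offline files are the supported path.
- Arc/label placement is aesthetic and not part of any contract; only
  byte-reproducibility of identical runs is guaranteed.
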