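# Methods

## The design procedure

The pipeline is deterministic end to end: read → catalog → design → overlap
→ write, with no randomness anywhere in the design path (the synthetic-data
generator is the only seeded component).

**Coordinates.** GFF3 1-based inclusive coordinates are used unchanged at
every stage — parsing, cataloguing, design arithmetic and output — so the
tables echo annotation coordinates verbatim and there is a single convention
to get right. All upstream/downstream reasoning is in *sense space*: the
strand read 5'→3' in the feature's direction of transcription. For a
minus-strand feature, "upstream" therefore means plus-strand positions
`end+1 … end+k`, reverse-complemented.

**Cataloguing.** Targets are selected from the annotation by type string
(`CDS`, `ncRNA`, `three_prime_UTR`/`3'UTR`, `tRNA` by default; extra
aliases such as pseudogene types are opt-in configuration, matching the
practice of treating pseudogenes and transposable elements as genes in
budding yeast). Segmented CDSs are merged to their outermost genomic
envelope, because a deletion cassette replaces the whole locus and the
geometry is defined on genomic, not spliced, coordinates. When a gene has
several transcripts, the transcript whose ID sorts first lexicographically
is used and the others are logged and dropped, so each gene yields exactly
one row. Groups mixing strands or chromosomes, and features without an
orientation (`.`/`?` strand), are skipped with a logged message — primer
geometry is undefined without a strand.

**Start/stop conventions.** The feature span is assumed to include the stop
codon. CDSs whose sense sequence does not begin `ATG` or end in
`TAA`/`TAG`/`TGA` (pseudogenes, annotation quirks) generate advisory
validation notes but are still designed; surfacing the violation is more
useful than silently repairing or excluding the locus.

**Arm extraction.** Homology length *N* is an absolute contract: arms are
never silently truncated. Positions beyond either chromosome end are padded
with uppercase `N`, symmetrically at both ends, so genes at telomere-
adjacent positions still receive length-*N* arms (orderable, with the
padding obvious to the user). *N* must be ≥ 4 because the CDS rules use
*N*−3 flank bases. The C-tag forward arm of a CDS shorter than *N*+3 simply
extends into genomic context upstream of the start codon; padding is applied
only at chromosome ends. When the arm would cross an annotated segment
boundary (intron within *N* bp of the stop), genomic sense context is used —
spliced-coordinate tagging is out of scope and the situation is visible in
the check file.

**Tails.** The constant 3' extensions are bit-exact constants
(`CGGATCCCCGGGTTAATTAA`, `GAATTCGAGCTCGTTTAAAC`, `GCGAATTTCTTATGATTTATG`);
they can only be changed through explicit configuration keys, never
silently. Tails always go at the 3' end of the long primer — homology 5',
priming site 3' — which is the orientation PCR chemistry requires for the
arm to anneal to the genome after extension from the vector template. The
3'UTR forward arm uses the non-coding homology rule (*N* bp upstream of the
UTR start) combined with the adh1-terminator tail; only the tail is fixed by
the vector design, so the homology geometry was an open choice and the
non-coding rule is the consistent one.

**Overlap reporting.** The disruption universe is the union of the CDS and
ncRNA catalogs on both strands. Overlap is closed-interval intersection of
spans on the same chromosome (`other.start ≤ target.end` and
`other.end ≥ target.start`); adjacency is not overlap. It is assessed on the
feature span only — the homology arms are regenerated by recombination — and
is strand-agnostic, since an antisense ncRNA is physically destroyed by the
deletion regardless of strand. All neighbours are reported, `;`-joined, with
their count; no fixed cap is imposed. Queries use an interval tree; the
all-pairs scan survives as the independent oracle in the tests.

**Outputs.** Every successful run writes exactly three tab-delimited UTF-8
files (header summary, primer database, check file), even for an empty
catalog; an XLSX mirror of the primer table is optional. All computation
happens before anything is written and partially written files are removed
on error, so a failed run never leaves a truncated primer database. The
check file's end-region length defaults to 30 bp — short enough to paste
into a browser search, long enough to be locally unique in a yeast genome.
Empty common names are rendered as empty fields, not `NA`, so sequences can
be pasted straight into ordering forms.

## Parameters

| parameter | default | meaning |
|---|---|---|
| homology length *N* | 80 bp (pombe preset), 50 bp (cerevisiae presets) | arm length; the organism conventions for efficient homologous recombination |
| feature type | — | CDS, ncRNA, 3'UTR (pombe annotations only) or tRNA |
| end region length | 30 bp | 5'/3' excerpt length in the check file |
| type aliases | none | extra annotation type strings to catalog (e.g. `pseudogene`) |
| tails | pFA6a constants | overridable only via explicit config keys |

The legacy CLI form takes three integers (genome 0–5, feature 1–4, *N*);
presets carry their organism's default *N* so the third argument may be
omitted — an ergonomic extension over requiring it, and logged when used.
Legacy and modern invocations resolving to the same configuration produce
byte-identical outputs.

## The synthetic-data generator

`yeastprimers.synthetic` plants features on random uniform-{A,C,G,T}
background across three chromosomes: ORFs written as `ATG` + non-stop codons
+ stop on either strand, plus ncRNA/3'UTR/tRNA spans annotated over
background. Every generated plan contains the cases that make indexing
arithmetic fail in practice: minus-strand genes, an intron-split CDS on each
strand, a nested antisense gene pair, a multi-transcript gene with a decoy
second transcript, overlapping ncRNAs, a gene starting at base 1 of a
chromosome and a gene flush with a chromosome end. Expected primers are
computed by a brute-force oracle that extracts a sense window (span ± *N*,
whole-window reverse complement for minus-strand features) and takes plain
substrings — deliberately different arithmetic from the engine's per-flank
genomic fetches, and sharing no code with it.

What the generator does **not** emulate: realistic yeast base composition,
intron statistics, UTR structure, ambiguity codes or assembly gaps. Passing
tests therefore demonstrate that the coordinate arithmetic, strand handling,
padding and file contracts are correct on annotations of realistic *shape*,
not that any particular published genome's annotation idiosyncrasies are
handled; for real genomes the check file exists precisely so users can spot-
verify against a browser.

Problem sizes: the routine suite uses a 40-feature genome (a few kb per
chromosome); the at-scale checks and `scripts/acceptance.py` use 520 planted
features (~560 with the overlap/decoy extras, ~40 kb per chromosome) and
check every primer at *N* ∈ {4, 6, 50, 80} — small enough to regenerate in
under a second, large enough to hit every special case many times.

## Known limitations

* GFF3 only; GFF2/GTF dialects and compressed inputs are unsupported
  (adapters are the user's responsibility).
* No melting-temperature optimisation, primer-dimer or off-target screening;
  the method is purely positional, as is conventional for pFA6a-style long
  primers. BLAST verification of a finished database is an external step.
* No N-terminal tagging or promoter-swap primers; no UTR inference when the
  annotation lacks UTR features; no splice-aware tagging across introns.
* The 3'UTR feature class is only meaningful where the annotation provides
  `three_prime_UTR` records (the pombe reference annotation does; the
  cerevisiae ones used with the legacy presets do not, hence the preset
  restriction).
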