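# yeastprimers

Batch design of the long PCR primers used to delete or C-terminally tag
features in yeast genomes.

In *Schizosaccharomyces pombe* and *Saccharomyces cerevisiae*, genes are
knocked out or tagged by transforming cells with a PCR product — a selectable
marker (or tag) amplified from a pFA6a-series template vector — whose ends
carry short regions of homology (50–100 bp) to the target locus. Homologous
recombination then replaces the target span with the cassette. The primers
for these PCRs are "long primers": a homology arm copied from the genome at
the 5' end, and a constant vector priming site at the 3' end. Designing them
by hand is mechanical but error-prone at scale; this package designs them for
**every** annotated CDS, ncRNA, 3'UTR or tRNA in a genome in one run, from a
genome FASTA and its GFF3 annotation.

## Primer geometry

For a feature of homology length *N* (all coordinates in sense space, i.e.
read in the feature's direction of transcription):

| primer | CDS rule | non-coding rule |
|---|---|---|
| deletion forward | ATG + (*N*−3) bp upstream of the start codon | *N* bp upstream of the feature |
| C-tag forward | *N* bp immediately 5' of the stop codon (in-frame fusion) | — |
| reverse (shared) | revcomp(stop codon + (*N*−3) bp downstream) | revcomp(*N* bp downstream) |

Untailed arms always have length exactly *N*; flanks that run past a
chromosome end are padded with `N` characters. Each arm is also provided
with its constant 3' vector tail:

* forward (deletion and tagging): `CGGATCCCCGGGTTAATTAA` (20 nt, pFA6a MCS)
* reverse: `GAATTCGAGCTCGTTTAAAC` (20 nt, pFA6a MCS)
* 3'UTR forward: `GCGAATTTCTTATGATTTATG` (21 nt, primes the adh1 terminator,
  so a gene whose 3'UTR is deleted keeps a terminator)

Conventional arm lengths are *N* = 80 for *S. pombe* and *N* = 50 for
*S. cerevisiae*; because yeast genomes are compact, every deletion target is
also annotated with the neighbouring CDSs/ncRNAs whose spans intersect the
deleted span.

## Worked example

The package ships a seeded synthetic-genome generator, so the pipeline can
be exercised without downloading a real genome:

```sh
python -c "
from yeastprimers import FixtureSpec, generate_synthetic_genome
generate_synthetic_genome(FixtureSpec(seed=7, n_features=40)).write('.')
"
yeastprimers design --genome genome.fa --annotation annotation.gff3 \
    --feature cds --organism pombe --out demo
```

This prints `designed 32 primer sets (CDS, N=80) -> demo_primers.tsv` and
writes three tab-delimited files. `demo_header.txt` summarises the run —
genome label, feature type, homology length, one line per chromosome with
its length, and the feature count:

```
Genome: custom
Feature type: CDS
Homology length (bp): 80
Chromosomes: 3
  chrI	3091
  chrII	3899
  chrIII	2751
Features analyzed: 32
```

`demo_primers.tsv` has one row per gene with its coordinates (1-based,
echoed unchanged from the annotation), strand, all primers tailed and
untailed, and the overlap report. The first gene starts at base 1 of chrI,
so its 80-mer deletion-forward arm is 77 padding `N`s followed by its start
codon — the length contract holds even at chromosome ends:

```
systematic_name  common_name  chromosome  start  end  strand ...
SYNG0001         edg1         chrI        1      42   +      ...
```

with `deletion_fwd` = `NNN…NNNATG` (80 nt). `demo_check.tsv` lists each
feature's 5' and 3' end regions (30 bp by default) and its full sense
sequence for manual verification in a genome browser.

The same run in the legacy three-integer form (genome preset 0 = pombe,
feature 1 = CDS, N = 80), with a config file mapping the preset to local
files, produces byte-identical output:

```sh
yeastprimers -c presets.cfg 0 1 80
```

For a real genome, point `--genome`/`--annotation` at the organism's
reference FASTA and GFF3 (e.g. from PomBase or SGD).

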