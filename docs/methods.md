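# Methods

## The problem

Genome annotation marks which regions are believed to code for protein,
but the evidence is mostly transcriptional or comparative, not direct
measurement of proteins. Whole-genome proteogenomic mapping closes that
gap: tandem mass spectra of tryptic peptides are searched not only against
an annotated protein set but also against every translation the genome and
the transcriptome could in principle produce. A peptide confidently
identified from the six-frame genome translation but absent from the
protein database is direct translational evidence for an unannotated
region. `pgmap` implements this workflow end to end on any genome,
together with a synthetic-data generator so the whole pipeline is testable
without external downloads.

## Database construction

Genomes are translated in all six reading frames (three codon offsets per
strand, standard genetic code); transcript sets (sense-strand mRNA) in the
three forward frames; protein FASTA records are used as-is. Each stop
codon ends one searchable entry and the next begins after it, so entries
are maximal stop-free fragments of a frame translation. Every entry keeps
(source id, strand, frame, offset of its first residue within the frame
translation), which makes the genomic back-projection of any peptide an
exact arithmetic operation rather than a re-alignment.

Codons containing N translate to `X`, and `X` splits entries exactly like
a stop. This keeps ambiguous sequence out of the peptide space entirely;
the alternative (expanding ambiguity codes) would create candidates whose
identification could never be verified against the genome.

Frame convention: frame *f* on the plus strand starts at 0-based base *f*;
on the minus strand, at base *f* of the reverse complement. The locus of a
peptide at codon offset *a* of a minus-strand frame is therefore
`end = L − (f + 3a)`, `start = end − 3·len` on the forward coordinate
system of a chromosome of length `L`. Every mapped locus is required to
retranslate (reverse-complemented when on the minus strand) to exactly the
peptide sequence; this round trip is asserted throughout the test suite
and is the module's central invariant.

Decoy databases reverse each target entry. Reversal preserves entry count,
length distribution and amino-acid composition, so decoy peptide candidates
are statistically exchangeable with false target candidates, which is the
assumption the FDR estimate rests on.

## Digestion and candidate indexing

Tryptic digestion cuts after K or R, suppressed before proline (standard
trypsin specificity; configurable). Products with up to one missed internal
cleavage site (default, configurable) and length 6–50 are kept. The length
bounds are a practical choice: shorter peptides are statistically
unidentifiable in a genome-scale search and only inflate the index.
Monoisotopic residue masses and the water/proton constants come from
pyteomics; peptide mass = residue sum + water. Peptides are held in a
mass-sorted array index supporting O(log n) precursor-window queries.
Identical sequences from different parents are deliberately kept apart so
the number of genomic sites per peptide remains recoverable; deduplication
happens only at reporting time. I and L are treated as distinct residues
throughout.

## Spectrum matching and scoring

Spectra are read from MGF (multi-spectrum; malformed blocks are skipped
with a warning) or dta (one spectrum per file; first line is the (M+H)+
mass and charge). The precursor tolerance (default 0.02 Da) is applied on
the neutral monoisotopic mass; the fragment tolerance defaults to 0.5 Da.
Spectra without a charge state are tried at 2+ and 3+ and the better match
is kept.

The scorer models CID fragmentation with singly-charged b- and y-ions. For
a candidate peptide of length n there are 2(n−1) theoretical fragments; k
of them are matched when an observed peak lies within the fragment
tolerance, with each observed peak consumable at most once (ties resolved
greedily, smallest mass error first — deterministic because peaks are
mz-sorted on load). With per-fragment random match probability
q = 2·tol·n_peaks/span (capped at 0.99), the score is
−log10 P(Binomial(2(n−1), q) ≥ k). The scorer sits behind a registry so a
different peptide–spectrum scoring function can be substituted without
touching the search driver. Neutral losses, multiply-charged fragments and
intensity weighting are deliberately out of scope.

## E-values

Each spectrum's candidate scores provide their own null model. The
survival count N(≥s) is fitted with a least-squares line in
(s, log10 N) and extrapolated to the top score: E = 10^(a·s_top + b),
the expected number of random candidates scoring at least that well.
Two numerical choices matter:

* The fit region runs from the median score down to the 5th-highest
  score, and the survival function is evaluated on an even grid of 12
  score values across that region rather than at each distinct observed
  score. Candidate scores cluster at discrete matched-fragment counts;
  sampling on a score grid makes the fit track the decay per unit score
  instead of the local density of tied values. This choice was validated
  on null simulations: the fraction of noise-spectrum searches with
  E ≤ 0.1 is statistically indistinguishable from 0.1 (the package's
  E-value calibration test).
* A 0.02 Da precursor window over a desk-scale database often holds fewer
  than 20 candidates, too few for any tail fit. The search therefore
  scores an additional *calibration set* drawn from a deterministically
  widened mass window (doubling from ±1 Da until 128 sequences or the
  whole index, even-subsampled to at most 256). Calibration candidates
  only feed the null fit; reported PSMs always come from the true
  precursor window. If even the widened window is short, the E-value
  falls back to the empirical count of candidates at or above the score,
  and a degenerate (all-equal or rising) fit falls back the same way.

## Per-database FDR

Target and decoy databases are searched separately with identical
configuration. For a threshold t, FDR(t) = (decoy rank-1 PSMs with E ≤ t)
/ (target rank-1 PSMs with E ≤ t); the threshold for a requested FDR
(default 1%) is the largest t with FDR(t) ≤ the target, with E-value ties
at the threshold counted against it (a tied decoy tightens the threshold).
Thresholds are estimated per database: a six-frame genome database is
orders of magnitude larger than a protein set, its score null is heavier,
and a shared threshold would be meaningless. FDR is computed on rank-1
PSMs; ranks 2–3 (kept for track export, default max rank 3) inherit their
database's threshold.

## Reconciliation

After per-database filtering, each spectrum keeps only its best-scoring
rank-1 peptide across the three searches. Spectra whose rank-1 peptides
agree keep all attributions; conflicts remove the lower-scoring hits,
tallied per losing database. Score ties prefer protein over transcript
over genome — the smallest database has the best-calibrated statistics.
Distinct peptide sets are compared as a three-set Venn partition.
Peptides found only by the transcript search are triaged against the
annotation in precedence order: *frameshift* (translated frame differs
from the annotated CDS frame), *noncoding transcript* (parent has no
coding annotation), *UTR/boundary* (in-frame but reaching outside the
CDS); anything else, including transcripts missing from the annotation,
is reported unclassified.

## Genomic classification and tracks

All internal coordinates are 0-based half-open; GTF input is converted on
read, BED output stays 0-based. A peptide is *unique* when its sequence
maps to exactly one genomic locus; unique loci are classified *exonic* on
≥1 bp overlap with any annotated exon, else *intronic* when inside any
transcript's span (strand-ignorant, min exon start to max exon end), else
*intergenic*. Arbitrary BED evidence tracks can be tallied against loci
(per-track overlap counts, union of intersections, central intersection).
BED6 export encodes the E-value in the score column as
min(1000, −100·log10 E), so taller browser bars mean stronger
identifications, with one record per (locus, rank).

## The synthetic world

The generator emulates the study conditions at desk scale. On a random
background genome it plants non-overlapping genes on both strands
(default 40 genes in 1 Mb, 2–5 exons each, 20% non-coding), builds the
spliced transcript and translated protein for each coding gene
(cross-consistency is asserted by independent re-extraction), and embeds
additional tryptic ORFs in intergenic space and inside introns (15% and
5% of planted peptides) to exercise the genome-only discovery scenario.
Planted peptides are chosen so one flanking codon on each side sits in the
same exon, making each one discoverable by the six-frame search with its
tryptic context intact.

Spectra are b/y-ion lists with Gaussian m/z jitter (default sd 0.1 Th),
peak dropout (default 0.2), 5 uniform noise peaks, and a small neutral
precursor-mass jitter (sd 0.003 Da, Orbitrap-like, i.e. well inside the
0.02 Da window). Hard-null noise spectra (default 10% of the total; 50% in
the FDR stress tests) draw their precursor masses from the planted mass
distribution so they always have real candidates — the most adversarial
null for FDR calibration. All randomness flows through named substreams
of a single seed (background, gene content, planted ORFs, spectra, in that
fixed order), so outputs are byte-reproducible and adding an output never
perturbs earlier ones.

What the simulator does *not* model: realistic intensity profiles,
retention time, chimeric spectra, modified residues, splice-junction
peptides (excluded from planting by construction), sequence homology and
repeat structure of real genomes. Passing tests therefore demonstrate the
correctness and calibration of the machinery, not instrument-level
performance on real data; in particular, real genomes' repetitive content
would raise the multi-mapping rate well above this simulator's.

## Problem sizes used in the checks

The automated checks run at sizes chosen to exercise each property
meaningfully on a single CPU: database-construction oracle equivalence on
100 random 10 kb sequences; recovery on five seeded 1 Mb worlds (≥95% of
planted peptides at 1% FDR); FDR calibration pooled over twenty 60 kb
null-spiked worlds (observed FDP ≤ 2× nominal); E-value null calibration
over 1,000 searches; database-size sensitivity at 1×/10×/100× inflation
(residue-shuffled, mass-preserving padding) over five seeds.

## Known limitations

* The binomial scorer is intentionally simple; a probabilistic or
  learned scorer can be registered in its place but none ships here.
* Transcript-search peptides are projected to the genome only through the
  annotation's exon structure; transcripts absent from the annotation are
  reported in transcript space.
* Splice-aware genome database construction (peptides across exon
  junctions in genome space) is out of scope; junction peptides are only
  reachable through the transcript database.
* FDR estimation uses the classic decoy/target ratio; no rescoring or
  semi-supervised post-processing.
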