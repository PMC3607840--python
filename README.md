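# pgmap — whole-genome proteogenomic mapping

`pgmap` searches tandem mass spectra (MS/MS) of tryptic peptides against
three databases at once — an annotated **protein** set, a 3-frame
translation of the **transcriptome**, and a full 6-frame translation of
the **genome** — and maps every confident identification back to
chromosome coordinates. Peptides found by the genome search but missing
from the protein database are direct, measured evidence of translation
outside the current annotation (new exons, new isoforms, translated
"non-coding" regions). The package is aimed at proteogenomics and genome
annotation groups who want this workflow on arbitrary genomes, with a
built-in synthetic-data generator so everything can be exercised and
validated without any external dataset.

## The method

* **Databases.** Six-frame genome / three-frame transcript translation
  under the standard genetic code; each stop codon ends one searchable
  entry and the next begins after it. Entries carry (source, strand,
  frame, offset), so an identified peptide's genomic locus is exact
  arithmetic: `start = f + 3a`, `end = start + 3·len` on the plus strand
  (mirrored on the minus strand), where `a` is the peptide's codon offset
  in frame `f`. Decoy databases reverse each target entry.
* **Digestion.** Tryptic (cut after K/R, not before P), ≤1 missed
  cleavage, length 6–50, monoisotopic masses, no modifications.
* **Matching.** Candidates within ±0.02 Da of the neutral precursor mass
  are scored by b/y-ion matching at ±0.5 Da: with `k` of `n = 2(len−1)`
  fragments matched (each observed peak used at most once) and a
  per-fragment random match probability `q` from peak density, the score
  is `−log10 P(Binom(n, q) ≥ k)`.
* **E-values.** Each spectrum's candidate score distribution is its own
  null: a least-squares line through the tail of `log10 N(≥s)` is
  extrapolated to the top score, giving the expected number of random
  candidates at least that good.
* **FDR.** Separate target and decoy searches per database; the E-value
  threshold is the largest `t` with `#decoy(E≤t) / #target(E≤t)` at or
  below the requested rate (default 1%), estimated **per database** —
  a six-frame genome needs a very different threshold than a protein set.
* **Reconciliation.** Each spectrum keeps its best-scoring peptide across
  the three searches; conflicts are removed from the losing databases and
  tallied. Distinct peptides are compared as a 3-set Venn partition.
* **Annotation.** Unique-locus peptides are classified exonic / intronic /
  intergenic against a GTF, tallied against arbitrary BED evidence
  tracks, and exported as BED6 with `score = min(1000, −100·log10 E)`.

## Worked example

Simulate a 100 kb world with 6 planted genes (plus intergenic and
intronic ORFs), search the spectra against the genome and protein
databases, reconcile, and export tracks:

```bash
pgmap simulate --out demo --seed 5 --genome-length 100000 --n-genes 6
pgmap search --spectra demo/spectra.mgf --fasta demo/genome.fasta \
             --db-kind genome  --out-psms demo/genome_psms.tsv
pgmap search --spectra demo/spectra.mgf --fasta demo/proteins.fasta \
             --db-kind protein --out-psms demo/protein_psms.tsv
pgmap reconcile --psms demo/genome_psms.tsv --psms demo/protein_psms.tsv \
                --out-dir demo/rec
pgmap annotate --psms demo/genome_psms.tsv --genome demo/genome.fasta \
               --gtf demo/annotation.gtf --out-bed demo/tracks.bed
```

which prints:

```
genome: 50 spectra identified at 1% FDR (threshold 1.52e-05)
protein: 40 spectra identified at 1% FDR (threshold 4.29e-08)
reconciled 50 spectra; removals {'genome': 0, 'protein': 0}
unique peptides: 25; classes: {'exonic': 21, 'intergenic': 3, 'intronic': 1}
```

Reading the numbers: the genome search identifies 50 spectra at 1% FDR —
more than the protein search's 40, because the intergenic/intronic planted
peptides are invisible to the protein database. The genome threshold
(1.5e-05) is far looser than the protein threshold (4.3e-08): the 1% FDR
is held per database, and the vastly larger six-frame search space needs
a different cut. All 50 reconciled spectra agree between the two searches
(no removals), and of the 25 unique-locus peptides, 4 fall outside
annotated exons — the genome-only discoveries. A PSM row and a BED record
look like:

```
sim|pep0|0  LPIYLHNPTSWEPFR  1868.957  35.72  2.34e-19  1  genome  False  chrS1|-0|32267@19
chrS1  2896  2929  WEYVVNQITTK|1|genome  1000  -
```

The parent field `chrS1|-0|32267@19` pins the peptide to minus-strand
frame 0 at codon offset 32267+19, from which the BED interval is computed
and verified by retranslation.

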