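# decoygen

**Realistic artificial intergenic DNA sequences as negative controls for
genome-analysis tools.**

Evaluating the false-positive rate of a gene predictor, repeat finder or
motif scanner requires "background" sequence that is guaranteed to
contain no functional elements yet looks like real genomic DNA.
Commonly used stand-ins fall short: presumed-intergenic regions may hide
unannotated functional elements and are finite, while dinucleotide-
preserving shuffles destroy the interspersed-repeat landscape that
dominates vertebrate genomes and so underestimate false-positive rates.

`decoygen` generates an inexhaustible supply of artificial decoy
sequences modeled on the *unconstrained* intergenic fraction of a
genome. It is a library plus a small CLI, aimed at people benchmarking
repeat detectors, *ab initio* gene predictors, or any tool whose
significance estimates need a realistic null.

## The model

**Training.** Annotated genes, pseudogenes, CpG islands, conserved
elements, interspersed repeats and tandem repeats are masked out of a
reference genome. On the remaining "base" sequence:

* local G+C content is computed in non-overlapping 1 kb windows and
  averaged over 10 kb sections; each window is assigned to one of five
  GC bins (default boundaries 37%, 39%, 42%, 45% G+C);
* per GC bin, the empirical continuation probabilities
  P(x<sub>i</sub> | x<sub>i−k</sub> … x<sub>i−1</sub>) of each k-mer
  (default k = 4) are tabulated;
* a row-stochastic matrix of GC-bin transitions between adjacent
  windows is estimated.

Each interspersed repeat annotated by RepeatMasker contributes the
joint tuple *(length, % divergence, % insertion, % deletion, fragment
count, GC bin)* to its family's empirical model, kept alongside the
family consensus; tandem repeats from Tandem Repeat Finder are modeled
the same way, keyed by their monomer. The frequency with which one
family interrupts another is tabulated as a nesting table.

**Generation** has two stages. First a base sequence is produced: a
GC-bin series is sampled from the transition chain and the sequence is
extended base by base from the per-bin k-mer tables. Second, the base
sequence is bombarded with repeats: instances are bootstrap-sampled
from the family models, each is *artificially evolved* from its
consensus (trim to the annotated length — 5′-truncation for LINEs —
then deletions, transitions/transversions at ti:tv = 2, and insertions,
with counts set by the sampled percentages), and spliced in at a random
position whose local GC bin matches the instance's, on a random strand,
**oldest first** (divergence from consensus proxies age). Every
mutation event is logged, so each repeat's construction is exactly
replayable, and the emitted annotation is byte-exact ground truth.

**Validation** is alignment-free (generated sequences are unique by
construction). Each sequence is summarized by composition measures

> gc = (n_G+n_C)/N,  gcs = (n_G−n_C)/(n_G+n_C),  cpg = n_CG/(n_G·n_C)

and complexity measures: Wootton–Federhen complexity
cwf = (1/N)·log₄(N!/∏nᵢ!), symbol entropy ce, word entropies cm and
linguistic complexities cl at word lengths 6/8/12, and zlib
compressibility cz. Descriptor matrices are z-scored and compared by
PCA and by PAM (k-medoids, k = 3) clustering with the mean silhouette
as the diagnostic: artificial sequences should *mix* with real
intergenic ones, while shuffled sequences are devoid of repeats.

## Worked example

The bundled fixture generator means no downloads are needed:

```bash
decoygen fixtures --outdir fix --length 200000 --seed 1
decoygen train --genome fix/genome.fa --mask fix/genes.bed \
    --rm-out fix/repeats.out --trf fix/simple.dat \
    --consensus fix/consensus.fa --out model.dg
decoygen generate --model model.dg --length 100000 \
    --repeat-fraction 0.5 --seed 42 --out-prefix run1
decoygen shuffle --fasta run1.fa --window 1000 --seed 42 \
    --out run1.shuffled.fa
```

prints (abridged):

```
INFO decoygen: trained on 200000 bases, retained fraction 0.820, 4 repeat families
INFO decoygen: generated 100700 bases, 57 repeat records, realized fraction 0.503 -> run1.fa
```

i.e. 82% of the toy genome survived masking and was used for training;
the generated sequence realizes 50.3% repetitive content against the
requested 50%. `run1.fa` is the sequence; `run1.bed` / `run1.out` are
the ground-truth repeat annotation (BED and RepeatMasker dialect):

```
artificial_seed42   1818    3318    TLINE1|23|0   0  +
artificial_seed42   8552   10052    TLINE1|17|0   0  -
```

`run1.mutations.tsv` logs every trim/deletion/substitution/insertion
used to build each repeat, and `run1.provenance.json` records the seed
and a config hash. Comparing 20 kb pieces of the artificial and the
shuffled sequence:

```bash
decoygen evaluate --fasta pieces.fa --fasta pieces_shuf.fa \
    --labels artificial,shuffled --clusters 3 --out metrics.tsv
# INFO decoygen: PCA explained variance ratios: [0.652, 0.254, 0.062]
# INFO decoygen: PAM k=3 mean silhouette: 0.373
```

`metrics.tsv` holds the full descriptor matrix (gc, gcs, cpg, cwf, ce,
cm_6/8/12, cl_6/8/12, cz) per sequence.

## Scope

Trained models for real species are not shipped; train on any genome
by supplying a FASTA, BED masks, RepeatMasker `.out`, TRF `.dat` and a
consensus library (RepBase-style headers accepted). Satellite and
telomeric repeats are not modeled — they arise by a generative process
different from transposon propagation — and third-party predictors are
not run by this package; it produces the benchmark sequences and truth
files they are evaluated against.
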