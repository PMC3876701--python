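# phagecensor

Error analysis for deep-sequenced phage-display peptide libraries, built on
an operator view of library preparation and sequencing.

## The problem

A phage-display library of 7-mer peptides is read out by amplicon
sequencing of the 21-nt DNA insert that encodes each peptide (flanked by a
constant adapter and the 12-nt region encoding the GGGS linker — a 33-nt
analysis window per read). Copy numbers in such libraries span many orders
of magnitude, so every manipulation that takes a subset of the molecules —
including discarding reads during Phred-quality filtering — perturbs the
observed copy-number vector **n**. The central question this package
answers: *when a quality filter removes reads, did it remove them at
random, or did it censor specific sequences?*

## The model

A library is a multiset: an ordered set of unique sequences with a
copy-number vector **n** (`sum(n)` = m total reads, `uni(n)` = observed
diversity, out of N = 20^7 possible peptides). Random removal of a
fraction of reads is the stochastic sampling operator **Sa**: drawing
`round(f·m)` of the m read instances uniformly without replacement, so the
sampled vector follows the multivariate hypergeometric law. If filtering
from library `n_before` to `n_after` were unbiased, then with
f = sum(after)/sum(before),

    n_after = Sa_f(n_before),

and every sequence's post-filter count lies (with known probability)
inside a Monte-Carlo band [loC, hiC] obtained by applying **Sa** k times
(default: min/max over k = 10,000 draws). Sequences that fall below loC
were censored; the censorship operator is the diagonal matrix **CEN** with

    B_ii = n_after,i / (f · n_before,i)   if n_after,i < loC_i,
    B_ii = 1                              otherwise,

so 1/B_ii is the fold-loss attributable to sequence-specific error.
Sequences with fewer than 10 reads before filtering are too sparse to
distinguish random loss from censorship and are reported as undetermined.

The package implements the full chain: FASTQ ingest with perfect-adapter
matching and Phred+33 decoding; min-Phred / cumulative-accuracy / combined
filtering over the 33-nt window; the sampling operator with an exact
small-multiset enumeration oracle; Monte-Carlo confidence bands; the
censorship detector; and a synthetic-data generator that plants censorship
with known ground truth.

## Worked example

Simulate a 200-sequence library (copy numbers log-uniform in 20..2000,
five sequences censored, 10% of reads randomly degraded), filter it at two
Phred cutoffs, and detect the censorship:

```sh
phagecensor simulate --n-unique 200 --copy-law log_uniform:20:2000 \
    --n-censored 5 --degraded-rate 0.1 --seed 42 \
    --out demo.fastq --truth truth.csv
phagecensor filter demo.fastq --min-phred 1  --out n1.txt
phagecensor filter demo.fastq --min-phred 13 --out n13.txt
phagecensor censor --before n1.txt --after n13.txt -k 5000 --seed 1 --out cen.csv
```

The stages log their multiset accounting and the detector reports:

```
[simulate] sum=80921 uni=200
[filter:min_phred] sum=80921 uni=200
[filter:min_phred] sum=72071 uni=200
[censor] f=0.890634 censored=5 -> cen.csv
```

The measured surviving fraction f = 0.89 reflects the 10% random read
degradation; all five planted censored sequences are flagged. The report
ranks them by censorship strength (smallest B = strongest loss first):

```
sequence,peptide,before,after,expected,loC,bias,fold_loss
CAGAGTTCTGCACGTAGTTCA,QSSARSS,27,1,24.047120030647175,16,0.041585021354970435,24.047120030647175
TCTGATAGTACCTAGCAGTGA,SDST*Q*,168,21,149.62652463513797,132,0.1403494470730252,7.125072601673237
```

Read the first row as: this insert had 27 reads before filtering, random
sampling at f = 0.89 would leave at least 16 (loC), but only 1 survived —
a 24-fold loss, far beyond sampling noise. Estimates for low-copy
sequences are noisy (this one was planted with B ≈ 0.17); for well-counted
sequences the recovered B converges to the planted value.

`phagecensor enumerate` prints the exact outcome distribution of the
sampling operator on small libraries — e.g. the toy library
{A(1) B(2) C(3) D(4)} half-sampled has exactly 22 possible outcome
vectors — and `phagecensor ci` exports confidence bands as CSV.

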