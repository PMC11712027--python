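# tapscan

Genome-wide annotation of **transcription-associated proteins (TAPs)** —
transcription factors (TFs), transcriptional regulators (TRs) and putative
TAPs (PTs) — from profile-HMM searches, plus inference of TAP family
**gains, losses, expansions and contractions** on a species tree.

The package is aimed at comparative plant genomicists: given the
`hmmsearch --domtblout` table of a proteome scanned against a TAP domain
profile collection, it assigns each protein to a TAP (sub)family by a
curated rule set; given a family × species count matrix and a species tree,
it reconstructs ancestral family sizes and classifies every change along
the tree.

## Method

**Classification.** A protein's candidate domains are the `hmmsearch` hits
that survive two filters:

* *gathering threshold* — the full-sequence bit score must satisfy
  `score ≥ GA(domain)`; scores strictly below the per-domain reference are
  discarded;
* *coverage cutoff* — per (sequence, domain) the union of the HMM-coordinate
  intervals of all domain rows must cover at least a fraction `c` of the
  profile's match states (default `c = 0.75`).

Each family rule is a conjunction of *should* clauses over domains (a
clause may be a one-of-two disjunction), a set of *should-not* domains, and
optional *best-of* pairs in which only the higher-scoring domain counts.
Subfamily rules nest under a parent family (the deepest matching rule
wins and supplies the subfamily label), and merge rules pool several
detection routes under one output family (e.g. the four bZIP rules).
Three outputs are written: per-sequence assignments with domain evidence
(output 1), per-family counts over the full 138-family catalog (output 2),
and the subfamily-differentiated table (output 3). The packaged rule set
annotates **138 TAP families using 155 domains** (91 TF / 41 TR / 6 PT);
it is a synthetic reconstruction of the published v4 catalog (see
`docs/methods.md`).

**Evolutionary events.** For each family with counts
$n_s$ at the leaves, ancestral counts minimise the asymmetric Wagner
parsimony criterion

$$\sum_{\text{branches } (u,v)} \big[\, g\,\max(0, n_v - n_u) + \ell\,\max(0, n_u - n_v) \,\big]$$

with per-unit gain penalty $g$ and loss penalty $\ell$ (defaults
$g=\ell=1$; branch lengths are ignored). The optimum is found by a two-pass
dynamic program over the bounded state space $0..\max_s n_s$; co-optimal
states resolve to the smallest count. Each branch change is then labelled
gain ($0 \to {>}0$), loss (${>}0 \to 0$), expansion or contraction (both
ends $\ge 1$), and totals are reported per node and tree-wide.

Family-size comparisons between two species groups use Shapiro–Wilk-gated
two-sided tests (Welch *t* when both samples look normal, Wilcoxon
rank-sum otherwise) with Benjamini–Hochberg correction across families.

## Worked example

Classify a single HMMER hit against the packaged rule set — an *HRT*
domain hit 7.3 bits above its gathering threshold, spanning the whole
80-state profile:

```bash
$ tapscan classify --domtblout one.domtblout --out ethit
$ head -2 ethit/output1.tsv
seq_id  family  domains
AT5G56780.1     ET      HRT:26.8:1.000
```

The protein is assigned to the ET family (either of the HRT and GIY_YIG
domains suffices); `output2.tsv` reports `ET 1` among 138 family rows, the
other 137 at zero. The evidence column reads `domain:bitscore:coverage`.

Infer family events on a tree from a count matrix (here a simulated matrix
with a recorded true history):

```bash
$ tapscan simulate counts --tree tree.nwk --n-families 50 --seed 8 --out sim
$ tapscan events --tree tree.nwk --counts sim/counts.tsv --out ev
{"gain": 0, "loss": 13, "expansion": 4, "contraction": 0}
$ head -3 ev/branch_events.tsv
node    family  event   parent_count    child_count
MARPO   FAM008  loss    1       0
MARPO   FAM010  loss    1       0
```

The JSON line is the tree-wide total over all families;
`node_totals.tsv` breaks the totals down by the branch leading to each
node, and `ancestral_counts.tsv` holds the reconstructed family sizes at
every internal node.

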