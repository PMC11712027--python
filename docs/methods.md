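# Methods

## Scope and data model

The package annotates transcription-associated proteins (TAPs) by rules
over protein domains detected with profile HMMs, and analyses TAP family
evolution on a species tree. It operates downstream of `hmmsearch`: the
unit of input is the per-domain tabular output (`--domtblout`), never raw
sequences, so the profile-HMM search itself (and HMM construction) stays
outside the package. An optional `search` subcommand shells out to an
external `hmmsearch` binary when one is installed; nothing else depends on
it.

## Hit filtering

Two filters precede rule evaluation.

**Gathering threshold (GA).** Each profile carries a reference bit score;
hits whose *full-sequence* bit score is strictly below it are discarded.
Values exactly at the threshold pass ("lower than" is read strictly). The
GA filter deliberately uses only the full-sequence score — no per-domain
score or i-E-value filtering is performed, so split domains cannot be
penalised twice. A score-ordered TSV report (descending sequence bit
score, ties by sequence id, with the `acc` mean-posterior column) supports
the manual curation workflow by which GA thresholds are chosen: the
threshold is set where the aligned motif starts to deviate from the
better-scoring sequences.

**Coverage cutoff.** For each (sequence, profile) pair the union of the
`[hmm_from, hmm_to]` intervals over all domain rows must cover at least
the profile's cutoff fraction of its match states (default 0.75; per-profile
overrides come from the coverage file). The union — rather than the best
single domain — was chosen so that one true domain split by the aligner
into fragments is not unfairly discarded; `--coverage-mode best` switches
to single-best-interval coverage for comparison. Groups exactly at the
cutoff pass. Because the full-sequence score is a property of the
(sequence, profile) pair, both filters are per-group predicates: they are
idempotent and commute, which the test suite checks on randomized
fixtures.

Coordinates are 1-based inclusive throughout, following HMMER conventions.

## Rule grammar and the packaged catalog

A family rule consists of required clauses (each satisfied by at least one
member domain; `A|B` encodes one-of-two), forbidden domains (`!X`),
best-of pairs (`A>B`: when both are detected only the higher full-sequence
score counts; an exact tie keeps the first element), an optional parent
family (subfamily nesting) and an output label (merge rules such as
bZIP1→bZIP). The on-disk dialect is a line-oriented TSV documented in
`tapscan/rules.py`; profile metadata (GA threshold, match-state count,
coverage override, origin class) lives in a companion TSV.

Per sequence, every rule is evaluated on the map of detected domains (best
score per profile, after best-of resolution for that rule). Within one
subfamily lineage the deepest matching rule wins and provides the
subfamily label; matches in unrelated lineages each produce an assignment
(with a warning — the catalog's forbidden-domain structure makes this
rare). Output 1 lists per-sequence assignments with evidence, output 2
counts distinct sequences per output family over the entire catalog (zero
rows included), output 3 adds the subfamily column. All outputs are
byte-deterministic: rows sort by (family, sequence id).

The packaged catalog (`data/rules_v4_synthetic.tsv`,
`data/coverage_v4_synthetic.tsv`) is a **synthetic reconstruction**, as the
filenames state: the documented v4 structures are encoded as published —
the ET family detected by either HRT or GIY_YIG; the bZIP merge of
bZIP1/bZIP2/bZIPCDD/bZIPAUREO; the two-route GARP_ARR-B merge; subfamilies
under C2H2, bHLH, HDZ, HAT, LBD, MYB, MYB-related and AP2; the
NF-YA/NF-YB/NF-YC trio and the RKD/NLP split (both realized as sibling
families rather than nested subfamilies, since no shared parent domain
exists); no CCAAT_Dr1 preference rule and no legacy HDZIP rule — while the
remaining families follow the TAP nomenclature established in the
literature, and the per-profile GA thresholds and lengths are synthetic
placeholders. The catalog arithmetic matches the published tool: 138
output families over 155 domains, 91 TF + 41 TR + 6 PT. Analyses that
depend on real thresholds require the published HMM collection; analyses
that depend only on catalog structure (counting, rule evaluation, output
formats) are fully supported.

Species are identified by the five-letter convention: first three letters
of the genus plus first two of the epithet, uppercased (ORYSA = *Oryza
sativa*), with optional source suffixes (pt/mt/pl/tr/hc/lc/org/iso) after
an underscore. The convention is positional, so collisions are possible;
they are warned about and never disambiguated.

## Asymmetric Wagner parsimony

For one family with leaf counts $n_s$, an ancestral assignment minimises
$\sum_{(u,v)} g\max(0,n_v-n_u) + \ell\max(0,n_u-n_v)$ over branches, with
positive per-unit penalties $g$ (gain) and $\ell$ (loss); branch lengths
are ignored. Defaults are $g=\ell=1$, exposed as `--gain-penalty` /
`--loss-penalty`.

*State space.* An optimal assignment never needs a state above the largest
leaf count $M$: lowering any node from $m>M$ to $M$ weakly decreases the
cost of every incident branch (each branch cost is convex with its minimum
on the segment between the endpoint states, and all leaves are $\le M$).
The DP therefore runs over states $0..M$: a post-order pass computes, per
node and state, the minimal subtree cost; a pre-order pass fixes each
node's state as the minimiser given its parent, taking the *smallest*
co-optimal count (a deliberate bias against postulating unobserved
ancestral copies; `argmin` over ascending states implements the tie rule).
Multiplying both penalties by a constant rescales all costs equally and
leaves the reconstruction unchanged; with $g=\ell$ the criterion is
classic Wagner parsimony. Correctness is checked against exhaustive
enumeration of all ancestral assignments on every rooted multifurcating
tree shape with up to 6 leaves (counts $\le 3$, penalty ratios 1, 2 and
0.5; shapes with $\le 4$ leaves exhaustively over all count vectors,
5- and 6-leaf shapes over seeded random vectors — sizes chosen to keep the
grid in the seconds range).

*Branch events.* gain: $0\to{>}0$; loss: ${>}0\to 0$; expansion / contraction:
increase / decrease with both endpoints $\ge 1$; else none. Totals are
reported for the branch leading to each node and tree-wide. Species in the
count matrix but absent from the tree must be resolved through an explicit
mapping file onto their closest sampled relative — never silently.

## Simulation and what recovery tests show

`gen_count_evolution` evolves integer counts root-to-leaves, sampling at
most one event per branch per family (gain 0→1, loss c→0, expansion c→c+1,
contraction c→c−1 staying ≥1) with given probabilities; the full history
is recorded. Two caveats define the regime in which parsimony recovery is
*provable* and which the recovery tests use:

* **Single-event histories.** One event per branch is not enough for exact
  recovery: two losses on sibling branches collapse into one ancestral
  loss, and a gain below a loss (or a contraction below an expansion) ties
  with cheaper single-event explanations. With at most one event per
  family on the whole tree (`max_events_per_family=1`) the optimum is
  unique and equals the truth, so inferred totals match the record
  exactly.
* **Root anchoring.** With a bifurcating root, a single loss on a
  root-child branch is indistinguishable from a gain on its sibling
  branch, and the smallest-count tie rule resolves toward the gain.
  Recovery fixtures therefore use trees with a trifurcating (outgroup-
  anchored) root, mirroring standard outgroup rooting practice.

Default rates (0.02 per event class per branch) keep simulated matrices in
the sparse-change regime of real TAP complements. The generator does not
emulate correlated events (whole-genome duplications raising many families
at once), rate variation across lineages, or annotation noise in leaf
counts — recovery results therefore demonstrate correctness of the
inference machinery, not robustness of parsimony on real data, where
sampling-depth bias is expected.

The planted-classification generator (`gen_toy_ruleset` / `gen_domtblout`)
builds rule sets from disjoint per-family domain pools (so recovery is
well-posed), plants members with all required domains at GA + margin and
full profile coverage, and decoys below GA or below the coverage cutoff.
At any positive margin the pipeline must recover the planted complement
with sensitivity = specificity = 1; fixture domtblout rows always carry
the exact 22-column layout so the parser is exercised end to end. No
amino-acid sequences are generated — only hit tables.

## Statistics

Family-size comparisons between two species groups (each ≥ 3 species) use
a per-family normality gate: Shapiro–Wilk on both samples, rejecting
normality at p ≤ 0.05 (the conventional reading of the gate). When neither
sample rejects, a Welch two-sample t-test is used (unequal variances are
the safe default for count data); otherwise the Wilcoxon rank-sum test,
exact for small tie-free samples and normal-approximated with tie and
continuity corrections otherwise (scipy's `mannwhitneyu`, method "auto").
Constant samples, where Shapiro–Wilk is undefined, gate to the rank test.
Family p-values are Benjamini–Hochberg adjusted (statsmodels `fdr_bh`);
the per-species totals comparison is reported alongside, unadjusted, and
totals can be pooled or restricted by filtering the input matrix to one
TAP class.

## Known limitations

* The packaged rule catalog reproduces documented structure, not the
  unpublished GA thresholds/profile lengths; absolute annotations of real
  proteomes require the published HMM collection.
* Parsimony-based event counts inherit parsimony's biases (no rate model,
  sensitivity to taxon sampling); a probabilistic birth–death mode is out
  of scope.
* A protein matching several unrelated families is reported under each —
  downstream count sums can exceed the number of classified proteins in
  that (warned) case.
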