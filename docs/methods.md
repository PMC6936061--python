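# Methods

## Model

`mecorank` scores genes per patient by propagating two signals over a
patient-specific bipartite graph drawn from a protein–protein interaction
(PPI) network, then aggregates the per-patient rankings across the cohort
by pairwise voting.

**Graph.** For tumor sample *s*, the left partition *U* contains every
expression gene present in the PPI (no variance or differential-expression
filter), and the right partition *V* contains the genes with at least one
somatic SNV in *s*, intersected with the PPI. An edge *u–v* (entry of the
binary *m × n* matrix *W<sup>VU</sup>*) exists iff the two genes interact
in the PPI; *W<sup>UU</sup>* is the binary, symmetric, zero-diagonal
adjacency among *U*. Because the PPI is a simple graph, a gene sitting on
both sides has no edge to itself: a mutation is only visible through its
interaction neighborhood (`self_edges=True` adds the same-gene edge for
experimentation). Mutation vertices with no neighbor in *U* are pruned —
they influence nothing and their degree factor would divide by zero. *U*
is never pruned; an isolated expression gene is still anchored by its own
expression term.

**Mutation damage.** Each SNV contributes a damaging probability: the
PolyPhen score when the PolyPhen label contains "damaging", or 1 − SIFT
score when the SIFT label contains "deleterious" (low SIFT = more
damaging). A variant matching both filters contributes the maximum of the
two, never the sum — one variant, one term. A matching label whose numeric
score is missing contributes `missing_score_default` (1.0; the label
itself asserts damage). Per (sample, gene), probabilities sum over the
gene's variants into *p*, and the propagated coefficient is *y = 1 + p*:
the offset keeps a recurrently mutated gene informative in the network
even when its variants all look benign (*y = 1*, not 0).

**Propagation.** Scores over *U* follow the damped update

    x_i = (1 − λu)·x0_i
        + λu(1 − λv)·Σ_k  w_ik^vu · d_k^(−1/2) · y_k
        + λu·λv·Σ_j  w_ij^uu · d_j^(−1/2) · x_j

whose three coefficients sum to one for any λu (λv = 1 − λu). x0 is the
per-gene z-score of tumor expression; the degree factors d<sup>−1/2</sup>
(d_k the *V*-side degree in *W<sup>VU</sup>*, d_j the degree within
*W<sup>UU</sup>*) suppress high-degree hubs. The normalization is applied
one-sided, exactly as the update is written; `sym_norm=True` switches to
the symmetric d_i^(−1/2)·w·d_j^(−1/2) variant. *W<sup>VU</sup>* columns
are kept binary rather than normalized to probabilities. The iterate
starts from the differential expression dx (tumor minus mean-normal;
`init` accepts `dx`, `x0` or `zeros`) and stops when the ∞-norm change
falls below ε.

The update is affine in x with linear part λu·λv·Ŵ<sup>UU</sup>. Since
Ŵ = W D<sup>−1/2</sup> is similar to the symmetric
D<sup>−1/4</sup> W D<sup>−1/4</sup>, its spectral radius is at most
d_max^(1/4)·(a constant near 1), so at the default λu·λv = 0.09 the
iteration is a strong contraction on any realistic PPI; convergence takes
single-digit iteration counts in practice (median 8 on the default
synthetic cohorts) and the fixed point is unique. A corollary worth
stating plainly: **the converged scores do not depend on the
initialization**, so the differential-expression vector influences the
result only through early stopping (within ε) — at convergence the signal
reduces to standardized expression (term 1) plus mutation-neighborhood
structure (terms 2–3). `Config(fixed_dx=True)` instead holds dx fixed in
the third term, which makes the update a one-step closed form and
preserves a direct differential-expression effect: a gene is then credited
for the differential expression of its interaction partners. The default
remains the iterative reading.

**Aggregation.** Each patient votes on every pair of candidate genes: the
pairwise winner is the gene with the larger δ(·)·Rank(·), where Rank is
the voter's min–max normalized score (best gene exactly 1, worst 0; genes
the voter does not rank get 0) and δ(g) is 1 if g is mutated *in that
voter's sample* and δ = 0.85 otherwise. Rank is the normalized score, not
the ordinal position: with ordinal positions (1 = best) a sub-unit
multiplier would *promote* an unmutated gene, inverting the penalty's
intent. Per-voter ties fall to the lexicographically later gene; a gene
beats another overall iff strictly more voters prefer it. The pairwise
outcomes are completed into a full order by the Copeland tally
(wins − losses), which recovers a Condorcet winner whenever one exists;
ties in the tally break by summed normalized score, then gene name. For
genome-scale inputs the candidate set is restricted to the union of each
voter's top `candidate_pool` (default 1000) genes — the quadratic pairwise
comparison over all ~20k genes is otherwise wasteful; `candidate_pool=None`
disables the restriction.

## Parameters

| name | default | meaning |
|---|---|---|
| `lambda_u` | 0.9 | weight of the network terms; mutation impact on the expression network is treated as the stronger signal. `lambda_v = 1 − lambda_u`; setting either updates both |
| `epsilon` | 1e-4 | ∞-norm convergence threshold on the score vector (expression-score units) |
| `max_iter` | 100 | iteration cap; with the default contraction it is never approached |
| `delta` | 0.85 | pairwise penalty on a gene not mutated in the voting patient |
| `top_k` | 100 | size of the final driver list |
| `candidate_pool` | 1000 | per-voter candidate cut before pairwise voting |
| `init` | `dx` | starting iterate (immaterial at convergence; see above) |
| `missing_score_default` | 1.0 | damage probability for a damaging/deleterious label without a numeric score |

Standardization of x0 uses the tumor cohort (population SD, zero-variance
genes map to 0); `expression_reference="normal"` z-scores against the
normal samples instead. Differential expression is unpaired: tumor value
minus the arithmetic mean of normals.

## Synthetic cohorts

`mecorank.synthetic` generates fully self-contained study data: a
preferential-attachment (Barabási–Albert) PPI over n = 200 genes with 2
edges per node (heavy-tailed degrees, connected, no self-loops), 50 tumor
and 20 normal samples, and 5 planted drivers. Drivers are drawn with
probability proportional to PPI degree — known cancer genes are
disproportionately high-degree in curated interaction databases, and a
degree-1 driver would be invisible to a neighborhood-propagation method by
construction. Each tumor sample carries each driver mutated with
probability 0.8 (one `probably_damaging` SNV, PolyPhen score 0.95) and
each passenger gene mutated at rate 0.02 (benign/tolerated labels); the
PPI neighbors of the sample's mutated drivers are shifted by +2 expression
SD on top of unit-variance Gaussian noise. The driver signal deliberately
enters through the *neighbors'* expression, matching the propagation
geometry in which a mutation vertex boosts adjacent expression vertices.

What the generator does *not* emulate: real expression marginals
(log-scale library-size effects, gene–gene correlation), realistic
mutation spectra or hotspots, indels/CNVs/fusions, and PPI ascertainment
bias. Passing tests on these cohorts therefore demonstrate that the
machinery computes what it claims on data with the assumed structure — not
that the method recovers drivers in real tumors.

### What the pipeline recovers on these cohorts — and what it does not

On the default cohorts the genes collecting the strongest aggregate signal
are the well-connected *interactors* of the recurrently mutated drivers,
not the drivers themselves: without same-gene edges a driver is scored
only second-hand (its boosted neighbors feed back through the weakly
weighted within-*U* term), and the δ = 0.85 penalty cannot bridge a large
normalized-score gap. Measured over 20 seeds, the mean fraction of planted
drivers in the aggregate top-20 is ≈ 0.24 at the defaults, and — because
the drivers remain recurrently mutated, well-connected vertices whose
*y = 1* still shapes the graph — a null cohort with the expression shift
and damage probabilities zeroed retains driver enrichment (≈ 0.33) rather
than falling to the ≈ 0.1 chance level. Both follow from the model's
design: the *y = 1 + p* offset and the mutation penalty reward mutation
recurrence as such, and the propagation rewards neighborhoods. Users who
want the mutated gene itself credited should look at `self_edges=True` or
`fixed_dx=True` (which credits a gene for its partners' differential
expression); the package's acceptance checks nevertheless run, and are
reported, at the defaults.

## Numerical choices

- Convergence is judged in the ∞-norm (the strictest per-gene criterion);
  scores are not re-normalized between iterations.
- d<sup>−1/2</sup> uses the 0 → 0 convention; a zero degree only ever
  multiplies a zero weight, so no product changes.
- A residual that grows for 10 consecutive iterations aborts with a
  diagnostic (a non-contracting operator); non-finite intermediates abort
  naming the patient.
- `λu·λv = 0` (and the edgeless graph) short-circuits to the closed form
  in a single application.
- All-equal score vectors normalize to 1 with a warning, ordered
  lexicographically; per-patient sorting breaks score ties
  lexicographically for reproducibility.
- Gene order within *U* and *V* is lexicographic; the whole pipeline is a
  pure function of (inputs, configuration) with no hidden randomness.
- Expression TSVs are written with `%.17g` and read with round-trip float
  parsing, so file round-trips are bit-exact.

## Limitations

- Only SNVs are scored; indels, CNVs and fusions are out of scope.
- Gene identity is the trimmed symbol string; no alias resolution.
- The PPI is unweighted and undirected; evidence quality is ignored.
- At convergence the iterative update forgets the differential-expression
  initialization (see Propagation above); `fixed_dx=True` is the supported
  alternative when that signal must persist.
- The Copeland completion and its tie-breaks are one standard choice among
  Condorcet completions; other completions can reorder genes with no
  pairwise-majority winner.
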