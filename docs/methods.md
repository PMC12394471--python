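# Methods

## Annotation transfer model

`goforge` assumes that a query protein inherits the GO annotations of the
reference sequences it aligns to. The unit of transfer is a *decorated
subject title*: when the reference is built, each protein accession is
given a description block

```
GN=<symbol> TAX=<taxid> GO=<id>!<evidence>!<category>[!NOT][;...]
```

appended after its existing FASTA description. `;` separates terms, `!`
separates fields, and symbols are scrubbed to `[A-Za-z0-9_.-]` so the
grammar is unambiguous; the block contains no tabs, so it survives the
`stitle` column of tabular search output and is exactly invertible. This
makes the annotation step a pure function of the hit table — no database
lookup at annotation time, which is what makes the pipeline fast and
trivially testable offline.

Transfer rules, in order:

1. hits with E-value above the cutoff are discarded;
2. at most `max_target_seqs` subjects per query are retained, ranked by
   (best E-value, highest bit score, subject id);
3. NOT-qualified assignments (gene2go qualifier beginning `NOT`) are never
   transferred — a NOT annotation asserts the *absence* of a function;
4. duplicate (query, GO id) pairs collapse to the record with the lowest
   E-value; ties break by higher bit score, then lexicographic subject id,
   then similarity-over-domain-scan provenance, so output is a
   deterministic function of the input *set* (order-independent).

Defaults are `blastp`, ultra-sensitive, E-value cutoff `1e-5`,
`max_target_seqs 1` — the operating point that balances coverage against
runtime; `--evalue 1e-10` restores the stricter cutoff. Coordinates of
translated (blastx) hits are passed through untouched: transfer uses only
the E-value and the subject title, so frame bookkeeping is out of scope.

Queries with no retained hit are listed separately and can be routed to an
external domain scanner. Scanner-derived records carry evidence code IEA,
no E-value (they always lose precedence ties to similarity records, which
have quantitative support), and category `-` since the scanner's TSV does
not state the term's namespace; supplying an ontology at enrichment time
restores names/namespaces where needed.

## Ontology handling

The OBO parser consumes `[Term]` stanzas only. Both `is_a` and
`relationship: part_of` become parent edges — the two edge types along
which annotation propagation is sound — and all other relationship types
are ignored. Obsolete terms are kept in a side table (annotations citing
them remain reportable) but carry no edges; alternate ids resolve silently
to their primary term before every lookup, since NCBI tables routinely cite
merged ids. The non-obsolete graph is validated to be acyclic at parse
time (one offending cycle is reported). `ancestors()` is the memoised
transitive closure over parent edges, excluding the term itself; namespace
roots have empty ancestor sets.

## Enrichment statistics

Each GO term with at least one carrier in the universe is tested on the
2×2 table (study × has-term). The p-value is the standard two-sided Fisher
exact probability under the point-probability rule: the sum of
hypergeometric point probabilities, over all tables with the observed
margins, that do not exceed the observed table's probability. Two numerical
choices matter:

- computation is in log space (gammaln), with the per-margin log-pmf
  vector, its sort, and its running log-sum-exp memoised (LRU, 4096
  margins) so sweeps over many tables sharing margins are cheap;
- a relative tie guard of `1 + 1e-7` keeps the observed table from being
  excluded from its own tail by floating-point noise — the convention of
  mainstream exact-test implementations.

Degenerate inputs: an all-zero table has a single attainable configuration
and p = 1; negative counts are rejected.

Multiplicity is controlled with Storey–Tibshirani q-values. π̂₀(λ) =
#{p > λ} / (m(1 − λ)) is evaluated on the grid λ = 0, 0.05, …, 0.90, a
cubic polynomial is fit to the grid and evaluated at λ = 0.90, and the
result is clamped into (0, 1] (values ≤ 0 after smoothing — which occur
only when essentially every p-value is tiny and the true π₀ is ≈ 0 — are
floored at 1e-8). Then q(p_(i)) = min_{j≥i} π̂₀·m·p_(j)/j. Pinning
`pi0 = 1` makes the procedure identical, element for element, to
Benjamini–Hochberg step-up — the equivalence the test suite verifies to
1e-12 against an independent oracle.

Design choices where the design was genuinely open:

- **Background universe**: defaults to all genes with ≥ 1 annotation in
  the supplied table; an explicit `--universe` file overrides. Study ids
  outside the universe are an input error (listed), not silently dropped.
- **Ancestor propagation** is off by default and enabled with
  `--propagate` plus an ontology; whether to test direct or propagated
  annotations is a modelling decision the user should make explicitly, and
  results depend on it.
- **One q-value family**: all three namespaces are tested together, giving
  a single ranked list.
- **Direction**: a term is "over" when the study frequency strictly
  exceeds the background frequency; significance is `q < threshold`
  (strict, so threshold 0 flags nothing).

## Synthetic fixtures

The generator produces every dialect the pipeline reads, with ground truth:

- **Reference sets**: random DAG over GO-shaped ids (reserved range
  GO:9000000+, so no real term is implied) with three namespace roots,
  1–2 parents per term, ~20% `part_of` edges, ~5% alt ids; proteins of
  80–400 residues; 0–6 gene2go assignments per gene with ~10% NOT
  qualifiers; 1 accession per gene by default (a keyword emulates isoform
  accessions).
- **Queries and hits**: point-mutated copies of reference sequences
  (default substitution rate 0.02); one true hit per query with E-value
  log-uniform on [1e-50, 1e-6] and the decorated subject title; decoys
  pair random queries with non-source subjects at E-values log-uniform on
  [1.1e-4, 10]. Any cutoff in [1e-6, 1e-4] therefore separates truth from
  decoys exactly, which is what makes 100% recall/precision the correct
  expectation on fixtures rather than an optimistic claim about real data.
- **Enrichment scenarios**: per-term background frequencies uniform on
  (0.02, 0.2); planted terms' frequencies are capped at 1/fold so
  fold × frequency is a valid probability, and study genes carry planted
  terms at fold times the background rate. `fold = 1` is an exchangeable
  null. The default study size is n_genes/10 (100 of 1,000 at the sizes
  the acceptance checks use). Genes that would end up term-less receive
  one frequency-weighted term, so every gene belongs to the default
  (annotated-genes) universe.

Every generator takes an explicit seed, uses a single PRNG stream, and is
byte-reproducible; seeds are recorded in the truth object.

What the fixtures do **not** emulate: realistic protein evolution
(mutations are i.i.d. substitutions), realistic E-value or bit-score
calibration (values are monotone-plausible placeholders), alignment-length
or composition effects, and paralogy. Passing tests therefore demonstrate
that the *bookkeeping* — filtering, NOT exclusion, collapse, propagation,
counting, FDR control — is exact, not that homology transfer is
biologically correct for any particular proteome.

## Problem sizes used by the checks

The test suite sweeps every 2×2 table with grand total ≤ 80 against the
enumeration oracle (1,929,501 tables), 1,000 random p-vectors against the
BH oracle, 100 null and 100 planted enrichment replicates at 1,000 genes ×
40 terms with a 100-gene study, and a 500-query / 200-decoy transfer
fixture; the acceptance script uses the same enrichment and transfer sizes
with 2,000 random Fisher tables and 500 p-vectors. These sizes make the
checks exhaustive where exhaustiveness is cheap and statistically stable
where sampling is involved.

## Known limitations

- The external aligner is invoked, never reimplemented; all tests use
  precomputed or simulated hit tables. The adapter has a dry-run mode that
  prints the exact command line.
- The remote domain-scanner submission loop is out of scope; only its TSV
  output is consumed, and the GO-column dialect assumption (optional
  parenthesised source suffix) is exactly that — an assumption about
  common scanner versions.
- No conditional / DAG-decorrelated enrichment, no gene-length or
  composition bias correction, no taxonomic filtering of hits, and no
  evidence-code weighting.
- Venn output is counts only (2–3 sets); drawing is left to the caller.
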