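# Methods

## The model

`gotransfer` predicts protein function by annotation transfer: a query
protein inherits the GO terms of the database proteins and Pfam domains it
aligns to, and each inherited term receives a confidence score. The score
is built from four signals:

- **Alignment strength.** A hit with e-value E contributes −log10(E) to
  every GO term of its subject; hits with E > 1 are discarded. Summing
  over hits means a term supported by many strong alignments accumulates
  more weight than one seen once.
- **Evidence quality.** Protein-search transfers whose source annotation
  carries a curated (non-IEA) evidence code are multiplied by log2(P),
  where P = (#IEA records)/(#non-IEA records) in the reference corpus.
  In real GOA releases electronic annotations dominate, so P ≫ 1 and
  curated evidence is up-weighted. The multiplier is floored at 1.0:
  as printed, log2(P) ≤ 0 whenever P ≤ 1, which would *penalise* curated
  evidence on corpora where it is abundant — the floor preserves the
  intent (curated evidence never scores worse than IEA) on small or
  atypical corpora. Domain-search transfers (pfam2go) are never
  multiplied, since pfam2go entries carry no per-record evidence codes.
- **DAG structure.** Weights are summed upward over the is_a/part_of
  graph (the true-path rule applied to evidence): ancestors aggregate the
  weight of all their descendants, each descendant counted exactly once
  even when multiple paths connect it (set-wise, not path-wise,
  aggregation — path-wise counting would double-count under diamond
  motifs). The internal confidence InC(v,i) = W(v,i)/W(v,root) then
  expresses each term's share of the total evidence; the deliberate
  consequence is that generic terms, being easier to support, score
  higher InC. The group score GS(v,i) pools the InC of the protein's
  terms within Lin similarity 0.7 of i, so the InC/GS ratio in the total
  score discounts terms whose confidence merely reflects a crowd of
  near-synonymous siblings. Each term keeps its own GS rather than one GS
  per similarity cluster.
- **Term specificity.** IC(i) = −log10 P(i), with P(i) the fraction of
  reference proteins annotated (after ancestor closure) with i, computed
  per namespace. The final score TS = IC · InC/GS · W therefore balances
  specificity against cumulative support.

The three GO namespaces are independent everywhere: separate roots,
separate IC scales, separate similarity spaces, separate normalisation.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `sim_threshold` | 0.7 | Lin similarity at or above which a sibling term's InC joins the group score. |
| `evalue_cap` | 1e-200 | Floor applied to e-values before −log10; aligners report underflowed e-values as 0.0, which would otherwise weigh infinitely. A 0.0 e-value thus contributes 200. |
| `evidence_weighting` | on | Apply the log2(P) multiplier to non-IEA-backed protein transfers. With it off the cascade reduces exactly to the plain −log10(E) sum. |
| `multiplier_floor` | 1.0 | Lower bound on the multiplier (see above). |
| `normalization` | batch | TS is min–max scaled to [0,1] per namespace across the whole prediction batch; `protein` rescales within each protein instead. Batch scaling is the mode the threshold-sweeping metrics assume; the per-protein alternative is kept behind a flag because the right choice is not settled and callers comparing proteins of very different hit depths may prefer it. A degenerate range (all TS equal) maps to 1.0. |
| `best_per_pair` | off | Keep only the lowest e-value per (query, subject). Off by default: the weight is a sum over *all* alignments, so multiple HSPs/domain matches of one pair each contribute. |

## Design choices

- **"Joint parent" in Lin similarity** is implemented as the
  most-informative common ancestor (maximum IC, the standard companion of
  Lin's measure), with ties broken to the lexicographically smallest GO
  id. It is isolated behind `joint_parent()` so a graph-topological
  alternative (e.g. minimum path distance) can be swapped in.
- **P counts annotation records**, not distinct GO ids: the ratio is
  taken over retained GAF rows. Either reading is defensible; rows are
  the finer-grained and simpler invariant (`iea_count + non_iea_count =`
  retained rows).
- **Terms absent from the reference corpus** get the maximum IC observed
  in their namespace rather than +infinity, keeping TS finite. Such terms
  can only be leaves-below-annotated-terms (closure guarantees an
  annotated term's ancestors are annotated).
- **GOA terms are transferred un-closed**; the DAG enters once, through
  weight propagation. Closing the transferred sets first and then
  propagating would double-count ancestors.
- **If a subject annotates the same term with several evidence codes**,
  the hit contributes once for that term, multiplied iff any of those
  codes is non-IEA.
- **Evaluation excludes namespace roots** from both truth and prediction
  sets (they are trivially predictable and would inflate precision and
  recall); a flag restores them. The GO:0005515 (protein binding)
  sole-MF-term filter runs on the direct annotations *before* ancestor
  closure — closure always adds binding's ancestors, which would defeat
  the check.
- **Proteins with no predictions** still count in the recall denominator
  n; precision at threshold t averages only over the m(t) proteins with
  at least one surviving prediction, and is 0 by convention when
  m(t) = 0.
- **Determinism.** Wherever floating-point contributions are summed over
  a set (weight accumulation, propagation, group scores, ru/mi), the
  iteration is explicitly sorted, so repeated runs — including across
  processes with different hash seeds — are bit-identical. Output rows
  are sorted by (protein, namespace, TS descending, GO id).

## The synthetic corpus generator

The `fixtures` module emulates the study setting at desk scale: a
three-namespace GO DAG (chain, diamond or random shape; random DAGs draw
parents only from earlier terms, guaranteeing acyclicity and a single
root), a reference proteome annotated in every namespace with an
IEA-heavy evidence mix (default 80% IEA, reflecting the dominance of
electronic annotations in real GOA releases), a small pfam2go mapping,
and query proteins hitting known subjects with log-uniform e-values (so
−log10 contributions are uniform and hand-checkable). Two edge-case hits
are always present: one above the e ≤ 1 filter and one reported as 0.0.
A truth GAF for the query proteins is derived from each query's closest
subject with experimental evidence codes, mirroring how benchmark truth
sets consist of proteins with experimentally determined functions that
have homologs in the database.

What the generator does **not** emulate: realistic sequence content or
alignment statistics (e-values are sampled, not computed), the size and
depth of the real GO (tens of terms versus ~45,000), annotation biases of
real curation pipelines, or taxon structure. Passing tests therefore
demonstrate the correctness of the arithmetic, the graph operations, the
filtering rules and the metrics — not predictive performance on real
proteomes, which depends on database coverage and is outside what a
synthetic corpus can show.

## Problem sizes

The test suite and `scripts/acceptance.py` run on corpora of 6–12 terms
per namespace, 4–20 reference proteins and 2–10 queries; the
conservation sweep uses 100 random corpora. These sizes make every
quantity checkable against brute-force enumeration (transitive-closure
descendant sums, O(n²) similarity loops, exhaustive threshold scans)
while the whole suite completes in seconds. The algorithms themselves are
linear in hits × terms-per-subject plus quadratic in terms-per-protein
for the group score, and handle real-scale inputs (full GO, GOA,
proteome-sized hit tables) without modification.

## Known limitations

- Only `is_a` and `part_of` edges are honoured; `regulates` and other
  relationship types are ignored, as is cross-ontology structure.
- Only hmmscan-orientation tblout is accepted (hmmsearch swaps the
  target/query columns); the full-sequence e-value (column 5) is used,
  not the best-domain e-value.
- pfam2go transfers are not supplemented with the GOA annotations of the
  family's member proteins, and no taxonomic filtering is applied — both
  are deliberate scope decisions of the method, not oversights.
- The evidence multiplier errors out on a corpus with *no* non-IEA
  records (P undefined in spirit); callers are told to disable evidence
  weighting instead of silently degrading.
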