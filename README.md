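# gotransfer

Weighted sequence-similarity transfer of Gene Ontology (GO) annotations.

`gotransfer` annotates query proteins with GO terms by homology: it reads
DIAMOND/BLASTP hits against a UniProtKB-style protein database and hmmscan
hits against Pfam-A, transfers the GO terms of each hit's subject (from a
GOA association file for proteins, from pfam2go for domains), and ranks the
transferred terms with a weighting cascade that combines alignment
strength, annotation evidence quality, the GO DAG structure and term
information content. It also ships a protein-centric evaluation suite
(precision–recall sweeps, F<sub>max</sub>, S<sub>min</sub>) and a
deterministic generator of toy input corpora, so the entire pipeline runs
and is testable offline.

It is aimed at people annotating predicted proteomes locally — comparative
genomics and other large-scale studies where web-based annotation servers
are impractical.

## The scoring cascade

For a query protein *v* and a GO term *i*:

1. **Weight.** Every alignment hit *j* whose subject is annotated with *i*
   contributes, with hits of e-value above 1 discarded:

   W(v,i) = Σ_j −log10(E_j) · M_j

   where M_j = log2(P) when the subject's annotation of *i* carries a
   curated (non-IEA) evidence code and 1 otherwise. P is the ratio of IEA
   to non-IEA annotation records in the reference corpus, so transfers
   backed by experimental evidence are up-weighted (the multiplier is
   floored at 1 so curated evidence is never penalised). Reported e-values
   of 0.0 (aligner underflow) are capped at a configurable floor
   (default 1e−200).

2. **DAG propagation.** Weights of descendant terms are added to each
   ancestor (each descendant counted once, also under diamond-shaped
   multiple-parent paths), expressing that annotation with a term implies
   its ancestors.

3. **Internal confidence.** InC(v,i) = W(v,i) / W(v, root) — the term's
   share of the namespace root's weight.

4. **Group score.** GS(v,i) = Σ_j InC(v,j) over the protein's terms *j*
   with Lin semantic similarity Sim(i,j) ≥ 0.7, where
   Sim(i,j) = 2·IC(k) / (IC(i)+IC(j)), *k* the most informative common
   ancestor, and IC(i) = −log10 (fraction of reference proteins annotated
   with *i*).

5. **Total score.** TS(v,i) = IC(i) · InC(v,i)/GS(v,i) · W(v,i),
   min–max rescaled to [0,1] per namespace for thresholding.

The three GO namespaces are treated independently throughout.

## Worked example

Generate a toy corpus, predict, and evaluate:

```sh
gotransfer fixtures --outdir demo --seed 13
gotransfer predict \
    --diamond demo/fixture_diamond.tsv --hmmer demo/fixture_hmmer.tblout \
    --gaf demo/fixture.gaf --pfam2go demo/fixture_pfam2go.txt \
    --obo demo/fixture.obo -o demo/predictions.tsv
gotransfer evaluate --predictions demo/predictions.tsv \
    --gaf demo/fixture_truth.gaf --obo demo/fixture.obo -o demo/report
```

`demo/predictions.tsv` holds one row per (protein, GO term) with every
stage of the cascade:

```
protein   go_id       namespace           weight        inc           gs  ic            ts           ts_norm
QUERY000  GO:0910002  biological_process  297.704096    0.5           1   0.3010299957  44.80893137  1
QUERY000  GO:0910003  biological_process  297.704096    0.5           1   0.3010299957  44.80893137  1
QUERY000  GO:0910006  biological_process  249.4405722   0.4189404438  0.8378808876  0.3010299957  37.54454718  0.8378808876
...
```

Here `weight` is the propagated evidence mass, `inc` its fraction of the
root's mass, `gs` the pooled confidence of similar sibling terms, `ic` the
term's specificity, `ts` the final score and `ts_norm` its [0,1] rescaling
— the prediction confidence used for thresholding. The evaluate step
prints, per namespace, F<sub>max</sub> (best precision/recall balance over
thresholds, 1.0 = perfect) and S<sub>min</sub> (the information-theoretic
distance to the truth annotation, 0.0 = perfect), e.g.:

```json
{
  "biological_process": {"fmax": 0.6516853932584269, "n": 3, "smin": 0.0},
  "cellular_component":  {"fmax": 0.9137931034482758, "n": 3, "smin": 0.0},
  "molecular_function":  {"fmax": 0.8,                "n": 3, "smin": 0.0}
}
```

(The S<sub>min</sub> of 0.0 is an artefact of the tininess of this demo
corpus: the few mispredicted terms are annotated to every reference
protein and therefore carry zero information content. Larger corpora —
e.g. the one used by `scripts/acceptance.py` below — yield non-zero
S<sub>min</sub>.)

The same pipeline is available as a library (`gotransfer.predict`,
`gotransfer.evaluate`, …); the CLI is a thin wrapper around it.

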