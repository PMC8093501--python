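# Packaged fixtures

Small plain-text transcriptions of published summary tables for the 12
breast cancer susceptibility genes, used by the test suite and examples.

- `table1_breast.tsv` — per-gene evidence for the gene–breast-cancer
  association across the six genetic resources: ClinGen validity category,
  NCCN strength category, and presence flags for OMIM, Genetics Home
  Reference (GHR), GeneCards and Gene-NCBI.  One gene (BARD1) carries an
  NCCN qualifier ("strong for triple-negative disease") in the original;
  the category is stored as Strong.
- `table2_spectrum.tsv` — the verified disease spectrum: 86 gene-disease
  pairs with a malignant/benign/borderline category and the verification
  route that established each pair (78 via ClinGen/NCCN, 4 via the
  ≥3-of-4 minor-resource rule, 4 via the NLP-aided literature review).
- `adjudication_examples.json` — the published effect estimates discussed
  alongside the spectrum (odds/hazard/relative ratios with CI and/or
  p-value), used as worked examples for the two-fold significance rule.

Note on unique-disease counts: the source publication states both "42
diseases" and "49 unique diseases" in different sections, and a direct
count of the spectrum table under natural name normalizations (this
package's normalization yields 47) matches neither unambiguously.  The
package therefore reports the unique-disease count it computes but never
asserts a published value for it.
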