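# junctionkit

Tools for analysing DNA double-strand-break repair junctions of the kind
produced during immunoglobulin class-switch recombination:

* **junction calling** — map a junction read onto donor and acceptor
  references, place the breakpoints, and classify the join as *blunt*,
  *microhomology* (overlap, with its ambiguity interval), or *insertion*;
  annotate point mutations in the 30-nt flanks and emit rows in the
  published-table dialect (`start:end` intervals spanning 30 nt,
  mutations lower-cased).
* **templated-insertion origin search** — exhaustive affine-gap local
  alignment of an insertion against the references on both strands, with
  uniqueness calling and distance-to-breakpoint measurement.
* **minimal-pairing extension model** — enumerate snapback and
  intermolecular priming registers requiring only a short run of
  Watson–Crick pairs at the 3′ terminus, extend by templated copying to
  the template 5′ end, and iterate slippage/repriming cycles to predict
  product sequences and lengths.
* **statistics** — insertion fractions with Wilson intervals, a
  two-tailed Fisher's exact test implemented directly from the
  hypergeometric distribution (log-space, stable for margins ~10⁷),
  translocation frequencies and fold changes.
* **synthetic data** — seeded switch-region-like reference generation and
  junction-read simulation under three joining mechanisms (cNHEJ-like,
  MMEJ, synthesis-dependent joining with templated blocks), with full
  per-read ground truth, so the entire pipeline is testable offline.

A bundled fixture transcribes the published 31-row junction table
(9 WT, 21 WT+NU7026, 1 KO rows; 30-nt flanks, insertions, coordinates,
homology annotations) and is checksum-verified on load.

## Tests

```bash
python -m pytest -q tests/
```

All unit and property tests pass.  Two tests in
`tests/test_acceptance.py` are expected to fail offline: they require
GenBank accession `D78344` (place it at `data/references/D78344.fasta`)
and the supplementary 16-mer oligo sequence (place it at
`data/text_s1_16mer.txt`); neither input can be fetched without network
access.

## CLI

```bash
# simulate references + junction reads with ground truth
junctionkit simulate --n 100 --mixture "CNHEJ=0.6,MMEJ=0.2,SDEJ=0.2" \
    --seed 1 --out-dir sim/

# call junctions in FASTA reads against donor/acceptor references
junctionkit call --reads sim/reads.fasta --donor donor.fasta \
    --acceptor acceptor.fasta --flank 30 --out calls.tsv

# search templated origins of insertions
junctionkit origin --insertions insertions.tsv --refs refs.fasta \
    --min-len 10 --out origins.tsv

# group statistics
junctionkit stats --counts 9,21 --totals 100,100
junctionkit translocation --counts 5,17 --genomes 9.6e6,9.6e6

# extension-model products of an oligo
junctionkit extend --oligo TACCCCTTTTGGGG --slip 0 --min-pair 4 \
    --seed 1 --out products.tsv

# full configured run (fixture / simulate / reads modes)
junctionkit run --config run.yaml --out-dir results/

# export the bundled junction-table fixture
junctionkit fixtures table1 --out-dir fixture/
```

A minimal `run.yaml` for the bundled fixture:

```yaml
mode: fixture
seed: 0
```

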