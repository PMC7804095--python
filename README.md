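# wincorr

Self-correction and assembly polishing for noisy long reads (PacBio / ONT),
built around windowed multiple sequence alignment:

1. **Alignment piles** — all-vs-all read overlaps (PAF, from any external
   overlapper) are grouped per template read, keeping the N highest-identity
   overlaps (default 150).
2. **Windows** — fixed-length intervals (default 500 bp, overlapping by
   50 bp) of the template where every base is supported by at least 3 pile
   reads.
3. **Segmented POA consensus** — each window's sequences are anchored on a
   longest chain of shared, non-repeated k-mers (k = 9, pair support ≥ 8),
   splitting one large partial-order-graph MSA into many small ones;
   consensus is a per-column majority vote with template tie-breaking.
   Windows with fewer than 2 chain anchors are left uncorrected.
4. **de Bruijn polishing** — weak (low-frequency) k-mer runs on the
   consensus are re-spelled by paths through a local de Bruijn graph over
   the window's solid k-mers (solidity 4).
5. **Realignment & splicing** — each polished consensus is locally realigned
   around its window (± the window overlap), overlaps between consecutive
   consensi are resolved by solid-k-mer counts, and the winning factors are
   spliced into the read.  Corrected bases are emitted in uppercase,
   untouched bases in lowercase; reads are never trimmed or split.

**Assembly polishing** runs the identical engine with contigs as templates
and a reads-vs-contigs PAF.

The package also ships a seeded synthetic toolkit (random genome,
indel-dominant read simulator with ground truth, truth-derived overlap PAF,
and a base-level recall/precision/error-rate evaluator) so the whole
pipeline is testable without external data.

## CLI

```sh
# simulate a dataset (writes sim.genome.fasta, sim.reads.fasta, sim.paf,
# sim.truth.tsv)
wincorr simulate --genome-len 50000 --coverage 50 --error-rate 0.12 --seed 1

# self-correction (PAF from any overlapper, e.g. minimap2 -x ava-ont)
wincorr correct --in sim.reads.fasta --overlaps sim.paf --out corrected.fasta

# assembly polishing (reads-vs-contigs PAF)
wincorr polish --contigs asm.fasta --in reads.fasta --overlaps map.paf \
    --out polished.fasta

# evaluate a correction run against simulated ground truth
wincorr evaluate --in sim.reads.fasta --corrected corrected.fasta \
    --truth sim.truth.tsv --genome sim.genome.fasta
```

All pipeline parameters (`--window-size`, `--window-overlap`, `--support`,
`--kmer-size`, `--solidity`, `--anchor-support`, `--max-overlaps`,
`--min-anchors`) are exposed with their defaults; `--config file` accepts
`key=value` lines overridden by flags. `--threads` only affects scheduling —
outputs are byte-identical for any worker count.

## Library

```python
from wincorr import Params, run_correction, simulate_reads

params = Params(window_length=500, min_support=3)
run_correction("reads.fasta", "overlaps.paf", "corrected.fasta", params)
```

Module map: `io_seq` (FASTA/PAF, 2-bit sequence store) · `piles`
(piles/support/windows) · `msa_poa` (POA graph, MSA matrix, majority
consensus) · `segmentation` (anchor selection and chaining, segmented
consensus) · `dbg_polish` (local de Bruijn graph repair) · `correct`
(orchestration, polishing mode) · `synthetic` (simulator + evaluator) ·
`cli`.
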