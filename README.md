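# samselect

Sample sequence selection for quorum planted motif search (qPMS) on large
DNA datasets.

## The problem

Given `t` DNA sequences of length `n`, qPMS asks for every *l*-mer `m`
that occurs, with up to `d` mismatches, in at least `q·t` of the sequences
(`0 < q ≤ 1`, `0 ≤ d < l < n`).  It is the standard combinatorial
formulation for locating transcription-factor binding sites, and it is
NP-complete: exact solvers handle the classic `t = 20, n = 600` benchmarks
well, but ChIP-seq-scale inputs with thousands of sequences and a small
quorum fraction `q` are far out of reach — both suffix-tree pattern-driven
and sample-pattern-driven solvers slow down sharply as `t` grows or `q`
shrinks.

`samselect` attacks the input instead of the solver.  It selects a small
**sample sequence set** `D′ ⊂ D` with `t′ ≪ t` sequences and an *enriched*
proportion `q′ > q` of motif-bearing sequences, so that any off-the-shelf
qPMS solver finishes quickly on `D′` and still finds the planted motif.
The selection runs in three stages:

1. **Word count with mismatches.**  Every `w`-mer window `x` (default
   `w = 12`) is scored with `count_k(x) = Σ_{y ∈ B_k(x)} count(y)`
   (default `k = 1`), where `count(y)` comes from a dense table of size
   `4^w` indexed by the *stn* encoding (reverse the string, map
   A,C,G,T → 00,01,10,11).  The table is built either by backward search
   on an FM-index, pruning a depth-`w` quadtree of candidate strings, or
   by a bit-identical vectorised tally.  Windows overlapping motif
   instances score systematically higher than background windows.
2. **High-frequency substring obtainment.**  Windows with
   `count_k > f` are chained when they overlap by at least `w/2` into
   substrings; substrings shorter than `l` are dropped, and `f` is
   escalated until at most 5000 substrings remain (set `A`).  Long
   substrings are then segmented at the maxima of their *attract tables*
   — histograms of which `l`-mer position inside a substring is nearest
   to each other substring — giving set `A′` whose members each cover at
   most one motif instance.
3. **High-frequency substring grouping.**  `A′` is clustered by affinity
   propagation under `sim(φ, φ′) = −dis(φ, φ′)` (times 10 beyond `2d`),
   where `dis` is the minimum Hamming distance over all `l`-window pairs.
   Clusters that describe the same motif are merged, trimmed to the `t′`
   members nearest the exemplar, and filtered by three rules: pairwise
   distances `≤ 2d`, center distances `≤ 3d/2`, and total weight
   `w(c) = Σ dis(φ, φ′) ≤ a_m`, with `a_m = μ + σ` calibrated on 1000
   randomly generated instance samples of the same size.  Each surviving
   cluster emits the set of source sequences of its members, ranked by
   size.

The package also bundles a planted-`(l, d)`-motif simulator with a
ground-truth sidecar and a small exact qPMS solver, so the whole pipeline
is verifiable end to end on synthetic data.

## Worked example

```bash
# simulate 500 sequences of length 600 with a (9,2) motif implanted in
# half of them at high conservation (g = 0.2)
samselect simulate --t 500 --n 600 --l 9 --d 2 --q 0.5 --g 0.2 --seed 1 \
    --out data.fasta --truth truth.json
# select sample sequence sets (w=12, k=1, t'=50)
samselect select data.fasta --l 9 --d 2 --q 0.5 --t-prime 50 --seed 1 \
    --outdir selected/
# solve qPMS exactly on the first (largest) sample set
samselect qpms selected/sample_set_rank01.fasta --l 9 --d 2 --q 0.95 \
    --truth truth.json --out motifs.tsv
```

The run prints

```
wrote 500 sequences to data.fasta; motif ATGCAACCG; 250 implants; truth in truth.json
1 sample set(s) in selected (18.9s; f=4, |A|=1417, |A'|=1423)
457 motif(s) written to motifs.tsv
implanted motif ATGCAACCG rank: 1
```

meaning: the threshold escalated to `f = 4`, 1417 high-frequency
substrings were extracted and segmented into 1423 pieces, and one cluster
survived all three rules.  Its sample set contains 50 of the 500
sequences, and the exact solver — run on those 50 sequences instead of
all 500 — reports the implanted motif `GTTAGGGCT` at rank 1 among the
(9, 2) motifs meeting the 0.95 quorum.  `samselect evaluate` additionally
measures the realised q′ of each sample set against the ground truth.

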