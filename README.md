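# qpi

Proteoform characterization from deconvoluted top-down ETD spectra:
fragment assignment with fragment-level FDR control, PTM site localization
via modification ladders, and quantification of co-isolated positional
isomers from fragment intensity ratios.

The package consumes (i) a protein sequence (FASTA) and (ii) deconvoluted
fragmentation spectra as neutral monoisotopic mass/intensity peak lists
(delimited text, as exported by upstream deisotoping software), typically
three technical replicates per precursor. It does **not** read raw or mzML
files — deisotoping is upstream.

## Pipeline

1. **Broad match** — theoretical neutral fragments (all 8 ion types
   a/b/c/c−1/x/y/z/z+1, optional water/ammonia/hydrogen losses, on a
   0..n-modification mass grid) matched to peaks at 10 ppm.
2. **Calibration** — the median ppm error of the assignment population is
   removed as the systematic shift; the matching tolerance becomes 3×SD.
3. **Ion-type selection** — "frequent flyer" test: a type is kept when its
   match count is a significant right-tail outlier versus scrambled-decoy
   counts (for ETD this recovers c, c−1, y, z, z+1).
4. **Tight match + majority voting** — fragments must be assigned in ≥ k of
   n replicates (default 2/3); accepted intensity is the replicate median.
   No intensity cutoff is ever applied.
5. **FDR** — the identical search is repeated against 200
   composition-preserving scrambled sequences; the fragment-level FDR is
   the median decoy sequence coverage.
6. **PTM ladders & localization** — accepted fragments are arranged per
   terminus on a cleavage × modification-count grid; candidate site
   combinations are scored per stretch with a binomial chance-match
   probability (q = peaks per 100 Da / 100) and ranked.
7. **Isomer quantification** — modified/unmodified intensity ratios per
   (cleavage, ion type) pair, median + SEM per stretch, a t-test for hidden
   isomers at boundary sites, and a non-negative, sum-to-one least-squares
   solve of candidate-isomer abundances; indistinguishable isomers are
   reported as groups with summed abundance.

A fully seeded simulator (`qpi.simulate`) generates deconvoluted ETD
spectrum sets for proteoform mixtures — shared per-cleavage fragmentation
efficiency, multiplicative intensity noise, ppm error, dropout and decoy
peaks — with complete ground truth, so every stage is testable without
instrument data.

## CLI

```bash
# generate a synthetic fixture with ground truth
qpi simulate --config sim.yaml --out fixture/

# full pipeline: assignment -> FDR -> ladders -> localization -> quantification
qpi full --fasta protein.fasta \
    --peaklist rep1.tsv --peaklist rep2.tsv --peaklist rep3.tsv \
    --modification phospho --precursor-mass 27234.56 \
    --vote 2/3 --n-scrambles 200 --seed 1 --out out/
```

`assign`, `localize` and `quantify` run the pipeline up to the named stage.
Useful flags: `--tolerance-ppm`, `--ion-types c,z` (omit for automatic
selection), `--losses`, `--no-calibration`, `--mass-offset` (e.g.
`-1.007276` for MH+ peak lists), `--score plain|corrected`,
`--fixed-site`, `--exclusive A,B`. Outputs: `assignments.tsv`, `fdr.json`,
ladder matrices as TSV heatmaps, ranked site combinations, `quant.json`,
and a `provenance.json` with all parameters and seeds.

Example simulator config:

```yaml
sequence: MQIFVKTLTG...   # residue string
modification: heavy-Val    # built-in, or {name, delta_mass, acceptor_residues}
proteoforms:
  - {sites: [17], abundance: 0.5}
  - {sites: [70], abundance: 0.5}
noise_cv: 0.10
ppm_sd: 1.0
dropout: 0.10
decoy_density: 2.0
n_replicates: 3
seed: 42
```

## Layout

| module | responsibility |
| --- | --- |
| `qpi.chem` | residue/modification masses, scrambling, isomer combinatorics |
| `qpi.fragments` | theoretical fragment mass grid |
| `qpi.peaklists` | FASTA / peak-list I/O, spectrum statistics, reports |
| `qpi.assignment` | matching, calibration, ion-type selection, voting, FDR |
| `qpi.ladder` | PTM ladders, stretch probabilities, localization |
| `qpi.quant` | pair ratios, occupancy, abundance system + solver |
| `qpi.simulate` | ground-truth spectrum simulator |
| `qpi.workflow` / `qpi.cli` | orchestration, provenance, command line |
| `qpi.benchmarks` | seeded end-to-end recovery harnesses |
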