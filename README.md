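# hic3d

Restraint-based reconstruction of coarse-grained 3D chromatin conformation
ensembles from Hi-C contact matrices, with the downstream structural
analyses built on top of them:

- **restraints** — contact→distance conversion via a cube-root scaling law
  (`d(l) = 2R (l/L)^(1/3)`, defaults R = 10 μm, L = 6 Gb), log-log
  interpolation on the empirical contact-decay curve, and 200 kb × 200 kb
  block smoothing of contacts beyond 2 Mb;
- **optimizer** — bead-spring optimization (harmonic bonds + asymmetric
  restraint potential: quadratic above target, logarithmic wall below) with
  an adaptive timestep inversely proportional to the maximum force and
  periodic random velocity kicks; ensembles from random initial coils;
- **ensemble** — restraint-satisfaction statistics (fraction of distances
  within 0.5–2× of target), inverse mapping back to a modeled contact
  matrix, Kabsch-RMSD clustering with representative selection, local
  spatial density;
- **compartments** — A/B compartment calling (observed/expected
  normalization → correlation matrix → two-way spectral split oriented by a
  genome track), per-bin degree of compartmentalization (log ratio of mean
  normalized contacts with A vs B), track correlations, per-bp overlap
  fractions for segment annotations;
- **chromatin_types** — two-type chromatin segment classification from
  log-variance contact features at log-spaced genomic separations (k-means
  seeding on ≥500 kb segments, LDA with 80/20 split and 5-fold CV,
  application to segments ≥300 kb);
- **synthetic** — seed-deterministic generators for ground-truth structures
  (jittered space-filling polymer with radial A/B segregation), forward
  Hi-C simulation with Poisson counting noise, planted plaid compartment
  matrices, two-type segment cohorts and correlated feature tracks;
- **stats** — masked Pearson correlation and Welch's unequal-variances
  t-test.

## Command-line interface

All stages are subcommands of `hic3d`, composable through plain-text files.
Every run writes `<out>.manifest.json` with the stage parameters and seed.
Global options: `--config defaults.json` (per-subcommand option defaults,
overridden by flags), `--threads` (results are thread-count independent),
`--log-level`.

```sh
# synthetic inputs with planted ground truth
hic3d simulate plaid     --n-bins 400 --seed 7 --out-prefix sim/
hic3d simulate structure --n-bins 200 --seed 7 --out-prefix sim/
hic3d simulate typed     --n-segments 200 --seed 7 --out-prefix sim/

# modeling pipeline
hic3d restraints --matrix M.tsv --binsize 50000 --out restraints.tsv
hic3d model      --restraints restraints.tsv --models 20 --steps 20000 \
                 --seed 7 --out ensemble.txt
hic3d evaluate   --ensemble ensemble.txt --restraints restraints.tsv \
                 --out summary.json
hic3d invmap     --ensemble ensemble.txt --matrix M.tsv --matrix-out modeled.tsv

# analyses
hic3d compartments --matrix M.tsv --orient cpg.bedGraph --out profile.bed
hic3d mapfeature   --profile profile.bed --track rt.bedGraph \
                   --window 200000 --out corr.json
hic3d classify     --matrix M.tsv --segments pmds.bed --seed 7 --out types.bed
```

## File formats

- **Dense TSV contact matrix** — tab-separated floats, no header, row *i* is
  bin *i*; bins are fixed-size, 0-based half-open (`--binsize`, `--chrom`).
- **Cooler-style matrix** (optional, HDF5) — datasets
  `bins/{chrom,start,end}` and upper-triangle `pixels/{bin1_id,bin2_id,count}`.
- **bedGraph / BED** — native 0-based half-open coordinates.
- **Conformation table** — `#chrom=`, `#bin_size=`, `#n_bins=` header lines,
  then whitespace columns `model bin x y z` with coordinates in μm.
- **Restraint table** — header metadata plus columns `i j target_um weight`,
  bond lengths in a `#d_eq=` line.
- **Compartment profile BED** — `chrom start end label degree` per bin.

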