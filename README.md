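# spiscreen

Quantitative analysis of **synthetic physical interaction (SPI) screens** in
budding yeast: colony-array growth quantification, plate normalization, log
growth-ratio hit calling with replicate retesting, checkpoint-suppression
classification, 3D nuclear fluorescence measurement, and exact statistics for
counted cells.

In an SPI screen, a bait protein fused to a GFP-binding nanobody (GBP) is
forced onto each GFP-tagged protein of an arrayed strain collection.  If the
forced association harms the cell — for example by activating the spindle
assembly checkpoint — the strain's colonies grow smaller than those carrying
control plasmids.  The readout is therefore a grid of colony sizes on scanned
agar plates (1536 colonies per plate; each strain pinned as a block of 16 or
4 replicates), and the analysis problem is to turn those sizes into
calibrated per-strain effect estimates and a confirmed hit list.

## The core statistic

Colony sizes on each plate are first normalized to a **median of 1**, which
cancels multiplicative plate-to-plate growth differences.  For each strain
the mean control size (averaged over the control plasmids) is compared with
the mean experimental size to give a growth ratio, reported on the natural
log scale:

```
LGR = ln( mean control size / mean experimental size )
```

An LGR of 0 means equal growth; LGR 1 means the experimental colony is ~37 %
of the control size; the conventional hit threshold LGR > 0.4 corresponds to
experimental colonies below two-thirds of control size.  A proteome-scale
screen at 4 replicates is ranked by the **z score** of each strain's LGR
(sample-sd standard score across all screened strains), the strongest
interactions are retested at 16 replicates, and hits are called at
LGR > 0.4 in the retest.  Screens repeated in checkpoint-deletion
backgrounds (e.g. *mad3∆*) classify each hit as `suppressed`
(checkpoint-mediated) or `not_suppressed`.

Around that core the package provides:

- `spiscreen.synthetic` — forward models with known ground truth: colony
  screens with planted hits, rendered plate scans, two-channel 3D nuclear
  stacks, binomial cell-count tables.
- `spiscreen.colony` — grid detection and per-cell colony measurement on
  plate images.
- `spiscreen.screen` — normalization, LGR, z scores, retest selection, hit
  calling.
- `spiscreen.suppression` — deletion-background and mutant-bait comparisons.
- `spiscreen.fluor` — 3D nuclear segmentation and background-shell-corrected
  mean intensities (shell 3 pixels outside the nucleus).
- `spiscreen.counts` — Fisher's exact test by direct hypergeometric
  enumeration, Clopper–Pearson intervals, plasmid/chromosome-loss rates.
- `spiscreen.pipeline` / `spiscreen.cli` — a `spiscreen` command with
  `simulate`, `render`, `quantify`, `screen`, `suppress`, `fluor`, `counts`
  and `run` (YAML-configured, manifest-writing) subcommands.

## Worked example

The numbered scripts under `analysis/` run the whole story on synthetic data
(each regenerates its inputs; run them in order from the repository root):

```sh
python analysis/01_simulate_screen.py
python analysis/03_score_and_retest.py
```

prints

```
simulated 1000 strains x 4 replicates on 3 plates per plasmid (3 plasmids); 10 planted hits with true LGR 0.85-1.30; tables in .../results/screen
scored 1000 strains; top-50 z selection contains 10/10 planted hits
16-replicate retest called 10 hits at LGR > 0.4: 10 true, 0 false; max |estimated - true LGR| = 0.226
```

i.e. all ten strains planted with a true growth defect (LGR ≥ 0.85) rank in
the top 50 of 1000 by z score, the 16-replicate retest confirms exactly
those ten with no false positives, and each effect size is recovered to
within ~0.2 natural-log units.  `analysis/02_quantify_plate_images.py`
replays the screen through rendered 300-dpi plate scans (grid centres
recovered to 0.04 px, Spearman 0.997 between measured and true sizes);
`04_suppression.py`, `05_fluorescence.py` and `06_count_statistics.py` do the
same for the suppression, imaging and counting arms.

Equivalent one-off runs are available from the CLI, e.g.:

```sh
spiscreen simulate --n-strains 384 --hit strain-0002=1.0 --outdir sim
spiscreen screen --experimental experimental \
    --table experimental=sim/colonies_experimental.tsv \
    --table control-1=sim/colonies_control-1.tsv \
    --table control-2=sim/colonies_control-2.tsv
spiscreen counts --fisher 71 70 28 532 --ci 71 141
```

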