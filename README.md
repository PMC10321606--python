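# artidelta

Analysis pipeline for articulatory ultrasound in a two-condition
question-answering (turn-taking) design:

- **Delta extraction** — converts a grayscale ultrasound frame stack into a
  movement-magnitude time series (the Euclidean distance between the pixel
  intensities of consecutive frames), anchored to the trial clock via a
  sync pulse.
- **Epoching** — sequential trial exclusion (incorrect / too-slow responses,
  hesitations, hard-to-image onset phonemes), time-locking to three event
  anchors (TL1 = question offset, TL2 = critical-word onset,
  TL3 = response onset), and per-participant condition averages on a common
  uniform grid with per-timepoint trial counts.
- **Cluster statistics** — timepoint-wise paired t-tests, suprathreshold
  clustering with mass = sum of t, and a sign-flip permutation null of the
  maximum |cluster mass| (Monte-Carlo or exhaustive), Bonferroni-corrected
  across locks.
- **RT model** — per-condition response-time summaries and a linear
  mixed-effects model with crossed random intercepts for participant and
  item (REML via statsmodels).
- **Synthetic data generator** — trial timelines with right-skewed,
  condition-dependent response times, latent tongue-speed kinematics
  (declining baseline, condition-dependent preparatory ramp, articulation
  burst), and rendered ultrasound-like frame stacks, so the whole pipeline
  is testable end to end without any recordings.

## CLI

```bash
artidelta simulate --config run.yaml --out data/ --seed 1
artidelta extract  --in data/ --events data/events.csv --norm none --out traces/
artidelta epoch    --traces traces/ --events data/events.csv --lock TL1 --out epochs/
artidelta cluster  --averages epochs/ --lock TL1 --n-perm 1000 --seed 2 --out stats/
artidelta rt       --events data/events.csv
artidelta run-all  --config run.yaml --out results/ --seed 1
artidelta plot     --bundle-dir results/ --lock TL1 --out tl1.svg
```

`run-all` chains everything in memory and writes `bundle.json` (exclusion
report, clusters with permutation p values, RT model, provenance including
all seeds), per-lock grand-average CSVs, and figures. Frame stacks are
8-bit grayscale multi-page TIFFs (`P<participant>_I<item>_<condition>.tif`)
or a documented raw binary format; events tables are plain CSV with times
in seconds.

A YAML config can override any generator, exclusion, or permutation
parameter; see `RunConfig.from_dict` in `src/artidelta/pipeline_io.py` for
the schema.

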