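# fpdscore

Automated scoring of footpad dermatitis (FPD) in poultry from RGB images,
together with the agreement/performance statistics used to validate such a
system against human observers, and a seeded synthetic foot-image generator
with full ground truth so the whole pipeline is testable offline.

## What it does

- **Imaging pipeline** (`fpdscore.imaging`): segments a foot against a blue
  background (HSV hue window + saturation), locates the metatarsal footpad
  as the largest inscribed circle of the morphologically opened foot mask
  (Euclidean distance transform), detects dark lesions inside the footpad
  with two algorithm variants — `AUT1` (single darkness threshold) and
  `AUT2` (two intensity strata plus shape-based pseudo-lesion rejection) —
  and maps the lesion/footpad area ratio onto the 5-level Hocking severity
  scale (half-open classes at 10 / 25 / 50 %). Stage failures become QC
  flags on the output record, never silent drops.
- **Synthetic generator** (`fpdscore.synthetic`): renders feet (circular
  pad, three tapering toe strips of phalange segments, irregular lesion
  blobs grown to a target area fraction) with controllable severity level,
  presentation skew, laterality and noise; emits exact ground-truth masks.
  Deterministic under a seed; per-foot seeds are split counter-style so
  flock generation is order-independent.
- **Agreement statistics** (`fpdscore.agreement`): Krippendorff's alpha
  (nominal / ordinal / interval) from a coincidence matrix with
  unit-resampling bootstrap CIs, one-vs-rest sensitivity / specificity /
  PPV / NPV / accuracy with binomial SEs (both gold-standard orientations),
  per-level deviation summaries, Landis–Koch verbal bands.
- **Detection audit** (`fpdscore.audit`): grades footpad localisation
  (0–3), alteration-area estimation (0/1/3) and presentation angle (0–2)
  against ground truth, and summarises audit distributions per stratum.
- **Fixtures** (`fpdscore.fixtures`): two packaged 5×5 human-vs-automated
  confusion matrices (`table3a`, n = 2,646; `table3b`, n = 2,510) used by
  the agreement reports and acceptance checks.

## CLI

```bash
# simulate a flock of 50 synthetic feet with ground truth
fpdscore simulate --n 50 --seed 1 --out flock/

# score every image in a directory (exit 2 if unscorable feet are present)
fpdscore score flock/ --algorithm AUT2 --out scores.csv

# agreement report from a packaged fixture or a ratings CSV
fpdscore agree table3a
fpdscore agree ratings.csv --metric ordinal --n-boot 5000 --seed 1

# simulate + score + audit detection quality
fpdscore audit --n 60 --seed 1 --out audit.csv
```

`score` writes one CSV row per foot (`foot_id, laterality, algorithm,
level, ratio, footpad_area_px, lesion_area_px, qc_flag`) and echoes the
fully resolved configuration next to the output. All defaults can be
overridden from a YAML config (`--config`), e.g.:

```yaml
algorithm: AUT2
thresholds:
  t1: 0.10
  t2: 0.25
  t3: 0.50
color:
  k_dark: 0.45
  k_intermediate: 0.65
```

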