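# pigbout

Bout-level quantification of agonistic behavior in group-housed pigs
from per-frame detection streams.

## The problem

Aggression, ear biting and tail biting in weaned pigs are welfare
problems that are expensive to score by hand: a trained observer coding
24 h of video is the bottleneck of every enrichment or management study.
A common automation route mounts an overhead camera over the pen,
samples it at 1 frame per second, and runs an object detector that
labels each frame with the agonistic behaviors it shows. That raw
stream — one CSV row per detection, with house channel, date,
second-of-day timestamp, class and confidence — is not yet biology:
single frames are not behaviors. `pigbout` implements the
post-processing chain that turns frame detections into interpretable
behavioral measurements, and the statistics used to validate it:

1. **Confidence filtering and rasterisation** — detections with score ≥
   0.45 are collapsed to a per-second binary presence series per class
   and day (`detection_io`).
2. **Bout segmentation with temporal hysteresis** — a bout opens when a
   class is present for ≥ 5 consecutive s (aggression) or ≥ 3 s (ear /
   tail biting) and closes after ≥ 5 s of absence; shorter absences are
   bridged. Intervals are half-open `[start, end)` seconds-of-day and
   duration is the timestamp difference (`bouts`). A second, independent
   implementation (`find_bouts_oracle`) exists purely to cross-check the
   first.
3. **Daily and weekly metrics** — bout count/day, total duration/day,
   mean duration per bout, plus pen-level growth (ADG, hay-inclusive
   ADFI, FCR = ADFI/ADG) and ordinal welfare scores (`summary`).
4. **Detector evaluation** — IoU-based greedy matching, precision,
   recall, F1 = 2PR/(P+R), all-point-interpolated AP and mAP50, and a
   background-augmented confusion matrix (`detection_eval`).
5. **AI-vs-manual agreement** — Pearson *r*, the single-measure
   two-way-random absolute-agreement intraclass correlation ICC(A,1)
   (a.k.a. ICC(2,1)), and Cohen's κ on per-second presence labels, after
   explicit overlap-based bout alignment (`agreement`).
6. **Synthetic data** — a seeded generator (`simulate`) that emulates
   the study design: Poisson daily bout counts with a group (enrichment)
   effect and a log-linear day trend, lognormal bout durations, per-second
   detector misses, spurious false-positive seconds, Beta-distributed
   confidences, and observer-noise-corrupted manual coding. Every
   pipeline stage is testable without any video.

## Worked example

Simulate a week of control and enriched pens, segment the control
detector stream into bouts, and validate it against the simulated
manual coding:

```bash
pigbout simulate --seed 42 --days 7 --out demo/sim
# control: 7 days, 3213 true bouts, 84367 detections, 3068 manual bouts
# treatment: 7 days, 1259 true bouts, 34762 detections, 1193 manual bouts

pigbout bouts --detections demo/sim/control/detections.csv --out demo/ai
# aggressive: 366 bouts over 7 day(s)
# ear_biting: 2097 bouts over 7 day(s)
# tail_biting: 744 bouts over 7 day(s)

pigbout validate --ai demo/ai/bouts.csv \
                 --manual demo/sim/control/manual_bouts.csv --out demo/val
#       class            metric        r      icc    kappa  n_units
#  aggressive       event_count 0.981805 0.949721 0.909223        7
#  aggressive    total_duration 0.952232 0.951127 0.909223        7
#  aggressive duration_per_bout 0.956116 0.924280 0.909223        7
#  ...
```

The first day of `demo/ai/daily_summary.csv` reads

```
date,class,bout_count,total_duration_s,mean_duration_per_bout_s
2024-07-15,aggressive,60,1461,24.35
2024-07-15,ear_biting,354,9880,27.90960451977401
2024-07-15,tail_biting,117,2865,24.487179487179485
```

i.e. on 15 July the pipeline measured 60 aggressive bouts totalling
1461 s at 24.4 s per bout — close to the generator's configured control
regime (≈ 60 aggressive bouts/day at ≈ 28 s per bout, declining over
days). In the agreement table, *r* ≈ 0.95–0.99 and ICC ≈ 0.85–0.98
show that, at the configured detector noise (5% per-second miss rate,
5 false-positive seconds/day/class) and observer noise (2 s boundary
jitter, 5% missed bouts), AI-derived and manually coded daily metrics
agree strongly; κ ≈ 0.91 is the chance-corrected per-second agreement.

Other subcommands: `summarize` (daily + weekly tables from a bout CSV),
`evaldet` (box-level P/R/F1/AP50 + confusion matrices), `growth`
(pen-week ADG/ADFI/FCR). The same functionality is importable from the
`pigbout` package; see the module docstrings.

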