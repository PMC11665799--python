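# toolmotion

Motion-efficiency skill assessment for ultrasound-guided needle
interventions, computed purely from video object detections.

In procedures such as percutaneous nephrostomy, trainees are traditionally
assessed with expert rubrics or electromagnetic tool tracking — both hard
to deploy in low-resource training settings. An alternative is to point two
consumer webcams at the workspace, run an object detector that outputs a
bounding box per tool per frame (an ultrasound probe and a needle), and
summarize each training trial with motion-efficiency metrics derived from
those boxes alone. `toolmotion` implements that analysis pipeline:

- **Per-trial metrics** (7 numbers per trial). With $B_t$ the
  highest-confidence box of a tool on frame $t$, center $c_t$ and corners
  $k_t^{(j)}$, $j \in \{TL, TR, BR, BL\}$, and $V$ the set of frames where
  the tool is detected:
  - *total procedure time* $= N / f$ (frame count over frame rate),
  - *tool usage time* $= |V| / f$ per tool,
  - *center path length* $= \sum_{t_i \in V} \lVert c_{t_{i+1}} - c_{t_i} \rVert$
    (pixels; gaps in visibility are bridged, not skipped),
  - *corner path length* $= \sum_{t_i \in V} \sum_j \lVert k_{t_{i+1}}^{(j)} - k_{t_i}^{(j)} \rVert$,
    which also picks up box-size change.

  With two synchronized cameras each metric is computed per view and the
  per-trial value is the maximum of the two.
- **Group statistics**: pooled-variance independent t-tests comparing
  novice vs. expert trials per metric, paired t-tests on each participant's
  first vs. last trial, and learning curves normalized by the minimum
  expert value of each metric.
- **Detector evaluation**: IoU, greedy confidence-ranked matching, average
  precision (all-point PR envelope, PASCAL VOC 2010+ style) and mAP at
  IoU 0.5, plus a leave-two-user-out cross-validation fold planner that
  reserves one novice + one expert per test fold.
- **Synthetic studies**: a seeded generator that emulates the study design
  (6 novices + 6 experts x 4 trials, two 640x480 streams at 10 fps, trial
  lengths 105-672 s) with group-dependent motion efficiency, Markov-chain
  tool visibility, and detector noise (misses, jitter, duplicates), so the
  whole pipeline can be exercised and power-checked without video data.

I/O is plain text: COCO-style JSON or YOLO-style per-frame text for
detections, CSV manifests and metric tables, JSON reports.

## Worked example

```python
import toolmotion as tm

config = tm.SimulationConfig()            # the default study conditions
study = tm.simulate_study(config, 1)      # 48 trials, seeded
table = tm.metrics_table([t.detected for t in study])

print(table.groupby("group")[["total_procedure_time",
                              "usage_time_needle",
                              "center_path_needle"]].mean().round(1))
for res in tm.compare_groups(table):
    print(f"{res.metric}: t = {res.statistic:.2f} (df = {res.degrees_of_freedom})")
```

prints

```
        total_procedure_time  usage_time_needle  center_path_needle
group
expert                 142.4               56.9              2905.7
novice                 266.6              101.6              6438.7

total_procedure_time: t = 5.22 (df = 46)
usage_time_probe: t = 5.00 (df = 46)
usage_time_needle: t = 4.95 (df = 46)
center_path_probe: t = 6.17 (df = 46)
center_path_needle: t = 5.81 (df = 46)
corner_path_probe: t = 5.88 (df = 46)
corner_path_needle: t = 5.58 (df = 46)
```

Novices in this synthetic cohort take ~1.9x longer, keep the needle in
view ~1.8x longer and move it ~2.2x further than experts; with 24 trials
per group every metric separates the groups decisively (all p < 1e-4 here;
positive t means novices score higher). The same analysis runs from the
shell against files on disk:

```sh
toolmotion simulate --seed 1 --out study/
toolmotion metrics --manifest study/manifest.csv --out metrics.csv
toolmotion stats --metrics metrics.csv --out stats.json
toolmotion eval-detector --manifest study/manifest.csv --out eval.json
# or everything at once:
toolmotion run --seed 1 --out results/
```

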