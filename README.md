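# ccfd — choriocapillaris flow deficits around geographic atrophy

`ccfd` quantifies choriocapillaris (CC) flow deficits on en-face OCT
angiography in eyes with geographic atrophy (GA), and relates the
perilesional deficit burden to how fast the lesion grows. It is written for
retinal-imaging researchers who need a reproducible, scriptable version of
the standard reading-centre workflow — and for methodologists studying how
the choice of axial slab changes the answer.

The pipeline, per eye and per slab:

1. **Compensation** — the flow image is multiplied by the inverted, 3 × 3
   Gaussian-smoothed structural image, correcting signal attenuation under
   RPE pathology.
2. **Binarization** — Phansalkar local thresholding, circular window of
   radius 3 px (≈17.6 µm on the 6 × 6 mm / 1024 × 1024 export grid):
   `t = m·(1 + p·e^(−q·m) + k·(s/r − 1))`, (k, r, p, q) = (0.25, 0.5, 2, 10);
   pixels below `t` are flow deficits.
3. **Particle filtering** — 8-connected deficits narrower than 24 µm
   (area-equivalent diameter) are excluded as normal intercapillary spacing.
4. **Rings** — successive 100-µm-wide concentric rings around the GA border,
   built from the Euclidean distance transform of the lesion mask; FD% =
   deficit area / ring area × 100 per ring.
5. **Growth** — square-root yearly enlargement rate
   `yER = (√GA2 − √GA1)/FU` (mm/yr) from baseline and follow-up lesion
   areas.
6. **Statistics** — per-ring, per-slab Spearman correlation of FD% with
   yER; paired Wilcoxon tests between slabs; two-grader ICC(2,1).

Because real OCTA exports of this kind are not publicly deposited, the
package ships a first-class synthetic cohort generator
(`ccfd.synthetic`) that emulates the inputs: capillary texture with a
tunable deficit fraction, a perilesional deficit gradient whose severity
drives lesion growth, slab-dependent RPE/BM-contamination that destroys the
signal in the shallow (11–21 µm) slab while sparing the deeper 21–31 and
31–41 µm slabs, and duplicate grader delineations. See `docs/methods.md`
for the model and its limitations.

## Worked example

```python
import dataclasses
from ccfd import SynthConfig, ImageGeometry
from ccfd.experiments import run_cohort, SHALLOW_SLAB, DEEP_SLAB

config = dataclasses.replace(
    SynthConfig(),                      # the default study conditions
    geometry=ImageGeometry(6.0, 256),   # coarse grid for a quick demo
    seed=42,
)
result = run_cohort(config, slabs=(SHALLOW_SLAB, DEEP_SLAB), n_graders=1)
print(result.summary().round(2))
print(result.ring_correlations().query("ring <= 6").round(3).to_string(index=False))
```

which prints

```
                 median     q1     q3   n
yer_mm             0.16   0.11   0.24  31
ga1_mm2            0.42   0.25   1.43  31
ga2_mm2            0.98   0.58   1.91  31
fu_years           1.35   1.26   1.37  31
fd_pct[11-21um]   48.04  42.96  52.91  31
fd_pct[21-31um]   27.31  26.49  29.03  31
   slab  ring    rho  p_value  n
11-21um     1 -0.138    0.459 31
11-21um     2 -0.091    0.627 31
11-21um     3 -0.183    0.325 31
11-21um     4 -0.030    0.872 31
11-21um     5  0.004    0.981 31
11-21um     6 -0.029    0.877 31
21-31um     1  0.806    0.000 31
21-31um     2  0.815    0.000 31
21-31um     3  0.836    0.000 31
21-31um     4  0.746    0.000 31
21-31um     5  0.625    0.000 31
21-31um     6  0.575    0.001 31
```

Reading the output: the cohort's median enlargement rate is ~0.17 mm/yr.
The contaminated shallow slab carries a far higher whole-image FD% than the
deep slab (the artifact raises the apparent deficit burden), yet none of
its perilesional rings correlates with growth; on the clean deep slab the
FD% of every ring within 600 µm of the border correlates with yER at
p < 0.05 — the slab-selection effect the pipeline is designed to expose.

## Command line

```sh
ccfd simulate --seed 7 --n-eyes 31 --grid 256 --out cohort/
ccfd analyze cohort/ --out results/
ccfd report results/
```

`simulate` writes one directory per eye (slab images as TIFF, lesion masks
as PNG, truth and metadata as JSON) plus a manifest CSV; `analyze` writes
tidy CSV tables (per-ring FD%, growth, correlations, slab tests, summary,
agreement) and a run log; `report` renders the ring-by-slab rho/p matrix as
markdown.

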