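# zygoquant

Quantification of sperm-content dynamics in *C. elegans* meiotic zygotes:
movement of the sperm contents under cytoplasmic streaming, scatter of
paternal mitochondria around the sperm DNA, and capture of the sperm DNA by
the meiotic spindle.

## The problem

Fertilisation happens before oocyte meiosis finishes, so the sperm DNA
shares the zygote with an active meiotic spindle. If cytoplasmic streaming
carries the sperm contents too close, spindle microtubules can capture the
paternal chromosomes — with the risk of their expulsion into a polar body.
Quantifying this requires three measurements from imaging data, which this
package implements as a tested, reusable pipeline:

* **Track metrics** — the sperm contents are tracked as the centre of the
  maternal ER ring around the sperm DNA in 5-s time-lapse video. Per meiotic
  phase (MI, AI, MII, AII, supplied as frame windows) the pipeline reports
  max x/y displacement (max − min coordinate per axis), displacement
  (first-to-last distance), distance traveled (path length), maximum average
  velocity (max of 3-point moving averages of frame-to-frame speeds), and
  phase duration.
* **Scatter statistic** — in fixed-embryo z-stacks, each mitochondrial focus
  contributes its 3-D distance to the sperm-DNA centroid. Brighter amorphous
  masses are weighted by integer multiplicity: ROI mean ÷ average punctum
  mean, rounded (a region 3× as bright counts as 3 mitochondria). Per embryo
  the weighted distance list is summarised by its mean and sample SD.
* **Capture classification** — a capture event is an approach of the sperm
  contents within 5.5 µm (centre to centre) of the spindle after which the
  sperm stops moving relative to it (default: < 1 µm cumulative relative
  displacement over 6 frames). Events are classed none / transient / stable
  / transient-then-stable and tallied into group contingency tables.
* **Statistics layer** — Shapiro-Wilk-gated choice between Welch's t /
  Welch's ANOVA and Mann-Whitney / Kruskal-Wallis, plus Brown-Forsythe for
  variances and Fisher's exact test for capture frequencies.

Because raw microscope data for this system is not generally available, the
package ships a ground-truthed **synthetic-zygote generator**: an ellipsoid
embryo (default 50 µm × 25 µm) with a Gaussian cloud of mitochondrial puncta
and masses around the sperm DNA, three streaming regimes (jostling,
short-axis and long-axis rotation), depletion modes that raise streaming
amplitude (katanin/kinesin-13-like) or cloud dispersion (ataxin-2-like), and
programmed spindle-capture scenarios. Every downstream stage is validated
against this generator's ground truth. See `docs/methods.md` for models,
defaults and limitations.

## Worked example

```python
import numpy as np
from zygoquant import SceneConfig
from zygoquant.synthetic import sample_puncta, simulate_capture_scenario
from zygoquant.scatter import Punctum, scatter_profile
from zygoquant.capture import classify_tracks
from zygoquant.tracks import Trajectory

# scatter of a control vs an ataxin-2-like dispersed cloud
for mode in ("control", "atx2_like"):
    cfg = SceneConfig(seed=1, n_puncta=30, n_masses=3, depletion_mode=mode)
    dna, truth = sample_puncta(cfg)
    puncta = [Punctum(tuple(p.position_um), p.true_intensity, p.true_intensity,
                      p.true_multiplicity, p.true_multiplicity > 1)
              for p in truth]
    prof = scatter_profile(puncta, dna, phase="AI", embryo_id=mode)
    print(f"{mode}: n={prof.distances_um.size} weighted distances, "
          f"mean={prof.mean_um:.2f} um, sd={prof.sd_um:.2f} um")

# a programmed stable capture, recovered by the classifier
cfg = SceneConfig(seed=1, capture_scenario="stable")
sperm, spindle, _ = simulate_capture_scenario(cfg)
ev = classify_tracks(Trajectory.from_points(sperm),
                     Trajectory.from_points(spindle))
print(f"capture: {ev.classification}, min distance {ev.min_distance_um:.2f} um")
```

prints

```
control: n=42 weighted distances, mean=1.36 um, sd=0.47 um
atx2_like: n=42 weighted distances, mean=4.09 um, sd=1.41 um
capture: stable, min distance 3.98 um
```

The control cloud (σ = 1 µm) has mean punctum-DNA distance near the
isotropic-Gaussian expectation 2σ√(2/π) ≈ 1.60 µm (this single embryo draws
slightly low; the 50-embryo recovery test pins the average down); the
ataxin-2-like mode
triples σ and the scatter mean and SD rise accordingly. The programmed
approach dips below the 5.5 µm threshold and sticks, and the classifier
calls it a stable capture.

A full synthetic experiment (simulate → quantify → classify → compare) runs
from the command line:

```sh
zygoquant all --outdir results/demo --seed 1
```

writing trajectories, per-embryo scatter profiles, track metrics, capture
events with a contingency table, and a statistics report (test chosen by the
normality gate, p-value, significance stars) as CSV/TSV with the config hash
and seed embedded in every file.

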