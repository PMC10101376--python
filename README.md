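# cognimage

Knowledge-based medical image understanding: a human-readable semantic-network
knowledge base drives a blackboard multi-agent engine that segments an image,
scores candidate regions against fuzzy anatomical expectations, and explains
its decisions — plus a genetic algorithm that co-optimizes every tunable
knowledge-base parameter against a tuning set.

## Who this is for

Segmentation models (including DNNs) make "obvious" mistakes: a stray
disconnected blob labelled kidney, a tube tip reported safe when it sits on
the carina. `cognimage` is for researchers who want to wrap such models — or
simple classical segmenters — in an explicit, inspectable layer of anatomical
knowledge that reviews candidate regions, rejects implausible ones, outputs
nothing rather than something wrong, and says *why*.

## The model

**Knowledge base.** A semantic network (SN) stored as plain text: a
`node_list` file plus one attribute file per node. Each node is an object
(spine, kidney, carina, safe zone, a decision). Attributes come from a
vocabulary and describe intensity ranges, sizes, spatial relations
(`PartOf`, `NotPartOf`, `LeftOf`, `Above`, `SameLevelAs`, ...), decisions and
learning parameters:

```
IntensityRange 300 2000
NotPartOf dense_bone
LeftOf spine 50 100
SameLevelAs kidney_right_init 30
```

Soft expectations are fuzzy sets: a piecewise-linear membership µ(x) ∈ [0, 1]
over a feature x, linear between vertices and flat outside. A printed range
[a, b] becomes a trapezoid with full confidence on [a, b] and shoulders of
width 0.2·(b−a).

**Blackboard engine.** One Solution Element per node lives on a shared
blackboard. Agents activate one at a time (highest activation score wins):
a scheduler picks the pending element whose prerequisite objects are most
resolved; reasoning derives a search area from spatial relations to
already-recognized objects; segmentation generates candidate connected
components (thresholding, morphology, derived boxes, landmark extraction, or
an external predictor hook for DNNs); reasoning then scores each candidate,

  score(c) = ∏ᵢ µᵢ(xᵢ(c)),

the product of fuzzy memberships over its features, and selects the best —
or rejects all and reports `not_found`. Decision nodes reduce results to an
explained boolean (e.g. "tube tip inside the safe zone"); consistency nodes
cross-check two estimates of the same landmark and report `unreliable` when
they disagree beyond a tolerance.

**Learning (chromosome co-optimization).** Any scalar parameter may carry a
value encoding `{bit_start, bit_end, lower, upper}`: the chromosome bits,
read as an unsigned index, select one of 2ⁿ equidistant values between the
bounds (`00…0` → lower, `11…1` → upper). A seeded GA (population 30,
elitism, tournament selection, single-point crossover, per-bit mutation)
maximizes a weighted per-node fitness (Dice, confusion-matrix metrics, or a
point-distance score) over a tuning set.

Everything runs on bundled synthetic phantoms with ground truth — an
abdominal-CT-like volume (spine, two kidneys, a stray distractor blob) and a
chest-radiograph-like image (trachea, carina, endotracheal tube) — so no
external data is needed.

## Worked example

```python
from cognimage import apps, make_abdominal_phantom, run_think, summary_report
import tempfile

net = apps.kidney_kb(tempfile.mkdtemp())     # write + parse the kidney KB
ph = make_abdominal_phantom(seed=0)          # CT-like phantom with ground truth
bb = run_think(net, ph.image, ph.spacing)    # the think loop
print(summary_report([bb], case_ids=["phantom_0"]).to_string(index=False))
```

```
     case              node     status  score  n_candidates  volume_mm3 decision explanation
phantom_0        dense_bone recognized    1.0             1     45600.0     None
phantom_0       kidney_left recognized    1.0             1     12900.0     None
phantom_0  kidney_left_init recognized    1.0             1     12900.0     None
phantom_0      kidney_right recognized    1.0             1     12900.0     None
phantom_0 kidney_right_init recognized    1.0             1     12900.0     None
phantom_0             spine recognized    1.0             1     45600.0     None
```

All six objects are recognized; the selected left kidney (12 900 mm³, the
analytic ellipsoid volume) contains **0** voxels of the stray distractor
blob, and its Hausdorff distance to ground truth is **0.0 mm** versus
**140.0 mm** for the raw threshold output that still contains the stray blob,
the other kidney and the spine — the reasoning layer is what removes the
distant spurious structure.

The same engine drives the tube application: with the tube tip 50 mm above
the carina the decision node reports `et_tube_correct = True`
("et_tip is inside et_zone"); at 10 mm it reports `False` with
"tip too low relative to the carina"; and when the two carina estimates
disagree by 25 mm at a 10 mm tolerance the system answers
"unable to reliably identify carina_3" instead of guessing.

A command-line surface wraps the library: `cognimage think`, `cognimage
learn`, `cognimage summarize`, `cognimage fixtures` (see `--help`).

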