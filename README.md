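# tmagraph

Automatic tumor–stroma separation in fluorescence tissue-microarray (TMA)
core images using **only the DAPI channel**.

Quantitative biomarker studies on TMAs need to know which cells belong to
the tumor and which to the surrounding stroma. In triple-negative breast
cancer no reference biomarker (ER, PR, Her2) is available, so the
separation must come from morphology alone — and in immunofluorescence the
only channel guaranteed to be present is the DAPI nuclear counterstain.
`tmagraph` implements a cell-graph pipeline for exactly this setting:

1. **Preprocessing** — flat-field (shading) correction, suppression of
   diffuse background below intensity 25, 3×3 median smoothing, Otsu
   binarization, removal of objects < 150 px, of isolated nuclei (no
   neighbour within a 20 px-expanded bounding box) and of large saturated
   "overstained" blobs.
2. **Segmentation** — the masked image is split at an Otsu threshold into
   bright and dark nuclear populations; each is seeded by the h-maxima
   transform and segmented by seeded watershed.
3. **Cell graphs** — nuclei *u*, *v* are linked iff their masks, dilated by
   a diamond of radius 2, intersect (equivalently: city-block distance
   ≤ 4 px) **and** |x̄ᵤ − x̄ᵥ| < 30 grey levels. Connected subgraphs are the
   classification units; tumor nuclei are darker and tighter packed, so
   tumor nests form large dark subgraphs.
4. **Features & classification** — 22 features per subgraph: 10 topological
   (nodes, edges, average degree, diameter, radius, central points, average
   clustering coefficient, end nodes, % end nodes, hop-plot exponent) and
   12 averaged nucleus features (area, eccentricity, equivalent diameter,
   extent, axes, perimeter and five intensity statistics). Features are
   min–max normalized to [0,1], ranked by the F-score

   F(i) = [ (x̄ᵢ⁺−x̄ᵢ)² + (x̄ᵢ⁻−x̄ᵢ)² ] / [ s²ᵢ⁺ + s²ᵢ⁻ ],

   the top 15 feed an RBF-kernel SVM (labels: +1 tumor, −1 stroma) and each
   subgraph's label is propagated to its member nuclei.
5. **Single-cell fallback** — nuclei in no subgraph are tested by two
   stromal rules (inflammatory: bright, round [4πS/w² above threshold],
   area < 500 px; fibroblast: eccentricity √(1−(d_min/d_max)²) > 0.9) and
   the remainder classified by a per-nucleus SVM on the 12 node features.

A synthetic-core generator (`tmagraph.synthetic`) renders DAPI-like cores —
dark clustered tumor nuclei, brighter sparse stroma with elongated
fibroblasts and small bright lymphocytes, multiplicative shading, noise and
saturated blobs — with exact per-nucleus ground truth, so the whole
pipeline is testable without real slides.

## Worked example

```python
from tmagraph import PipelineConfig, evaluate_classification, generate_core
from tmagraph.pipeline import (predict_core, process_core, train_models,
                               truth_for_records)
from tmagraph.synthetic import default_spec
import pandas as pd

cfg = PipelineConfig()
train = [generate_core(default_spec(rng_seed=100 + i)) for i in range(10)]
graph_model, node_model, _ = train_models(train, cfg)

rows = []
for i in range(20):
    image, truth = generate_core(default_spec(rng_seed=200 + i))
    result = process_core(image, cfg)
    pred = predict_core(result, graph_model, node_model, cfg)
    per_rec = truth_for_records(result.records, truth)
    pred["truth"] = [per_rec[lab] for lab in pred["label"]]
    pred["core_id"] = i
    rows.append(pred)

report = evaluate_classification(pd.concat(rows, ignore_index=True))
print(f"overall {report.overall_mean:.2f}(±{report.overall_sd:.2f})  "
      f"tumor {report.tumor_mean:.2f}(±{report.tumor_sd:.2f})  "
      f"stroma {report.stroma_mean:.2f}(±{report.stroma_sd:.2f})")
```

prints (training on 10 synthetic cores, testing on 20 held-out cores):

```
overall 99.88(±0.53)  tumor 99.79(±0.93)  stroma 100.00(±0.00)
```

— the per-core mean ± sd of the overall accuracy and of the producer's
accuracy (per-class recall) for tumor and stroma. On these synthetic cores
the two classes are nearly perfectly recovered; the numbers measure the
pipeline's internal consistency, not performance on real tissue.

The same protocol is available from the shell:

```sh
tmagraph simulate --seed 9 --out core_dir        # synthetic core + truth
tmagraph preprocess --in core_dir/core.tif --out-dir pre
tmagraph segment --in pre/corrected.tif --mask pre/mask.tif --out-dir seg
tmagraph graph --labels seg/labels.tif --image pre/corrected.tif --out-dir g
tmagraph train --features train.csv --top-k 15 --out model.json
tmagraph run --in core_dir/core.tif --graph-model model.json --out-dir out
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole method from scratch: it generates a seeded synthetic
cohort, trains the subgraph and per-nucleus classifiers on five cores,
segments and classifies ten held-out cores, and prints the segmentation
accuracy and the per-class classification summary before writing the JSON
result map.
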