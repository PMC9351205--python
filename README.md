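# lunggraph

Anatomical lung-graph construction from chest CT and GraphSAGE-style
survival prediction, with a synthetic lung-phantom generator that makes the
whole pipeline testable without any real data or pretrained weights.

The pipeline turns one chest CT (plus a lobe label map and a tumor
annotation) into a 10-node graph — four airway landmarks (trachea root,
carina, distal left/right main bronchi), five lobes, one tumor node — and
trains a graph neural network to predict 5-year overall survival:

1. **phantom** — synthetic CT volumes with a known air-filled Y-shaped
   airway tree, five lobe compartments, a planted tumor, and exponential
   survival times whose hazard depends on tumor diameter (a recoverable
   signal).
2. **airway** — adaptive region growing from a deterministic trachea seed,
   3D skeletonization, and landmark search (root / carina / distal
   bronchi).
3. **sampling** — ten 64x64x64 normalized-intensity patches per patient
   (landmark crops, masked lobe crops, tumor crop).
4. **features** — a 3D conv encoder (randomly initialized by default;
   pretrained encoders plug in through the `Encoder` interface) with global
   average pooling to 1024-d, then a ridge-shrunk PCA reduction to 96-d,
   fitted on training rows only.
5. **lung_graph** — fixed anatomical topology plus tumor-to-host-lobe
   edges; JSON serialization.
6. **gcn** — SageConv blocks with an LSTM neighbor aggregator (canonical
   neighbor order), mean readout, sigmoid head. Implemented in NumPy with
   hand-written backprop (verified against finite differences), Adam,
   plateau learning-rate schedule (0.01 -> 1e-5), weight decay 5e-5.
7. **evaluation** — stratified 75/12.5/12.5 splitting, rank AUC with
   bootstrap CI, sensitivity/specificity/precision/F2, median-split risk
   groups, Kaplan-Meier, log-rank, single-covariate Cox (Newton-Raphson,
   Breslow ties).

Conventions: arrays are (z, y, x) with superior = decreasing z and
patient-left = increasing x; bounding boxes are half-open `[min, max)`;
higher model score = higher predicted 5-year mortality risk.

## CLI

```bash
lunggraph phantom --n 20 --seed 7 --out cohort/          # synthetic cohort (NIfTI + cohort.csv)
lunggraph segment-airway --ct cohort/P00000/ct.nii.gz --out seg/
lunggraph build-graphs --data cohort/ --out graphs/ --seed 0
lunggraph train --graphs graphs/ --out model/ --epochs 100
lunggraph evaluate --graphs graphs/ --model model/model --out metrics.json
lunggraph run-all --out run/ --n 100 --seed 7            # end to end
```

## Notes

- The landmark-search rules are a documented reconstruction of the
  anatomical definitions (root = most superior endpoint, carina = branch
  point nearest the root, distal bronchus = geodesically farthest skeleton
  point per side); no published search algorithm was available.
- Lobe segmentation is taken as input (ground truth from the phantom);
  training/distributing pretrained encoder weights is out of scope.
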