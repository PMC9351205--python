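"""End-to-end pipeline: phantom cohort -> patches -> features -> graphs -> GCN -> metrics.

The pipeline has two landmark sources: the full imaging route (airway
region growing, skeletonization, landmark search) and the phantom's
ground-truth landmarks.  Cohort-scale runs default to ground truth for
speed; the imaging route is exercised end-to-end on single patients and in
the landmark-recovery checks.

The ridge reducer is fitted on training-set rows only, after the cohort
split, so no test information leaks into node features.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from lunggraph import evaluation as ev
from lunggraph.airway import segment_airway
from lunggraph.features import (
    NODE_DIM,
    RAW_DIM,
    Encoder,
    RandomConvEncoder,
    RawFeature,
    NodeFeature,
    fit_reducer,
    reduce_matrix,
)
from lunggraph.gcn import ModelConfig, TrainConfig, TrainedModel, train
from lunggraph.lung_graph import LungGraph, build_graph, save_graph
from lunggraph.phantom import CohortSpec, PhantomSample, cohort_table, iter_cohort
from lunggraph.roles import CANONICAL_ROLE_ORDER, NodeRole
from lunggraph.sampling import extract_patient_patches

logger = logging.getLogger("lunggraph")


def patient_raw_features(
    sample: PhantomSample,
    encoder: Encoder,
    use_segmentation: bool = False,
) -> tuple[np.ndarray, list[NodeRole]]:
    """Run one patient to the 10 x 1024 raw-feature block.

    Returns the block (rows in canonical role order) and the tumor lobes.
    """
    if use_segmentation:
        _, _, marks = segment_airway(sample.ct)
        landmarks = marks.as_dict()
    else:
        if sample.landmarks_truth is None:
            raise ValueError(f"sample {sample.patient_id}: no ground-truth landmarks")
        landmarks = sample.landmarks_truth
    patches = extract_patient_patches(
        sample.ct, landmarks, sample.lobe_labels, sample.tumor_annotation
    )
    from lunggraph.features import encode_patch

    block = np.stack(
        [encode_patch(patches[role], encoder).vector for role in CANONICAL_ROLE_ORDER]
    )
    return block, sample.tumor_annotation.lobe_roles


@dataclass
class CohortGraphs:
    """Result of the graph-construction stage for a whole cohort."""

    graphs: list[LungGraph]
    table: pd.DataFrame
    split: ev.SplitAssignment
    reducer_meta: dict

    def subset(self, ids: Sequence[str]) -> list[LungGraph]:
        wanted = set(ids)
        return [g for g in self.graphs if g.patient_id in wanted]


def build_cohort_graphs(
    cs: CohortSpec,
    encoder: Optional[Encoder] = None,
    ratios: tuple[float, float, float] = (0.75, 0.125, 0.125),
    split_seed: int = 0,
    reducer_penalty: float = 1.0,
    use_segmentation: bool = False,
) -> CohortGraphs:
    """Generate a phantom cohort and build one labelled graph per patient.

    Patients are generated lazily so only raw feature blocks (not volumes)
    stay in memory.  The reducer is fitted on training rows only.
    """
    encoder = encoder or RandomConvEncoder(seed=0)
    blocks: list[np.ndarray] = []
    lobes_per_patient: list[list[NodeRole]] = []
    samples_meta: list[PhantomSample] = []
    t0 = time.time()
    for sample in iter_cohort(cs):
        block, lobes = patient_raw_features(sample, encoder, use_segmentation)
        blocks.append(block.astype(np.float32))
        lobes_per_patient.append(lobes)
        sample.ct = None  # type: ignore[assignment]  # free volume memory
        sample.airway_truth = None  # type: ignore[assignment]
        sample.lobe_labels = None  # type: ignore[assignment]
        samples_meta.append(sample)
    logger.info("cohort feature extraction: %d patients in %.1fs", len(blocks), time.time() - t0)

    table = cohort_table(samples_meta)
    labeled = table.dropna(subset=["label_5yr"])
    split = ev.stratified_split(
        labeled["label_5yr"].astype(int).to_numpy(),
        ratios=ratios,
        seed=split_seed,
        ids=labeled["id"].to_numpy(),
    )
    train_ids = set(split.train)
    train_rows = np.concatenate(
        [b for b, s in zip(blocks, samples_meta) if s.patient_id in train_ids]
    ).astype(np.float64)
    reducer = fit_reducer(
        train_rows,
        penalty=reducer_penalty,
        out_dim=NODE_DIM,
        fitted_on=f"train[{len(train_ids)} patients]",
    )

    graphs = []
    for block, lobes, sample in zip(blocks, lobes_per_patient, samples_meta):
        reduced = reduce_matrix(reducer, block.astype(np.float64))
        features = {
            role: NodeFeature(vector=reduced[i], role=role)
            for i, role in enumerate(CANONICAL_ROLE_ORDER)
        }
        label = sample.survival.label_5yr if sample.survival else None
        graphs.append(
            build_graph(features, lobes, patient_id=sample.patient_id, label=label)
        )
    return CohortGraphs(
        graphs=graphs,
        table=table,
        split=split,
        reducer_meta={
            "penalty": reducer_penalty,
            "out_dim": NODE_DIM,
            "in_dim": RAW_DIM,
            "fitted_on": reducer.fitted_on,
        },
    )


# ---------------------------------------------------------------------------
# Full pipeline with config + survival evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str = "pipeline_out"
    n_patients: int = 100
    seed: int = 7
    ratios: tuple[float, float, float] = (0.75, 0.125, 0.125)
    n_blocks: int = 2
    hidden_dim: int = 32
    dropout_p: float = 0.3
    epochs: int = 40
    batch_size: int = 32
    reducer_penalty: float = 1.0
    use_segmentation: bool = False
    beta_size: float = float(np.log(2.0))
    threshold: float = 0.5

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def evaluate_predictions(
    scores: np.ndarray,
    labels: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    threshold: float = 0.5,
    seed: int = 0,
) -> dict:
    """Classification + survival evaluation of one score vector."""
    metrics = ev.classifier_metrics(scores, labels, threshold=threshold, seed=seed)
    out = {"classification": metrics.to_json()}
    groups = ev.stratify_risk(scores)
    records = ev.records_from_arrays(times, events)
    out["risk_groups"] = {"low": int((groups == 0).sum()), "high": int((groups == 1).sum())}
    if 0 < groups.sum() < groups.size:
        chi2, p = ev.log_rank(groups, records)
        out["log_rank"] = {"chi2": chi2, "p": p}
        km = {}
        for gname, gval in (("low", 0), ("high", 1)):
            est = ev.kaplan_meier([r for r, g in zip(records, groups) if g == gval])
            km[gname] = {
                "times": est.times.tolist(),
                "survival": est.survival.tolist(),
                "at_risk": est.at_risk.tolist(),
            }
        out["kaplan_meier"] = km
        try:
            fit = ev.cox_hr(groups, records)
            out["cox"] = {
                "hazard_ratio": fit.hazard_ratio,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
                "p": fit.p_value,
                "n_events": fit.n_events,
            }
        except (ValueError, RuntimeError) as exc:
            out["cox"] = {"error": str(exc)}
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run phantom generation -> graphs -> training -> evaluation; write artifacts."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logger.info("pipeline start: hash=%s config=%s", chash, config)

    cs = CohortSpec(n_patients=config.n_patients, seed=config.seed, beta_size=config.beta_size)
    cohort = build_cohort_graphs(
        cs,
        ratios=config.ratios,
        split_seed=config.seed,
        reducer_penalty=config.reducer_penalty,
        use_segmentation=config.use_segmentation,
    )
    graphs_dir = out_dir / "graphs"
    graphs_dir.mkdir(exist_ok=True)
    for g in cohort.graphs:
        save_graph(g, graphs_dir / f"{g.patient_id}.json")
    cohort.table.to_csv(out_dir / "cohort.csv", index=False)

    mc = ModelConfig(
        n_blocks=config.n_blocks,
        hidden_dim=config.hidden_dim,
        dropout_p=config.dropout_p,
        input_dim=NODE_DIM,
    )
    tc = TrainConfig(epochs=config.epochs, batch_size=config.batch_size, seed=config.seed)
    trained = train(
        cohort.subset(cohort.split.train), cohort.subset(cohort.split.val), mc, tc
    )
    trained.save(out_dir / "model")
    pd.DataFrame(trained.history).to_csv(out_dir / "training_history.csv", index=False)

    test_graphs = cohort.subset(cohort.split.test)
    scores = trained.predict(test_graphs)
    tbl = cohort.table.set_index("id")
    ids = [g.patient_id for g in test_graphs]
    labels = np.array([g.label for g in test_graphs], dtype=int)
    times = tbl.loc[ids, "os_months"].to_numpy()
    events = tbl.loc[ids, "os_event"].to_numpy().astype(int)
    report = {
        "config_hash": chash,
        "config": dataclasses.asdict(config),
        "n_patients": config.n_patients,
        "split_sizes": list(cohort.split.sizes),
        "reducer": cohort.reducer_meta,
        "best_epoch": trained.best_epoch,
        "best_val_auc": trained.best_val_auc,
        "test": evaluate_predictions(
            scores, labels, times, events, threshold=config.threshold, seed=config.seed
        ),
    }
    (out_dir / "metrics.json").write_text(json.dumps(report, indent=2))
    km = report["test"].get("kaplan_meier")
    if km:
        rows = [
            {"group": gname, "time": t, "survival": s, "at_risk": r}
            for gname, curve in km.items()
            for t, s, r in zip(curve["times"], curve["survival"], curve["at_risk"])
        ]
        pd.DataFrame(rows).to_csv(out_dir / "km_curves.csv", index=False)
    logger.info("pipeline done: test AUC=%.3f", report["test"]["classification"]["auc"])
    return report
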