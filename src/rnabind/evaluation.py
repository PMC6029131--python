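"""Scoring and end-to-end experiment orchestration."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from . import io as rio
from .encoding import SEQ_ALPHABET, STRUCT_ALPHABET
from .io import LabeledDataset
from .model import BindingSiteModel, BindingSiteResults
from .motifs import enrichment_report, enrichment_to_tsv, write_meme
from .nn.network import ModelConfig
from .synthetic import SimConfig, generate

logger = logging.getLogger("rnabind")


@dataclass
class MetricsReport:
    """Threshold-free classification metrics."""

    auc: float
    n_pos: int
    n_neg: int
    split: str = "test"


def auc(labels, scores) -> float:
    """Area under the ROC curve: the probability that a random positive
    outscores a random negative, ties counted one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores differ in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


@dataclass
class RunConfig:
    """Everything one end-to-end run needs."""

    sim: SimConfig = field(default_factory=SimConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    out_dir: str | None = None
    motif_width: int = 7
    motif_pseudocount: float = 0.1
    score_fraction: float = 0.75
    enrichment: bool = True
    write_dataset: bool = False


@dataclass
class ExperimentResult:
    metrics: MetricsReport
    results: BindingSiteResults
    seq_pwms: list
    struct_pwms: list
    seq_enrichment: list
    struct_enrichment: list
    artifacts: dict


def structure_background_for(positives: LabeledDataset, seed: int) -> list[str]:
    """Background structure strings for structure-motif enrichment: shuffle
    the positive sequences, re-fold, re-annotate.  A plain letter shuffle of
    a structure string would destroy its run-length statistics and fake
    enrichment; re-predicting from shuffled sequences preserves them."""
    from .motifs import shuffle_background
    from .structure import annotate_loops, fold_baseline, parse_dotbracket

    shuffled = shuffle_background(positives.sequences, seed)
    return [annotate_loops(parse_dotbracket(fold_baseline(s)), len(s)) for s in shuffled]


def run_experiment(cfg: RunConfig, dataset: LabeledDataset | None = None) -> ExperimentResult:
    """Simulate (or accept) a dataset, train, score the test split, extract
    motifs from both branches, and test their enrichment.

    Writes artifacts (checkpoint, history, predictions, metrics, MEME motif
    files, enrichment TSVs, manifest) into ``cfg.out_dir`` when set.
    """
    t0 = time.time()
    timing: dict[str, float] = {}
    if dataset is None:
        dataset = generate(cfg.sim)
        timing["simulate"] = time.time() - t0
        logger.info("simulated %d records in %.1fs", len(dataset), timing["simulate"])

    t = time.time()
    model = BindingSiteModel(dataset, cfg.model)
    results = model.fit()
    timing["train"] = time.time() - t
    logger.info("trained %d epochs in %.1fs", len(results.history), timing["train"])

    t = time.time()
    test, probs = results.predict_split("test")
    metrics = MetricsReport(auc(test.labels, probs), int(test.labels.sum()),
                            int((1 - test.labels).sum()))
    timing["predict"] = time.time() - t
    logger.info("test AUC %.4f", metrics.auc)

    t = time.time()
    train_split = dataset.split("train")
    seq_pwms = results.motif_pwms("sequence", train_split, cfg.motif_width, cfg.motif_pseudocount)
    struct_pwms = (
        results.motif_pwms("structure", train_split, cfg.motif_width, cfg.motif_pseudocount)
        if cfg.model.use_structure
        else []
    )
    seq_enr: list = []
    struct_enr: list = []
    if cfg.enrichment:
        pos = train_split.positives()
        seq_enr = enrichment_report(
            seq_pwms, pos.sequences, cfg.model.n_filters_seq,
            seed=cfg.sim.seed, score_fraction=cfg.score_fraction,
        )
        if struct_pwms:
            bg = structure_background_for(pos, cfg.sim.seed)
            struct_enr = enrichment_report(
                struct_pwms, pos.structures, cfg.model.n_filters_struct,
                seed=cfg.sim.seed, score_fraction=cfg.score_fraction, background=bg,
            )
    timing["motifs"] = time.time() - t

    artifacts: dict = {}
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if cfg.write_dataset:
            artifacts.update({k: str(v) for k, v in rio.write_dataset(dataset, out).items()})
        results.save(out / "model.json")
        (out / "history.jsonl").write_text(
            "\n".join(json.dumps(h) for h in results.history) + "\n"
        )
        rio.write_predictions(out / "predictions.tsv", test.ids, probs)
        (out / "metrics.json").write_text(json.dumps(asdict(metrics), indent=2))
        write_meme(seq_pwms, SEQ_ALPHABET, out / "motifs_sequence.meme")
        if struct_pwms:
            write_meme(struct_pwms, STRUCT_ALPHABET, out / "motifs_structure.meme")
        if seq_enr:
            enrichment_to_tsv(seq_enr, out / "enrichment_sequence.tsv")
        if struct_enr:
            enrichment_to_tsv(struct_enr, out / "enrichment_structure.tsv")
        manifest = {
            "seed": cfg.sim.seed,
            "model_seed": cfg.model.seed,
            "sim_config": asdict(cfg.sim),
            "model_config": cfg.model.to_dict(),
            "timing_s": {k: round(v, 2) for k, v in timing.items()},
            "versions": _versions(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        artifacts.update(
            {
                "model": str(out / "model.json"),
                "metrics": str(out / "metrics.json"),
                "predictions": str(out / "predictions.tsv"),
                "manifest": str(out / "manifest.json"),
            }
        )
    return ExperimentResult(metrics, results, seq_pwms, struct_pwms, seq_enr, struct_enr, artifacts)


def _versions() -> dict[str, str]:
    import numpy
    import scipy
    import sklearn

    from . import __version__

    return {
        "rnabind": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }
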