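"""Model / Results objects tying the pipeline together.

``BindingSiteModel`` holds a labeled dataset and a :class:`ModelConfig`;
``fit()`` trains the two-branch CNN->BLSTM classifier and returns a
``BindingSiteResults`` carrying the trained parameters, the training
history, prediction and evaluation methods, and motif extraction for both
branches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as rio
from .encoding import encode_sequence, encode_structure, normalize_sequence, standardize_length
from .io import LabeledDataset
from .nn.network import (
    ModelConfig,
    NetworkState,
    build_network,
    predict_proba,
    train_network,
)


def _encode_inputs(
    sequences: list[str],
    structures: list[str] | None,
    cfg: ModelConfig,
) -> tuple[np.ndarray, np.ndarray | None]:
    Xs = np.empty((len(sequences), cfg.input_length + 2 * (cfg.filter_len_seq - 1), 4))
    Xt = (
        np.empty((len(sequences), cfg.input_length + 2 * (cfg.filter_len_struct - 1), 6))
        if cfg.use_structure
        else None
    )
    if cfg.use_structure and structures is None:
        raise ValueError("config uses the structure branch but no structures were given")
    for i, s in enumerate(sequences):
        t = structures[i] if (structures is not None and cfg.use_structure) else None
        s, t = standardize_length(normalize_sequence(s), t, cfg.input_length, cfg.struct_filler)
        Xs[i] = encode_sequence(s, cfg.filter_len_seq)
        if Xt is not None:
            Xt[i] = encode_structure(t, cfg.filter_len_struct)
    return Xs, Xt


class BindingSiteModel:
    """Binding-site classifier over a labeled sequence(+structure) dataset."""

    def __init__(self, dataset: LabeledDataset, config: ModelConfig | None = None) -> None:
        self.dataset = dataset
        self.config = config or ModelConfig()
        if self.config.use_structure and dataset.structures is None:
            raise ValueError(
                "dataset has no structure strings; annotate it first or set use_structure=False"
            )

    @classmethod
    def from_files(
        cls,
        fasta: str | Path,
        labels_tsv: str | Path,
        struct_fasta: str | Path | None = None,
        config: ModelConfig | None = None,
    ) -> "BindingSiteModel":
        return cls(rio.load_dataset(fasta, labels_tsv, struct_fasta), config)

    def fit(self) -> "BindingSiteResults":
        cfg = self.config
        tr = self.dataset.split("train")
        va = self.dataset.split("validation")
        if len(tr) == 0 or len(va) == 0:
            raise ValueError("train and validation splits must be non-empty")
        Xs_tr, Xt_tr = _encode_inputs(tr.sequences, tr.structures, cfg)
        Xs_va, Xt_va = _encode_inputs(va.sequences, va.structures, cfg)
        state = build_network(cfg)
        state, history = train_network(
            state, Xs_tr, Xt_tr, tr.labels, Xs_va, Xt_va, va.labels, cfg
        )
        return BindingSiteResults(self, state, history)


class BindingSiteResults:
    """Fitted classifier: parameters, history, prediction, motifs."""

    def __init__(
        self,
        model: BindingSiteModel | None,
        state: NetworkState,
        history: list[dict],
    ) -> None:
        self.model = model
        self.state = state
        self.history = history

    @property
    def config(self) -> ModelConfig:
        return self.state.config

    # --- prediction --------------------------------------------------------

    def predict(self, sequences: list[str], structures: list[str] | None = None) -> np.ndarray:
        """Binding probabilities for new inputs (deterministic inference)."""
        Xs, Xt = _encode_inputs(sequences, structures, self.config)
        return predict_proba(self.state, Xs, Xt)

    def predict_split(self, split: str = "test") -> tuple[LabeledDataset, np.ndarray]:
        if self.model is None:
            raise ValueError("results were loaded without a dataset")
        ds = self.model.dataset.split(split)
        return ds, self.predict(ds.sequences, ds.structures)

    def evaluate(self, split: str = "test"):
        from .evaluation import MetricsReport, auc

        ds, probs = self.predict_split(split)
        return MetricsReport(
            auc=auc(ds.labels, probs),
            n_pos=int(ds.labels.sum()),
            n_neg=int((1 - ds.labels).sum()),
            split=split,
        )

    # --- motifs -------------------------------------------------------------

    def motif_hits(self, branch: str = "sequence", dataset: LabeledDataset | None = None):
        from .motifs import collect_hits

        if dataset is None:
            if self.model is None:
                raise ValueError("results were loaded without a dataset")
            dataset = self.model.dataset.split("train")
        return collect_hits(self, dataset, branch)

    def motif_pwms(
        self,
        branch: str = "sequence",
        dataset: LabeledDataset | None = None,
        width: int = 7,
        pseudocount: float = 0.1,
    ):
        from .encoding import SEQ_ALPHABET, STRUCT_ALPHABET
        from .motifs import pwms_from_hits

        cfg = self.config
        hits = self.motif_hits(branch, dataset)
        alphabet = SEQ_ALPHABET if branch == "sequence" else STRUCT_ALPHABET
        n_filters = cfg.n_filters_seq if branch == "sequence" else cfg.n_filters_struct
        prefix = "seq_filter" if branch == "sequence" else "struct_filter"
        return pwms_from_hits(hits, alphabet, n_filters, width, pseudocount, prefix)

    # --- reporting ----------------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Binding-site classifier (CNN + BLSTM)",
            "=" * 44,
            f"branches:         sequence{' + structure' if cfg.use_structure else ' only'}",
            f"filters/length:   {cfg.n_filters_seq} x {cfg.filter_len_seq}"
            + (f" | {cfg.n_filters_struct} x {cfg.filter_len_struct}" if cfg.use_structure else ""),
            f"recurrent:        {'BLSTM ' + str(cfg.lstm_hidden) + '/direction' if cfg.use_blstm else 'none (flatten)'}",
            f"input length:     {cfg.input_length}",
            f"epochs run:       {len(self.history)} (max {cfg.max_epochs})",
        ]
        if self.history:
            best = min(self.history, key=lambda h: h["val_loss"])
            lines.append(f"best val loss:    {best['val_loss']:.4f} (epoch {best['epoch']})")
            lines.append(f"final train loss: {self.history[-1]['train_loss']:.4f}")
        if self.model is not None and any(s == "test" for s in self.model.dataset.splits):
            rep = self.evaluate("test")
            lines.append(f"test AUC:         {rep.auc:.4f} ({rep.n_pos} pos / {rep.n_neg} neg)")
        return "\n".join(lines)

    # --- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        rio.save_checkpoint(
            path,
            self.state.params,
            self.state.bn_state,
            self.config.to_dict(),
            extra={"history": self.history},
        )

    @classmethod
    def load(cls, path: str | Path, dataset: LabeledDataset | None = None) -> "BindingSiteResults":
        blob = rio.load_checkpoint(path)
        cfg = ModelConfig.from_dict(blob["config"])
        state = NetworkState(blob["params"], blob["bn_state"], cfg)
        model = BindingSiteModel(dataset, cfg) if dataset is not None else None
        return cls(model, state, blob.get("history", []))
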