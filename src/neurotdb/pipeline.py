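"""End-to-end orchestration: simulate → blocks → features → label →
sequences → train → evaluate, as one seeded, reproducible run."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import yaml

from . import __version__
from .blocks import BlockConfig
from .labeling import LabelerSpec, train_auto_labeler
from .metrics import similarity_features
from .sequences import build_sequences, same_label_fraction
from .ssm import TrainConfig, evaluate
from .synth import SynthConfig, generate_labeled_corpus, manifest_hash

__all__ = ["RunConfig", "run_end_to_end", "EmptyCorpusError"]

log = logging.getLogger("neurotdb.pipeline")


class EmptyCorpusError(RuntimeError):
    """No blocks survived construction/filtering."""


@dataclass
class RunConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    blocks: BlockConfig = field(default_factory=BlockConfig)
    labeler: LabelerSpec = field(default_factory=LabelerSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    sequence_lengths: Tuple[int, ...] = (1, 3)
    test_fraction: float = 0.3
    manual_fraction: float = 0.5  # share of blocks playing the manually-labeled role
    runs: int = 1
    seed: int = 0
    out_dir: str = "run_output"

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        kwargs = dict(d)
        for key, sub in (
            ("synth", SynthConfig),
            ("blocks", BlockConfig),
            ("labeler", LabelerSpec),
            ("train", TrainConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in kwargs[key].items()
                })
        if "sequence_lengths" in kwargs:
            kwargs["sequence_lengths"] = tuple(kwargs["sequence_lengths"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _split_neurons(
    neuron_ids: List[str], test_fraction: float, seed: int
) -> Tuple[set, set]:
    rng = np.random.default_rng(seed)
    ids = sorted(set(neuron_ids))
    perm = rng.permutation(len(ids))
    n_test = max(1, int(round(test_fraction * len(ids))))
    test = {ids[i] for i in perm[:n_test]}
    return set(ids) - test, test


def run_end_to_end(cfg: RunConfig) -> Dict:
    """Execute all stages; returns (and writes) the run report."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: Dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    }

    stage = "simulate"
    try:
        synth_cfg = dataclasses.replace(cfg.synth, seed=cfg.seed)
        blocks, manifest = generate_labeled_corpus(synth_cfg, cfg.blocks)
        if not blocks:
            raise EmptyCorpusError("empty corpus: no blocks survived filtering")
        report["n_blocks"] = len(blocks)
        report["manifest_hash"] = manifest_hash(manifest)
        report["label_distribution"] = {
            lab: int(sum(b.label == lab for b in blocks)) for lab in ("low", "high")
        }
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        log.info("simulate: %d blocks", len(blocks))

        stage = "features"
        feats = [similarity_features(b.gold, b.auto) for b in blocks]

        stage = "label"
        rng = np.random.default_rng(cfg.seed + 1)
        n_manual = max(2, int(round(cfg.manual_fraction * len(blocks))))
        manual_idx = rng.permutation(len(blocks))[:n_manual]
        labeler_spec = dataclasses.replace(cfg.labeler, seed=cfg.seed)
        labeler, labeler_report = train_auto_labeler(
            [feats[i] for i in manual_idx],
            [blocks[i].label for i in manual_idx],
            labeler_spec,
        )
        rest_idx = [i for i in range(len(blocks)) if i not in set(manual_idx)]
        if rest_idx:
            pred = labeler.predict([feats[i] for i in rest_idx])
            agree = float(
                np.mean([pred[k].value == blocks[i].label for k, i in enumerate(rest_idx)])
            )
        else:
            agree = float("nan")
        report["labeler"] = {**labeler_report, "agreement_with_construction": agree}
        labeler.save(out_dir / "labeler.json")

        stage = "sequences"
        pairs = build_sequences(blocks, 2)
        report["n_pairs"] = len(pairs)
        report["same_label_fraction"] = same_label_fraction(pairs) if pairs else None

        stage = "train"
        train_ids, test_ids = _split_neurons(
            [b.neuron_id for b in blocks], cfg.test_fraction, cfg.seed + 2
        )
        train_blocks = [b for b in blocks if b.neuron_id in train_ids]
        test_blocks = [b for b in blocks if b.neuron_id in test_ids]
        report["split"] = {
            "train_neurons": sorted(train_ids),
            "test_neurons": sorted(test_ids),
            "n_train_blocks": len(train_blocks),
            "n_test_blocks": len(test_blocks),
        }
        results = {}
        for s in cfg.sequence_lengths:
            train_cfg = dataclasses.replace(cfg.train, sequence_length=s, seed=cfg.seed)
            results[f"s={s}"] = evaluate(
                train_blocks, test_blocks, train_cfg, runs=cfg.runs
            )
            log.info("evaluated s=%d", s)
        report["model"] = results
    except EmptyCorpusError:
        raise
    except Exception as exc:  # pragma: no cover - stage context for operators
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (out_dir / "config.yaml").write_text(cfg.to_yaml())
    return report
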