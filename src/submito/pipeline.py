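"""End-to-end orchestration of the toolkit stages with manifests and seeds.

Stage order: simulate -> encode -> train -> evaluate -> predict -> screen
-> annotate.  Every stage writes its artifacts under the configured work
directory plus a manifest (sha256 of inputs, config hash, stage seed), so
a rerun with an identical configuration is byte-identical for the
deterministic stages and any stage can be re-run in isolation.

One global seed fans out to per-stage seeds by fixed offsets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import annotation_transfer as at
from . import cnn_model, encoding, evaluation, io_formats, mito_ensemble
from . import synthetic_data as synth

logger = logging.getLogger(__name__)

STAGES = ("simulate", "encode", "train", "evaluate", "predict", "screen", "annotate")

#: fixed per-stage seed offsets from the global seed
STAGE_SEED_OFFSET = {name: 1000 * (i + 1) for i, name in enumerate(STAGES)}


@dataclass
class RunConfig:
    workdir: str = "submito_run"
    model: cnn_model.ModelConfig = field(default_factory=cnn_model.ModelConfig)
    train: cnn_model.TrainConfig = field(default_factory=cnn_model.TrainConfig)
    n_per_class: int = 60
    length_range: tuple[int, int] = (60, 120)
    substitution_rate: float = 0.1
    pssm_noise: float = 1.0
    cv_folds: int = 5
    go_clusters: int = 3
    go_cluster_size: int = 8
    go_background: int = 200
    identity_threshold: float = at.IDENTITY_THRESHOLD
    coverage_threshold: float = at.COVERAGE_THRESHOLD
    alpha: float = at.ALPHA
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.identity_threshold <= 100:
            raise ValueError("identity threshold must be a percentage in [0, 100]")
        if not 0 <= self.coverage_threshold <= 100:
            raise ValueError("coverage threshold must be a percentage in [0, 100]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def stage_seed(self, stage: str) -> int:
        return self.seed + STAGE_SEED_OFFSET[stage]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["model"] = cnn_model.ModelConfig(**d.get("model", {}))
        d["train"] = cnn_model.TrainConfig(**d.get("train", {}))
        if "length_range" in d:
            d["length_range"] = tuple(d["length_range"])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    def __init__(self, config: RunConfig):
        self.config = config
        self.workdir = Path(config.workdir)

    # -- paths --------------------------------------------------------------

    def path(self, name: str) -> Path:
        return self.workdir / name

    def _require(self, name: str, producer: str) -> Path:
        p = self.path(name)
        if not p.exists():
            raise FileNotFoundError(
                f"missing artifact {p}; run the {producer!r} stage first"
            )
        return p

    def _manifest(self, stage: str, inputs: list[Path], outputs: list[Path]) -> None:
        mdir = self.workdir / "manifests"
        mdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "stage": stage,
            "seed": self.config.stage_seed(stage),
            "config_sha256": hashlib.sha256(
                self.config.to_json().encode()
            ).hexdigest(),
            "inputs": {str(p): _sha256(p) for p in inputs},
            "outputs": {str(p): _sha256(p) for p in outputs},
        }
        with open(mdir / f"{stage}.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    # -- stages --------------------------------------------------------------

    def simulate(self) -> None:
        cfg = self.config
        seed = cfg.stage_seed("simulate")
        self.workdir.mkdir(parents=True, exist_ok=True)
        spec = synth.SyntheticSpec(
            n_per_class=cfg.n_per_class,
            length_range=cfg.length_range,
            substitution_rate=cfg.substitution_rate,
            pssm_noise=cfg.pssm_noise,
            seed=seed,
        )
        labelled = synth.generate_proteome(spec)
        records = [rec for rec, _ in labelled]
        io_formats.write_fasta(self.path("proteome.fasta"), records)
        io_formats.write_labels(
            self.path("labels.tsv"), {rec.id: lab.name for rec, lab in labelled}
        )
        pssm_dir = self.path("pssms")
        pssm_dir.mkdir(exist_ok=True)
        profiles = synth.generate_profiles(records, noise=cfg.pssm_noise, seed=seed + 1)
        for rec in records:
            io_formats.write_pssm(pssm_dir / f"{rec.id}.pssm", rec, profiles[rec.id])
        votes = synth.generate_votes(records, seed=seed + 2)
        io_formats.write_votes(self.path("votes.tsv"), votes)
        go_records, go_annotations, go_truth = synth.generate_go_world(
            n_clusters=cfg.go_clusters,
            cluster_size=cfg.go_cluster_size,
            background_size=cfg.go_background,
            seed=seed + 3,
        )
        io_formats.write_fasta(self.path("go_sequences.fasta"), go_records)
        io_formats.write_go_table(self.path("go_annotations.tsv"), go_annotations)
        with open(self.path("go_truth.tsv"), "w") as fh:
            fh.write("go_term\tfamily\n")
            for term, fam in go_truth.items():
                fh.write(f"{term}\t{fam}\n")
        outputs = [
            self.path("proteome.fasta"),
            self.path("labels.tsv"),
            self.path("votes.tsv"),
            self.path("go_sequences.fasta"),
            self.path("go_annotations.tsv"),
            self.path("go_truth.tsv"),
        ]
        self._manifest("simulate", [], outputs)
        logger.info("simulate: %d labelled proteins", len(labelled))

    def _load_encoded_labelled(self):
        encoded = encoding.load_encoded(self._require("encoded.npz", "encode"))
        labels = io_formats.read_labels(self._require("labels.tsv", "simulate"))
        return [
            (e, cnn_model.CompartmentLabel[labels[e.protein_id]]) for e in encoded
        ]

    def encode(self) -> None:
        fasta = self._require("proteome.fasta", "simulate")
        pssm_dir = self._require("pssms", "simulate")
        records = io_formats.read_fasta(fasta)
        encoded = []
        for rec in records:
            profile = io_formats.read_pssm(pssm_dir / f"{rec.id}.pssm", rec)
            encoded.append(encoding.encode_protein(rec, profile))
        out = self.path("encoded.npz")
        encoding.save_encoded(out, encoded)
        self._manifest("encode", [fasta], [out])
        logger.info("encode: %d proteins -> %s", len(encoded), out)

    def train(self) -> None:
        data = self._load_encoded_labelled()
        cfg = self.config
        model_cfg = dataclasses.replace(cfg.model, seed=cfg.stage_seed("train"))
        train_cfg = dataclasses.replace(cfg.train, seed=cfg.stage_seed("train") + 1)
        model = cnn_model.build_model(model_cfg)
        model, history = cnn_model.train(model, data, train_cfg)
        out = self.path("model.npz")
        cnn_model.save_checkpoint(out, model)
        with open(self.path("loss_history.tsv"), "w") as fh:
            fh.write("epoch\tloss\n")
            for i, loss in enumerate(history, 1):
                fh.write(f"{i}\t{loss:.6f}\n")
        self._manifest(
            "train",
            [self.path("encoded.npz"), self.path("labels.tsv")],
            [out, self.path("loss_history.tsv")],
        )
        logger.info("train: final loss %.4f after %d epochs", history[-1], len(history))

    def evaluate(self) -> None:
        data = self._load_encoded_labelled()
        cfg = self.config
        model_cfg = dataclasses.replace(cfg.model, seed=cfg.stage_seed("evaluate"))
        train_cfg = dataclasses.replace(cfg.train, seed=cfg.stage_seed("evaluate") + 1)
        folds, pooled = evaluation.cross_validate(
            data,
            cfg.cv_folds,
            seed=cfg.stage_seed("evaluate"),
            model_config=model_cfg,
            train_config=train_cfg,
        )
        out = self.path("cv_report.tsv")
        with open(out, "w") as fh:
            fh.write("compartment\tmcc\n")
            for label, mcc in pooled.items():
                fh.write(f"{label.name}\t{mcc:.4f}\n")
        self._manifest(
            "evaluate", [self.path("encoded.npz"), self.path("labels.tsv")], [out]
        )
        logger.info("evaluate: pooled MCC %s", {k.name: round(v, 3) for k, v in pooled.items()})

    def predict(self) -> None:
        model = cnn_model.load_checkpoint(self._require("model.npz", "train"))
        encoded = encoding.load_encoded(self._require("encoded.npz", "encode"))
        results = cnn_model.predict_many(model, encoded)
        out = self.path("predictions.tsv")
        io_formats.write_predictions(out, results)
        self._manifest(
            "predict", [self.path("model.npz"), self.path("encoded.npz")], [out]
        )
        logger.info("predict: %d proteins -> %s", len(results), out)

    def screen(self) -> None:
        votes_path = self._require("votes.tsv", "simulate")
        table = io_formats.read_votes(votes_path)
        decisions, rejects = mito_ensemble.screen_proteome(table)
        d_out, r_out = self.path("decisions.tsv"), self.path("rejects.tsv")
        mito_ensemble.write_decisions(d_out, decisions)
        mito_ensemble.write_rejects(r_out, rejects)
        self._manifest("screen", [votes_path], [d_out, r_out])
        logger.info(
            "screen: %d mitochondrial of %d decided, %d rejected",
            sum(d.is_mitochondrial for d in decisions),
            len(decisions),
            len(rejects),
        )

    def annotate(self) -> None:
        cfg = self.config
        fasta = self._require("go_sequences.fasta", "simulate")
        go_path = self._require("go_annotations.tsv", "simulate")
        records = io_formats.read_fasta(fasta)
        annotations = io_formats.read_go_table(go_path)
        clusters = at.build_clusters(
            records, cfg.identity_threshold, cfg.coverage_threshold
        )
        transferred: list[io_formats.GOAnnotation] = []
        enrichment_rows = []
        for cluster in clusters:
            if cluster.singleton:
                continue
            enriched = at.enrich_cluster(cluster, annotations, annotations, cfg.alpha)
            enrichment_rows.extend(enriched)
            transferred.extend(at.transfer_annotations(cluster, enriched, annotations))
        merged = at.merge_annotations(annotations, transferred)
        c_out = self.path("clusters.tsv")
        with open(c_out, "w") as fh:
            fh.write("cluster\tprotein_id\tsingleton\n")
            for i, cl in enumerate(clusters):
                for pid in sorted(cl.members):
                    fh.write(f"{i}\t{pid}\t{str(cl.singleton).lower()}\n")
        e_out = self.path("enrichment.tsv")
        with open(e_out, "w") as fh:
            fh.write("go_term\taspect\tk\tn\tK\tN\tp_value\tn_terms_tested\tsignificant\n")
            for r in enrichment_rows:
                fh.write(
                    f"{r.term}\t{r.aspect}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                    f"{r.p_value:.6g}\t{r.n_terms_tested}\t{str(r.significant).lower()}\n"
                )
        t_out = self.path("transferred.tsv")
        io_formats.write_go_table(t_out, transferred)
        m_out = self.path("merged.tsv")
        io_formats.write_go_table(m_out, merged)
        self._manifest("annotate", [fasta, go_path], [c_out, e_out, t_out, m_out])
        logger.info(
            "annotate: %d clusters, %d transferred annotations",
            sum(1 for c in clusters if not c.singleton),
            len(transferred),
        )

    def run(self, stages: tuple[str, ...] = STAGES) -> None:
        for stage in stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
        for stage in STAGES:
            if stage in stages:
                getattr(self, stage)()


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> None:
    """Run the requested stages in canonical order."""
    Pipeline(config).run(stages)
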