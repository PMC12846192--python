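"""End-to-end experiment orchestration.

Ties the stages together: simulate a dataset, interpolate sensor frames
into field vectors, train the magnetic depth-correction encoder, train
the fusion regressor, and evaluate on the held-out test split in mm.
Every random draw descends from a single master seed through a counter
scheme, so a run directory (config + manifests + checkpoints + reports)
fully determines its outputs.

Two problem-size profiles are provided: ``desk`` (the default: 300
samples, 64 points per wire, 64 x 64 field grid, 60 epochs per stage --
sized so a full run takes minutes on one CPU core) and ``paper_faithful``
(128 points, 256 x 256 grid -> 65536-long field vectors, 200 epochs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .fusion import FusionConfig, TrainedFusion, standardize_depth, train_fusion
from .geometry import CenterlineCloud, denormalize_cloud, normalize_cloud, resample_centerline
from .mag_encoder import EncoderConfig, TrainedMagEncoder, mag_depth_batch, train_mag_encoder
from .metrics import MetricsReport, evaluate_pairs
from .phantom import Dataset, SimulatorConfig, generate_dataset, save_dataset
from .preprocess import interpolate_field

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "run_ablation",
    "reconstruct",
    "reconstruct_from_image",
    "prepare_modalities",
]


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class ExperimentConfig:
    n_samples: int = 300
    n_points: int = 64
    field_grid: tuple = (64, 64)
    seed: int = 0
    simulator: SimulatorConfig = None
    encoder_hidden: tuple = (256,)
    decoder_hidden: tuple = (256,)
    encoder_epochs: int = 60
    encoder_lr: float = 1e-3
    encoder_weight_decay: float = 1e-4
    fusion_epochs: int = 60
    fusion_lr: float = 1e-3
    batch_size: int = 4
    embed_dim: int = 64
    fused_dim: int = 128
    k: int = 4
    use_knn: bool = True
    use_attention: bool = True
    use_magnetic: bool = True
    output_dir: str = None

    @classmethod
    def paper_faithful(cls, **overrides) -> "ExperimentConfig":
        base = dict(
            n_points=128,
            field_grid=(256, 256),
            encoder_hidden=(1024, 512),
            decoder_hidden=(512, 1024),
            encoder_epochs=200,
            encoder_lr=1e-4,
            fusion_epochs=200,
        )
        base.update(overrides)
        return cls(**base)

    def simulator_config(self) -> SimulatorConfig:
        sim = self.simulator or SimulatorConfig()
        return replace(sim, n_points=self.n_points)

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(
            input_length=int(np.prod(self.field_grid)),
            n_points=self.n_points,
            encoder_hidden=self.encoder_hidden,
            decoder_hidden=self.decoder_hidden,
            learning_rate=self.encoder_lr,
            weight_decay=self.encoder_weight_decay,
            epochs=self.encoder_epochs,
            batch_size=self.batch_size,
            seed=_stage_seed(self.seed, 2),
        )

    def fusion_config(self) -> FusionConfig:
        return FusionConfig(
            n_points=self.n_points,
            embed_dim=self.embed_dim,
            fused_dim=self.fused_dim,
            k=self.k,
            learning_rate=self.fusion_lr,
            epochs=self.fusion_epochs,
            batch_size=self.batch_size,
            seed=_stage_seed(self.seed, 3),
            use_knn=self.use_knn,
            use_attention=self.use_attention,
            use_magnetic=self.use_magnetic,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class _Logger:
    def __init__(self, path=None, seed=None, cfg_hash=None):
        self.path = Path(path) if path else None
        self.seed = seed
        self.cfg_hash = cfg_hash

    def __call__(self, event: str, **fields):
        rec = {"t": round(time.time(), 3), "event": event, "seed": self.seed, "config": self.cfg_hash}
        rec.update(fields)
        if self.path:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(rec, default=str) + "\n")


def _stage(name: str):
    """Decorator: re-raise stage failures tagged with the stage name."""

    def wrap(fn):
        def inner(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

        inner.__name__ = fn.__name__
        return inner

    return wrap


def prepare_modalities(dataset: Dataset, field_grid: tuple):
    """Per-sample field vectors, normalized clouds and transform records."""
    fields, norm_clouds, records = [], [], []
    for smp in dataset.samples:
        fields.append(interpolate_field(smp.frame, field_grid).values)
        nc, rec = normalize_cloud(smp.cloud)
        norm_clouds.append(nc)
        records.append(rec)
    return np.vstack(fields), norm_clouds, records


@_stage("reconstruct")
def reconstruct(sample, trained_enc: TrainedMagEncoder, trained_fusion: TrainedFusion, field_grid: tuple, record=None):
    """End-to-end prediction for one sample, in mm.

    Composition: field interpolation -> magnetic depth correction ->
    embedding / fusion / KNN / attention -> per-point regression ->
    denormalisation.  The similarity transform used to undo the
    normalisation defaults to the sample's own ground-truth record (the
    evaluation convention: the learned model predicts shape in
    normalized coordinates; the metric frame comes from the label).
    """
    fv = interpolate_field(sample.frame, field_grid).values
    z_mag = mag_depth_batch(fv.reshape(1, -1), trained_enc)[0]
    z_img = standardize_depth(sample.z_img)
    pred_norm = trained_fusion.model.predict(z_img, z_mag)
    if record is None:
        _, record = normalize_cloud(sample.cloud)
    return denormalize_cloud(CenterlineCloud(pred_norm), record)


def reconstruct_from_image(image, depth_map, frame, trained_enc, trained_fusion, field_grid, threshold=None):
    """Image-input front end: segment, extract the centerline, sample the
    depth map along it, then run the fusion pipeline.

    Returns the prediction in normalized coordinates (an external
    reference transform is needed to place it metrically).
    """
    from .preprocess import extract_ordered_centerline, threshold_segment

    n = trained_fusion.config.n_points
    mask = threshold_segment(image, threshold)
    chain = extract_ordered_centerline(mask)
    chain3 = np.column_stack([chain, np.zeros(len(chain))])
    pix = resample_centerline(CenterlineCloud(chain3), n).points[:, :2]
    rows = np.clip(np.round(pix[:, 1]).astype(int), 0, depth_map.shape[0] - 1)
    cols = np.clip(np.round(pix[:, 0]).astype(int), 0, depth_map.shape[1] - 1)
    z_img = depth_map.values[rows, cols]
    fv = interpolate_field(frame, field_grid).values
    z_mag = mag_depth_batch(fv.reshape(1, -1), trained_enc)[0]
    pred_norm = trained_fusion.model.predict(standardize_depth(z_img), z_mag)
    return CenterlineCloud(pred_norm)


def run_experiment(config: ExperimentConfig, dataset: Dataset = None, trained_enc: TrainedMagEncoder = None):
    """simulate -> preprocess -> train encoder -> train fusion -> evaluate.

    Returns a dict with the test-split :class:`MetricsReport` and all
    intermediate artifacts; if ``output_dir`` is set, manifests,
    checkpoints, training logs and reports are written beneath it.
    ``dataset`` / ``trained_enc`` may be supplied to share the simulation
    and encoder stages across ablation rows.
    """
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1, sort_keys=True, default=str))
    log = _Logger(out / "log.jsonl" if out else None, config.seed, config.config_hash())

    if dataset is None:
        dataset = _stage("simulate")(generate_dataset)(
            config.n_samples, config.simulator_config(), master_seed=_stage_seed(config.seed, 1)
        )
    log("simulated", n=len(dataset))
    if out:
        (out / "manifest.json").write_text(json.dumps(dataset.manifest, indent=1, sort_keys=True))

    fields, norm_clouds, records = _stage("preprocess")(prepare_modalities)(dataset, config.field_grid)
    log("preprocessed", field_length=fields.shape[1])

    splits = dataset.manifest["splits"]
    if trained_enc is None:
        enc_idx = splits["train"] + splits["val"]  # test stays unseen
        pairs = [(fields[i], norm_clouds[i]) for i in enc_idx]
        trained_enc = _stage("train_encoder")(train_mag_encoder)(pairs, config.encoder_config())
        log("encoder_trained", best_val_cd=min(h[2] for h in trained_enc.history))
        if out:
            trained_enc.save(out / "encoder.npz")
            np.savetxt(out / "encoder_history.csv", np.asarray(trained_enc.history),
                       delimiter=",", header="epoch,train_cd,val_cd", comments="")

    z_mag_all = mag_depth_batch(fields, trained_enc)

    def triples(idx):
        return [(dataset.samples[i].z_img, z_mag_all[i], norm_clouds[i]) for i in idx]

    trained_fusion = _stage("train_fusion")(train_fusion)(
        triples(splits["train"]), triples(splits["val"]), config.fusion_config()
    )
    log("fusion_trained", best_val_wmae=min(h[2] for h in trained_fusion.history))
    if out:
        trained_fusion.save(out / "fusion.npz")
        np.savetxt(out / "fusion_history.csv", np.asarray(trained_fusion.history),
                   delimiter=",", header="epoch,train_wmae,val_wmae", comments="")

    test_idx = splits["test"]
    zi = np.stack([standardize_depth(dataset.samples[i].z_img) for i in test_idx])
    zm = np.stack([z_mag_all[i] for i in test_idx])
    pred_norm = trained_fusion.model.predict(zi, zm)
    pairs_mm = [
        (denormalize_cloud(CenterlineCloud(pred_norm[j]), records[i]), dataset.samples[i].cloud)
        for j, i in enumerate(test_idx)
    ]
    report = _stage("evaluate")(evaluate_pairs)(
        pairs_mm, per_sample_csv=(out / "per_sample_metrics.csv") if out else None
    )
    log("evaluated", **dataclasses.asdict(report))
    if out:
        report.to_json(out / "metrics.json")
    return {
        "report": report,
        "dataset": dataset,
        "encoder": trained_enc,
        "fusion": trained_fusion,
        "fields": fields,
        "z_mag": z_mag_all,
        "records": records,
        "norm_clouds": norm_clouds,
    }


ABLATION_GRID = (
    {"use_knn": False, "use_attention": False},  # base encoder-decoder fusion
    {"use_knn": True, "use_attention": False},
    {"use_knn": False, "use_attention": True},
    {"use_knn": True, "use_attention": True},  # full model
)


def run_ablation(config: ExperimentConfig, grid=ABLATION_GRID):
    """Run the fusion stage once per ablation row on shared data.

    The simulated dataset, field vectors, trained encoder and split
    manifest are identical across rows, so rows differ only in the
    fusion switches.  Returns ``[(switches, MetricsReport), ...]``.
    """
    shared = None
    results = []
    for switches in grid:
        row_cfg = replace(
            config,
            output_dir=(str(Path(config.output_dir) / _row_name(switches)) if config.output_dir else None),
            **switches,
        )
        if shared is None:
            res = run_experiment(row_cfg)
            shared = (res["dataset"], res["encoder"])
        else:
            res = run_experiment(row_cfg, dataset=shared[0], trained_enc=shared[1])
        results.append((dict(switches), res["report"]))
    return results


def _row_name(switches: dict) -> str:
    tags = ["base"]
    if switches.get("use_knn"):
        tags.append("knn")
    if switches.get("use_attention"):
        tags.append("attn")
    return "_".join(tags)
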