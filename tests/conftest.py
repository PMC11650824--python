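"""Shared fixtures: synthetic datasets and trained models reused across tests."""

from __future__ import annotations

import datetime

import imageio.v3 as iio
import numpy as np
import pytest

from rhizopipe import io as rio, pipeline, segnet, synthetic


def make_patch_dataset(
    n: int, size: int, seed: int, target: str = "roots"
) -> list[segnet.PatchPair]:
    """Patch pairs from synthetic scenes.

    ``target='roots'`` uses the generator's ground-truth mask;
    ``target='threshold'`` replaces it with a brightness-threshold rule
    (mean RGB > 150), a deterministic pixel rule the network must learn.
    """
    rng = np.random.default_rng(seed)
    out: list[segnet.PatchPair] = []
    while len(out) < n:
        spec = synthetic.SceneSpec(
            canvas_shape=(size * 4, size * 4),
            n_roots=5,
            seed=int(rng.integers(2**31)),
        )
        img, mask, _ = synthetic.generate_scene(spec)
        if target == "threshold":
            mask = (img.mean(axis=2) > 150).astype(np.uint8)
        out += segnet.cut_patches(img, mask, size=size, overlap=0.0)
    return out[:n]


@pytest.fixture(scope="session")
def threshold_dataset() -> list[segnet.PatchPair]:
    """200 patches of 32 px whose mask is the brightness-threshold rule."""
    return make_patch_dataset(200, 32, seed=42, target="threshold")


@pytest.fixture(scope="session")
def trained_threshold_model(threshold_dataset):
    """Narrow network trained 60 epochs on the threshold-rule dataset."""
    cfg = segnet.TrainConfig(max_epochs=60, seed=0)
    model, history = segnet.train(threshold_dataset, cfg)
    return model, history, cfg


@pytest.fixture()
def constant_model():
    """Untrained-weights model forced to a constant output probability.

    All conv weights are zeroed and the output bias set directly, so the
    network emits one fixed probability everywhere — a handle for testing
    the tiling/averaging/thresholding plumbing in isolation.
    """

    def _make(prob: float) -> segnet.SegmentationModel:
        model = segnet.SegmentationModel(seed=0)
        for layer in model._conv_layers():
            layer.W[:] = 0.0
            layer.b[:] = 1.0  # keep ReLU blocks passing a constant through
        out = model._conv_layers()[-1]
        out.b[:] = np.log(prob / (1.0 - prob))
        model.trained = True
        return model

    return _make


@pytest.fixture(scope="session")
def pipeline_env(tmp_path_factory):
    """Scan series on disk + a briefly trained root-mask model + core table."""
    root = tmp_path_factory.mktemp("pipe")
    scans = root / "scans"
    scans.mkdir()
    spec = synthetic.SceneSpec(canvas_shape=(256, 384), n_roots=5, seed=11)
    tiles, _, _, _ = synthetic.generate_tube_series(spec, 4, 118)
    for t in tiles:
        iio.imwrite(scans / f"{t.tube_id}_{t.scan_date}_p{t.position_index}.png", t.pixels)
    dataset = make_patch_dataset(120, 32, seed=3, target="roots")
    model, _ = segnet.train(dataset, segnet.TrainConfig(max_epochs=40, seed=0))
    model.save(root / "model.npz")
    rio.write_core_table(
        [
            rio.CoreRecord("T01", lab, 0.5, datetime.date(2022, 5, 20))
            for lab in rio.DEPTH_BIN_LABELS
        ],
        root / "cores.csv",
    )
    return root


def make_pipeline_config(root, out_name, **overrides) -> pipeline.PipelineConfig:
    kwargs = dict(
        input_dir=str(root / "scans"),
        output_dir=str(root / out_name),
        model_checkpoint=str(root / "model.npz"),
        core_table=str(root / "cores.csv"),
        patch_size=128,
        soil_entry_col=0,
        seed=0,
    )
    kwargs.update(overrides)
    return pipeline.PipelineConfig(**kwargs)
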