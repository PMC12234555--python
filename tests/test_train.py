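"""Training loop, estimator facade, checkpointing and CLI plumbing."""

import numpy as np
import pytest
from click.testing import CliRunner

from tonguenet.cli import main as cli_main
from tonguenet.data import IDENTITY_AUGMENT, ImagePair, load_pair
from tonguenet.estimator import TongueSegmenter
from tonguenet.model import GATongueNet, _preset, load_checkpoint, save_checkpoint
from tonguenet.synthetic import generate_pairs
from tonguenet.train import TrainSettings, evaluate_model, train_model


def small_settings(**kw):
    base = dict(epochs=4, batch_size=4, lr=1e-3, input_size=(64, 64),
                augment=IDENTITY_AUGMENT, seed=0)
    base.update(kw)
    return TrainSettings(**base)


@pytest.fixture(scope="module")
def toy_pairs():
    return generate_pairs(10, "A", seed=3, canvas=(64, 64))


def test_overfit_small_set_halves_the_loss(toy_pairs):
    model = GATongueNet(_preset("tiny"))
    logs = train_model(model, toy_pairs, small_settings())
    assert logs[-1].loss < 0.5 * logs[0].loss


def test_identical_seeds_reproduce_epoch_losses(toy_pairs):
    runs = []
    for _ in range(2):
        model = GATongueNet(_preset("tiny"))
        logs = train_model(model, toy_pairs[:4], small_settings(epochs=1))
        runs.append(logs[0].loss)
    assert runs[0] == runs[1]


def test_training_rejects_empty_manifest():
    model = GATongueNet(_preset("tiny"))
    with pytest.raises(ValueError, match="empty"):
        train_model(model, [], small_settings())


def test_checkpoint_round_trip_is_bit_exact(tmp_path, toy_pairs):
    model = GATongueNet(_preset("tiny"))
    train_model(model, toy_pairs[:4], small_settings(epochs=1))
    before = model.predict_logits(toy_pairs[0].image)
    save_checkpoint(model, tmp_path / "ckpt.npz")
    restored = load_checkpoint(tmp_path / "ckpt.npz")
    after = restored.predict_logits(toy_pairs[0].image)
    assert np.array_equal(before, after)
    assert restored.config.to_dict() == model.config.to_dict()


def test_ground_truth_as_prediction_scores_one(toy_pairs):
    class Oracle:
        def eval(self):
            return self

        def predict_mask(self, image):
            return lookup[image.tobytes()]

    lookup = {p.image.tobytes(): p.mask for p in toy_pairs}
    records, summaries = evaluate_model(Oracle(), toy_pairs)
    for r in records:
        assert (r.dice, r.iou, r.precision, r.recall) == (1.0, 1.0, 1.0, 1.0)
    for s in summaries.values():
        assert (s.mean, s.ci_low, s.ci_high) == (1.0, 1.0, 1.0)


def test_constant_predictor_recall_is_all_or_nothing(toy_pairs):
    class Constant:
        def __init__(self, value):
            self.value = value

        def eval(self):
            return self

        def predict_mask(self, image):
            return np.full(image.shape[:2], self.value, np.uint8)

    ones, _ = evaluate_model(Constant(1), toy_pairs)
    zeros, _ = evaluate_model(Constant(0), toy_pairs)
    for r in ones:
        assert r.recall == 1.0
    # dice of the all-ones mask is determined by the foreground fraction
    for r, p in zip(ones, toy_pairs):
        frac = p.mask.mean()
        assert r.dice == pytest.approx(2 * frac / (1 + frac))
    for r in zeros:
        assert r.recall == 0.0


def test_estimator_follows_sklearn_conventions(toy_pairs):
    est = TongueSegmenter(epochs=1, batch_size=4, input_size=(64, 64),
                          augment=IDENTITY_AUGMENT, seed=1)
    params = est.get_params()
    assert params["epochs"] == 1
    est.set_params(epochs=2)
    assert est.epochs == 2
    from sklearn.exceptions import NotFittedError
    with pytest.raises(NotFittedError):
        est.predict([toy_pairs[0].image])
    est.set_params(epochs=1)
    est.fit([p.image for p in toy_pairs], [p.mask for p in toy_pairs])
    assert est.n_parameters_ > 0
    assert len(est.history_) == 1
    masks = est.predict([toy_pairs[0].image])
    assert masks[0].shape == toy_pairs[0].mask.shape
    proba = est.predict_proba([toy_pairs[0].image])[0]
    assert proba.shape == (64, 64, 2)
    assert np.allclose(proba.sum(axis=-1), 1.0, atol=1e-5)
    assert 0.0 <= est.score([p.image for p in toy_pairs],
                            [p.mask for p in toy_pairs]) <= 1.0


def test_cli_synth_train_eval_predict(tmp_path):
    runner = CliRunner()
    data_dir = tmp_path / "data"
    res = runner.invoke(cli_main, ["synth", "--n", "6", "--domain", "A",
                                   "--seed", "4", "--out", str(data_dir),
                                   "--size", "64"])
    assert res.exit_code == 0, res.output
    manifest = res.output.strip()

    cfg = tmp_path / "cfg.yaml"
    cfg.write_text("preset: tiny\nepochs: 1\nbatch_size: 4\n"
                   "input_size: [64, 64]\nlr: 0.001\n")
    ckpt = tmp_path / "model.npz"
    res = runner.invoke(cli_main, ["train", manifest, "--config", str(cfg),
                                   "--checkpoint", str(ckpt),
                                   "--log", str(tmp_path / "log.jsonl")])
    assert res.exit_code == 0, res.output
    assert ckpt.exists() and (tmp_path / "log.jsonl").exists()

    res = runner.invoke(cli_main, ["eval", str(ckpt), manifest,
                                   "--table", str(tmp_path / "scores.csv")])
    assert res.exit_code == 0, res.output
    assert "dice:" in res.output and (tmp_path / "scores.csv").exists()

    img_path = data_dir / "A0000.png"
    out_mask = tmp_path / "pred.png"
    res = runner.invoke(cli_main, ["predict", str(ckpt), str(img_path),
                                   str(out_mask)])
    assert res.exit_code == 0, res.output
    pred = load_pair(img_path, out_mask)
    assert pred.mask.shape == (64, 64)


def test_ablation_switches_produce_four_distinct_models():
    variants = {(d, m): TongueSegmenter(preset="tiny", use_difp=d, use_mdi=m)
                .build_model() for d in (False, True) for m in (False, True)}
    counts = {k: v.n_parameters() for k, v in variants.items()}
    assert len(set(counts.values())) == 4
    assert counts[(True, True)] == max(counts.values())
    assert counts[(False, False)] == min(counts.values())
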