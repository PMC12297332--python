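"""End-to-end study workflows composed from the library modules.

These are the desk-scale experiments the package uses to demonstrate the
pretraining objective and the evaluation protocol on synthetic data: small
enough to run on a single CPU in minutes, structured exactly like the
full-scale pipeline (pretrain -> embed -> patient-level split -> linear
probe -> paired bootstrap).
"""

from __future__ import annotations

import numpy as np

from .embed_store import EmbeddingMatrix, compute_embeddings
from .model import BackboneConfig, build_student
from .prep import GREEN_SCHEME, normalize, patient_level_split, resize_image
from .probe_eval import EvalProtocol, fit_linear_probe
from .synthetic import SyntheticSpec, generate_dataset
from .tokrecon import TrainConfig, train

__all__ = ["desk_scale_config", "desk_scale_pretraining", "grade_probe_auc"]


def desk_scale_config() -> tuple[BackboneConfig, TrainConfig]:
    """The desk-scale study conditions: a tiny backbone (embed 32, depth 2,
    patch 8 on 64x64 inputs) trained for a few hundred steps at batch 16.

    The learning rate is scaled up relative to the full-scale run (peak 3e-3
    instead of 5e-5): a 200-step budget needs proportionally larger steps for
    training progress to be measurable, while warmup/cosine/cooldown shape
    and the 0.1 gradient clip are kept.
    """
    backbone = BackboneConfig(image_side=64, patch_side=8, embed_dim=32,
                              depth=2, heads=2)
    training = TrainConfig(epochs=16, batch_size=16, peak_lr=3e-3, min_lr=3e-6,
                           warmup_epochs=2, cooldown_epochs=2)
    return backbone, training


def grade_probe_auc(model, images, table, seed: int = 0) -> float:
    """Macro-average one-vs-rest AUC of the multinomial lesion-grade probe on
    a patient-level held-out split of the model's embeddings."""
    emb = compute_embeddings(model, [im.pixels for im in images], GREEN_SCHEME,
                             batch_size=32, ids=[im.image_id for im in images])
    train_ids, test_ids = patient_level_split(table, 0.8, seed=seed)
    pos = {i: r for r, i in enumerate(emb.ids)}
    grades = table.set_index("image_id")["grade"]
    tr = [pos[i] for i in train_ids]
    te = [pos[i] for i in test_ids]
    probe = fit_linear_probe(
        EmbeddingMatrix(emb.values[tr], train_ids),
        grades.loc[train_ids].values, EvalProtocol(), target="grade")
    aucs = probe.auc(EmbeddingMatrix(emb.values[te], test_ids),
                     grades.loc[test_ids].values)
    return float(np.mean(list(aucs.values())))


def desk_scale_pretraining(seed: int = 0, n_patients: int = 128,
                           images_per_patient: int = 2,
                           n_steps: int = 200) -> dict:
    """Pretrain the tiny student on 256 synthetic fundus images and compare a
    lesion-grade linear probe on its embeddings against the same probe on a
    random-initialisation network of the same architecture.

    Returns initial / final running loss and the two probe AUCs.
    """
    backbone, training = desk_scale_config()
    spec = SyntheticSpec(image_side=backbone.image_side, seed=seed)
    images, table = generate_dataset(
        spec, n_patients=n_patients, images_per_patient=images_per_patient,
        grade_distribution=(0.2, 0.2, 0.2, 0.2, 0.2), seed=seed)
    side = backbone.image_side
    stack = np.stack([normalize(resize_image(im.pixels, (side, side)), GREEN_SCHEME)
                      for im in images])

    model = build_student(backbone, seed=seed + 1)
    model, history = train(stack, model, train_config=training, n_steps=n_steps,
                           rng=np.random.default_rng(seed))
    random_model = build_student(backbone, seed=seed + 2)

    return {
        "initial_loss": history["loss"][0],
        "final_running_loss": float(np.mean(history["loss"][-20:])),
        "loss_history": history["loss"],
        "max_grad_norm": max(history["grad_norm"]),
        "trained_grade_auc": grade_probe_auc(model, images, table, seed=seed),
        "random_grade_auc": grade_probe_auc(random_model, images, table, seed=seed),
        "n_images": len(images),
        "model": model,
    }
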