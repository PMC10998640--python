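"""Label construction, composite loss and the training loop.

Affinity labels exist only for native complexes, yet training runs over
docking decoys too.  The model therefore predicts, alongside RMSD and
pKd, a decay factor W in (0, 1) expressing how fast apparent binding
strength decays per Angstrom of deviation from the native pose.  The
pKd regression target of a decoy is constructed on the fly as

    pKd_label = pKd_nat - W * RMSD_real

so a near-native pose is anchored at the measured affinity and worse
poses are discounted at a learned, complex-specific rate.  By default W
is treated as a constant inside the label (no gradient) so the network
cannot chase its own target.

The loss over a mini-batch of N samples is

    L = alpha * mse(RMSD_real, RMSD_pred)
      + beta  * mse(pKd_label, pKd_pred)
      + gamma * (1/N) * sum(pKd_pred)

with default weights (1, 0.5, 0.05); the third term pushes predicted
pKd downward overall, promoting the designed negative correlation
between predicted affinity and pose RMSD.  Samples lacking pKd_nat
contribute only the RMSD term.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .featurize import FeatureConfig, featurize_complex
from .geometry import automorphisms, symmetry_corrected_rmsd
from .model.autodiff import Adam, Tensor
from .model.network import ScoringModel
from .structure_io import DatasetManifest, read_ligand, read_protein

logger = logging.getLogger(__name__)

__all__ = [
    "SampleLabel",
    "TrainingConfig",
    "TrainingSample",
    "pkd_label",
    "loss",
    "build_training_set",
    "train",
]


@dataclass(frozen=True)
class SampleLabel:
    rmsd_real: float
    pkd_nat: float | None = None

    def __post_init__(self) -> None:
        if self.rmsd_real < 0:
            raise ValueError("rmsd_real must be >= 0")


@dataclass(frozen=True)
class TrainingConfig:
    alpha: float = 1.0
    beta: float = 0.5
    gamma: float = 0.05
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 200
    seed: int = 0
    detach_W_in_label: bool = True
    val_fraction: float = 0.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be >= 0")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must be in [0, 1)")


@dataclass
class TrainingSample:
    sample_id: str
    graphs: tuple  # (InteractionGraph, PocketGraph)
    label: SampleLabel


def pkd_label(pkd_nat: float, W, rmsd_real: float):
    """Decayed affinity label ``pKd_nat - W * RMSD_real`` (W in (0,1))."""
    return pkd_nat - W * rmsd_real


def loss(predictions: dict, labels: dict, config: TrainingConfig | None = None):
    """Composite training loss.

    `predictions` carries ``rmsd_pred``, ``pkd_pred`` and ``W`` (autodiff
    Tensors or arrays of length N).  `labels` carries ``rmsd_real`` and
    either precomputed ``pkd_label`` or ``pkd_nat`` (NaN marks samples
    without affinity, which then contribute only the RMSD term).

    Returns ``(total, breakdown)`` where total is a Tensor (so it can be
    backpropagated) and breakdown maps term names to floats.
    """
    config = config or TrainingConfig()
    rmsd_pred = Tensor._wrap(predictions["rmsd_pred"])
    pkd_pred = Tensor._wrap(predictions["pkd_pred"])
    n = rmsd_pred.shape[0]
    if n == 0:
        raise ValueError("empty batch")
    rmsd_real = np.asarray(labels["rmsd_real"], dtype=float)

    err_r = rmsd_pred - Tensor(rmsd_real)
    mse_rmsd = (err_r**2.0).mean()

    if "pkd_label" in labels:
        target = np.asarray(labels["pkd_label"], dtype=float)
        mask = np.isfinite(target)
        label_t = Tensor(target[mask])
    else:
        pkd_nat = np.asarray(labels["pkd_nat"], dtype=float)
        mask = np.isfinite(pkd_nat)
        W = Tensor._wrap(predictions["W"])
        if config.detach_W_in_label:
            label_t = Tensor(pkd_nat[mask] - W.data[mask] * rmsd_real[mask])
        else:
            idx = np.nonzero(mask)[0]
            label_t = Tensor(pkd_nat[mask]) - W[idx] * Tensor(rmsd_real[mask])
    if mask.any():
        idx = np.nonzero(mask)[0]
        err_p = pkd_pred[idx] - label_t
        mse_pkd = (err_p**2.0).mean()
    else:
        mse_pkd = Tensor(0.0)

    mean_pkd = pkd_pred.mean()
    total = config.alpha * mse_rmsd + config.beta * mse_pkd + config.gamma * mean_pkd
    breakdown = {
        "mse_rmsd": float(mse_rmsd.data),
        "mse_pkd": float(mse_pkd.data),
        "mean_pkd": float(mean_pkd.data),
        "total": float(total.data),
    }
    return total, breakdown


def build_training_set(
    manifest: DatasetManifest, feature_config: FeatureConfig | None = None
) -> list[TrainingSample]:
    """Load and featurize every resolvable manifest row.

    Missing ``rmsd_real`` is computed as the symmetry-corrected RMSD of
    the pose against the reference ligand (a pose identical to the
    reference gets exactly 0).
    """
    feature_config = feature_config or FeatureConfig()
    proteins: dict[str, object] = {}
    references: dict[str, object] = {}
    samples: list[TrainingSample] = []
    for row in manifest:
        if not row.resolved:
            logger.warning("skipping %s: unresolved paths", row.sample_id)
            continue
        if row.receptor_path not in proteins:
            proteins[row.receptor_path] = read_protein(row.receptor_path)
        if row.ref_ligand_path not in references:
            references[row.ref_ligand_path] = read_ligand(row.ref_ligand_path)
        protein = proteins[row.receptor_path]
        reference = references[row.ref_ligand_path]
        pose = read_ligand(row.pose_path, pose_index=row.pose_index)
        rmsd_real = row.rmsd_real
        if rmsd_real is None:
            autos = automorphisms(pose.topology)
            rmsd_real = symmetry_corrected_rmsd(pose, reference, autos)
        graphs = featurize_complex(protein, pose, reference, feature_config)
        samples.append(
            TrainingSample(
                sample_id=row.sample_id,
                graphs=graphs,
                label=SampleLabel(rmsd_real=rmsd_real, pkd_nat=row.pkd_nat),
            )
        )
    if not samples:
        raise ValueError("manifest yielded no usable samples")
    return samples


def _eval_loss(model: ScoringModel, samples: list[TrainingSample],
               config: TrainingConfig, batch_size: int) -> float:
    model.set_training(False)
    losses, weights = [], []
    for k in range(0, len(samples), batch_size):
        chunk = samples[k : k + batch_size]
        out = model.forward_batch([s.graphs for s in chunk])
        _, br = loss(
            out,
            {
                "rmsd_real": [s.label.rmsd_real for s in chunk],
                "pkd_nat": [
                    np.nan if s.label.pkd_nat is None else s.label.pkd_nat
                    for s in chunk
                ],
            },
            config,
        )
        losses.append(br["total"])
        weights.append(len(chunk))
    return float(np.average(losses, weights=weights))


def train(
    samples: list[TrainingSample],
    model: ScoringModel,
    config: TrainingConfig | None = None,
) -> pd.DataFrame:
    """Seeded epoch-based optimization; returns the per-epoch history.

    A validation split (``val_fraction``) selects the best parameters by
    validation loss; without one the final-epoch parameters are kept.
    The model is left holding the selected parameters, in evaluation
    mode.
    """
    config = config or TrainingConfig()
    if not samples:
        raise ValueError("no training samples")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(samples))
    n_val = int(round(config.val_fraction * len(samples)))
    val = [samples[i] for i in order[:n_val]]
    tr = [samples[i] for i in order[n_val:]]
    if not tr:
        raise ValueError("validation split consumed all samples")

    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate)
    best_val = np.inf
    best_state: dict | None = None
    records = []
    for epoch in range(config.epochs):
        model.set_training(True)
        perm = rng.permutation(len(tr))
        terms = {"mse_rmsd": [], "mse_pkd": [], "mean_pkd": [], "total": []}
        for k in range(0, len(tr), config.batch_size):
            chunk = [tr[i] for i in perm[k : k + config.batch_size]]
            out = model.forward_batch([s.graphs for s in chunk])
            total, br = loss(
                out,
                {
                    "rmsd_real": [s.label.rmsd_real for s in chunk],
                    "pkd_nat": [
                        np.nan if s.label.pkd_nat is None else s.label.pkd_nat
                        for s in chunk
                    ],
                },
                config,
            )
            opt.zero_grad()
            total.backward()
            opt.step()
            for key in terms:
                terms[key].append(br[key])
        rec = {"epoch": epoch} | {k: float(np.mean(v)) for k, v in terms.items()}
        if val:
            rec["val_loss"] = _eval_loss(model, val, config, config.batch_size)
            if rec["val_loss"] < best_val:
                best_val = rec["val_loss"]
                best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        records.append(rec)
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.set_training(False)
    return pd.DataFrame(records)
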