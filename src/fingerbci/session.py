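"""End-to-end session pipelines: open-loop training, the closed-loop
training protocol with ReFIT rounds, and the dSNR channel-scaling
experiment.

The training protocol mirrors standard practice for bootstrapping a finger
decoder: supervised training on scripted open-loop trials first, then
closed-loop blocks on the easier T_TRAIN variant until roughly 80% of
trials succeed, then the full task, with a ReFIT parameter update after
every closed-loop block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SessionConfig
from .decoder import Decoder, DecoderConfig, TrainingSet, refit_relabel, windows_from_sbp
from .dsnr import DsnrCurve, DsnrDataset, PowerLawFit, dsnr_vs_channels, power_law_fit
from .population import BIN_WIDTH_S, TuningModel, emit_sbp, make_population
from .tasks import (
    DOF_LABELS_2D,
    DOF_LABELS_4D,
    TaskConfig,
    TrialRecord,
    open_loop_trajectory,
    run_closed_loop_session,
)

__all__ = [
    "make_open_loop_training_set",
    "SessionBlock",
    "SessionLog",
    "run_training_protocol",
    "intent_directions",
    "simulate_dsnr_dataset",
    "dsnr_scaling_experiment",
]


def make_open_loop_training_set(
    model: TuningModel,
    n_trials: int = 40,
    n_rest_trials: int = 8,
    seed: int = 0,
    dof_labels: tuple[str, ...] | None = None,
) -> TrainingSet:
    """Scripted open-loop trials rendered into (window, velocity) pairs.

    Each trial cues one random DOF to full flexion or extension along a
    minimum-jerk profile; the population emits SBP for the instantaneous
    trajectory velocity; labels are those velocities in ROM-units/s.  Rest
    trials contribute zero-velocity bins.
    """
    if dof_labels is None:
        dof_labels = DOF_LABELS_2D if model.dof == 2 else DOF_LABELS_4D
    if len(dof_labels) != model.dof:
        raise ValueError("dof_labels inconsistent with model.dof")
    rng = np.random.default_rng(seed)
    windows, labels = [], []

    def render(velocities: np.ndarray) -> None:
        sbp = emit_sbp(model, velocities, rng)
        windows.append(windows_from_sbp(sbp))
        labels.append(velocities)

    for _ in range(n_trials):
        dof = int(rng.integers(model.dof))
        direction = "flex" if rng.random() < 0.5 else "extend"
        pos = open_loop_trajectory(dof, direction, dof_labels=dof_labels)
        render(np.diff(pos, axis=0) / BIN_WIDTH_S)
    rest_bins = int(round(1.0 / BIN_WIDTH_S))
    for _ in range(n_rest_trials):
        render(np.zeros((rest_bins, model.dof)))

    return TrainingSet(
        windows=np.concatenate(windows),
        targets=np.concatenate(labels),
        provenance=np.full(sum(len(l) for l in labels), "open_loop"),
    )


@dataclass
class SessionBlock:
    task_kind: str
    records: list[TrialRecord]
    decoder_version: int
    success_rate: float


@dataclass
class SessionLog:
    config_hash: str
    seed: int
    blocks: list[SessionBlock] = field(default_factory=list)


def run_training_protocol(
    cfg: SessionConfig,
) -> tuple[Decoder, TuningModel, SessionLog]:
    """Open-loop training, then closed-loop blocks with ReFIT updates.

    For 4-DOF tasks the first closed-loop blocks use the T_TRAIN variant
    until the configured success gate is reached, then switch to the
    configured task.  Decoder versions increase by one at every retraining
    event.  Fully deterministic from ``cfg.seed``.
    """
    root = np.random.default_rng(cfg.seed)
    seeds = root.integers(0, 2**31 - 1, size=64)
    model = make_population(
        n_channels=cfg.population.n_channels,
        dof=cfg.population.dof,
        tuning_sd=cfg.population.tuning_sd,
        noise_sd=cfg.population.noise_sd,
        interaction_scale=cfg.population.interaction_scale,
        baseline=cfg.population.baseline,
        seed=int(seeds[0]),
    )
    labels = DOF_LABELS_2D if model.dof == 2 else DOF_LABELS_4D
    dconf = DecoderConfig(
        n_channels=model.n_channels,
        dof=model.dof,
        n_time_features=cfg.decoder.n_time_features,
        hidden_widths=(*cfg.decoder.hidden_widths, model.dof),
        dropout_rate=cfg.decoder.dropout_rate,
        speed_scale=cfg.decoder.speed_scale,
    )
    decoder = Decoder(dconf, seed=int(seeds[1]))
    ol = make_open_loop_training_set(
        model,
        n_trials=cfg.schedule.open_loop_trials,
        n_rest_trials=cfg.schedule.rest_trials,
        seed=int(seeds[2]),
        dof_labels=labels,
    )
    decoder.train_supervised(
        ol,
        epochs=cfg.decoder.epochs,
        learning_rate=cfg.decoder.learning_rate,
        batch_size=cfg.decoder.batch_size,
        seed=int(seeds[3]),
    )
    version = 1
    log = SessionLog(config_hash=cfg.config_hash(), seed=cfg.seed)

    def run_block(kind: str, seed: int) -> SessionBlock:
        task = TaskConfig(
            task_kind=kind,
            width=cfg.task.width,
            user_speed=cfg.task.user_speed,
            motor_noise_sd=cfg.task.motor_noise_sd,
            hold_s=cfg.task.hold_s,
            timeout_s=cfg.task.timeout_s,
        )
        records = run_closed_loop_session(
            task, decoder, model, cfg.schedule.closed_loop_trials, seed=seed
        )
        rate = float(np.mean([r.success for r in records]))
        return SessionBlock(kind, records, version, rate)

    def refit(records: list[TrialRecord], seed: int) -> None:
        nonlocal version
        relabeled = refit_relabel(records)
        decoder.refit_update(
            relabeled,
            seed=seed,
            n_iterations=cfg.decoder.refit_iterations,
            learning_rate=cfg.decoder.refit_learning_rate,
            weight_decay=cfg.decoder.refit_weight_decay,
        )
        version += 1

    next_seed = iter(range(4, 64))
    # T_TRAIN bootstrapping applies to 4-DOF tasks only
    if model.dof == 4 and cfg.task.kind != "t_train":
        for _ in range(cfg.schedule.max_t_train_rounds):
            block = run_block("t_train", int(seeds[next(next_seed)]))
            log.blocks.append(block)
            refit(block.records, int(seeds[next(next_seed)]))
            if block.success_rate >= cfg.schedule.t_train_gate:
                break
    for _ in range(max(1, cfg.schedule.refit_rounds)):
        block = run_block(cfg.task.kind, int(seeds[next(next_seed)]))
        log.blocks.append(block)
        refit(block.records, int(seeds[next(next_seed)]))
    return decoder, model, log


# ------------------------------------------------------------ dSNR experiment


def intent_directions(dof: int) -> np.ndarray:
    """The idealized unit target directions of the paired-target tasks.

    In 2D these are the four diagonal unit vectors (both finger groups move
    simultaneously toward flexion/extension targets); for higher DOF all
    sign patterns over two simultaneously cued axes are used.
    """
    if dof == 2:
        d = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        return d / np.sqrt(2.0)
    dirs = []
    for i in range(dof):
        for j in range(i + 1, dof):
            for si in (1.0, -1.0):
                for sj in (1.0, -1.0):
                    v = np.zeros(dof)
                    v[i], v[j] = si, sj
                    dirs.append(v / np.sqrt(2.0))
    return np.array(dirs)


def simulate_dsnr_dataset(
    n_bins: int = 5000,
    n_channels: int = 192,
    dof: int = 2,
    tuning_sd: float = 1.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> tuple[DsnrDataset, TuningModel]:
    """Go-window intent/SBP pairs from an ideal linear population.

    Intents are unit target vectors drawn uniformly from the task's
    idealized directions; the population has linear tuning and i.i.d.
    Gaussian channel noise -- the regime in which dSNR grows as the square
    root of the channel count.
    """
    rng = np.random.default_rng(seed)
    model = make_population(
        n_channels=n_channels,
        dof=dof,
        tuning_sd=tuning_sd,
        noise_sd=noise_sd,
        interaction_scale=0.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    dirs = intent_directions(dof)
    v = dirs[rng.integers(len(dirs), size=n_bins)]
    x = emit_sbp(model, v, rng)
    return DsnrDataset(x, v), model


def dsnr_scaling_experiment(
    seed: int = 0,
    n_bins: int = 5000,
    n_channels: int = 192,
    dof: int = 2,
    tuning_sd: float = 1.0,
    noise_sd: float = 5.0,
    n_subsets: int = 25,
) -> tuple[DsnrCurve, PowerLawFit]:
    """The full channel-scaling analysis on an ideal simulated population."""
    dataset, _ = simulate_dsnr_dataset(
        n_bins=n_bins,
        n_channels=n_channels,
        dof=dof,
        tuning_sd=tuning_sd,
        noise_sd=noise_sd,
        seed=seed,
    )
    curve = dsnr_vs_channels(
        dataset, n_subsets=n_subsets, rng=np.random.default_rng(seed + 1)
    )
    return curve, power_law_fit(curve)
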