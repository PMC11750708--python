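import numpy as np
import pytest

from fingerbci import Decoder, DecoderConfig, make_population
from fingerbci.session import make_open_loop_training_set


@pytest.fixture(scope="session")
def noiseless_2d():
    """A small noiseless linear population with a converged decoder.

    Read-only: tests that mutate the decoder must build their own.
    Returns (model, decoder, training_set).
    """
    model = make_population(n_channels=24, dof=2, tuning_sd=1.0, noise_sd=0.0, seed=3)
    train = make_open_loop_training_set(model, n_trials=30, n_rest_trials=6, seed=4)
    dec = Decoder(
        DecoderConfig(n_channels=24, dof=2, hidden_widths=(64, 64, 64, 2)), seed=5
    )
    dec.train_supervised(train, epochs=60, seed=6)
    return model, dec, train


@pytest.fixture(scope="session")
def noisy_2d_population():
    return make_population(n_channels=24, dof=2, tuning_sd=1.0, noise_sd=2.0, seed=11)


def make_manual_record(inside_bins, center=0.8, width=0.2, n_bins=None, dof=1):
    """Build a 1-DOF TrialRecord whose all-inside bins are exactly `inside_bins`.

    ``inside_bins`` are bin indices k (entry credited at t = 0.05 k).
    """
    from fingerbci.tasks import TargetSet, TrialRecord

    if n_bins is None:
        n_bins = max(inside_bins) + 1 if inside_bins else 20
    inside = np.zeros(n_bins, dtype=bool)
    inside[list(inside_bins)] = True
    pos = np.full((n_bins + 1, dof), 0.4)
    pos[1:, 0] = np.where(inside, center, 0.4)
    ts = TargetSet(np.full(dof, center), width=width)
    return TrialRecord(
        task_kind="cl2d",
        target_set=ts,
        positions=pos,
        decoded_velocities=np.zeros((n_bins, dof)),
        dof_labels=("thumb_flex",) if dof == 1 else ("thumb_flex", "index_middle"),
        cued_groups=("thumb",),
    )
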