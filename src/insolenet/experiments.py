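"""Desk-scale study harness: canonical small-cohort experiment definitions.

These functions pin down the reduced problem sizes used for end-to-end
validation on a single CPU: a 10-subject cohort running the full 3-10 kph
ramp with 30-s stages (240 s per subject), 10-s windows advanced by 5 s, and
a small network (stem stride 4, 2 layers per block, growth 8, hidden 32)
trained for at most 12 epochs on 3 LOSO folds. The same harness backs the
test suite and the reproduction script so both report the same experiment.
"""

from __future__ import annotations

import numpy as np

from .channels import AXIS_GROUPS
from .model import DenseNetConfig
from .simulate import CohortConfig, ProtocolConfig, _default_coupling
from .training import FoldResult, TrainConfig, run_loso

#: Small feature extractor: T(333 samples) = 21, c1 = 32.
SMALL_DENSENET = DenseNetConfig(
    initial_channels=16, growth_rate=8, layers_per_block=2, n_blocks=3,
    stem_stride=4,
)

#: Number of LOSO folds actually trained in scaled-down runs.
SMALL_N_FOLDS = 3


def small_cohort_config(seed: int, couplings: str = "default") -> CohortConfig:
    """10 subjects x 240 s (full ramp, 30-s stages) at 33.3 Hz.

    ``couplings="equal"`` sets every channel's intensity coupling to the same
    value (the null configuration for calibration checks).
    """
    if couplings == "default":
        coupling = _default_coupling()
    elif couplings == "equal":
        coupling = np.ones_like(_default_coupling())
    else:
        raise ValueError("couplings must be 'default' or 'equal'")
    return CohortConfig(
        n_subjects=10,
        protocol=ProtocolConfig(stage_seconds=30.0),
        coupling=coupling,
        seed=seed,
    )


def small_train_config(seed: int, target: str = "ee",
                       attention_enabled: bool = True) -> TrainConfig:
    return TrainConfig(
        target=target,
        attention_enabled=attention_enabled,
        seed=seed,
        max_epochs=12,
        early_stop_patience=5,
        hidden_size=32,
        densenet=SMALL_DENSENET,
        hop_s=5.0,
    )


def run_small_study(
    seed: int,
    target: str = "ee",
    attention_enabled: bool = True,
    couplings: str = "default",
    n_subjects: int | None = None,
    n_folds: int = SMALL_N_FOLDS,
    max_epochs: int | None = None,
) -> list[FoldResult]:
    """Simulate a small cohort and run the (partial) LOSO experiment on it."""
    from .simulate import simulate_cohort

    cfg = small_cohort_config(seed, couplings)
    if n_subjects is not None:
        cfg.n_subjects = n_subjects
    tcfg = small_train_config(seed, target, attention_enabled)
    if max_epochs is not None:
        tcfg.max_epochs = max_epochs
    cohort = simulate_cohort(cfg)
    return run_loso(cohort, tcfg, max_folds=n_folds)


def attention_z_vs_rest(fold_results: list[FoldResult]) -> tuple[float, float]:
    """Mean attention on the four z-axis IMU channels vs the other 16."""
    att = np.vstack([f.att_matrix for f in fold_results])
    z_cols = AXIS_GROUPS["z"]
    other = [c for c in range(att.shape[1]) if c not in z_cols]
    return float(att[:, z_cols].mean()), float(att[:, other].mean())
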