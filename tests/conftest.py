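"""Shared fixtures: small synthetic sessions reused across test modules.

The tiny 16x16x8 grid keeps per-test runtimes in seconds while preserving
the full design structure (run count, trial count, mask hierarchy,
somatotopic clusters); an amplitude of 0.2 on this grid puts
leave-one-run-out accuracy in the rising part of its SNR curve, and 3.0
saturates it.
"""

from __future__ import annotations

import numpy as np
import pytest

import somatobci as sb

TINY_GRID = (16, 16, 8)


def tiny_generator(
    amplitude: float,
    n_training_runs: int = 6,
    n_answer_runs: int = 0,
    **overrides,
) -> sb.GeneratorConfig:
    return sb.GeneratorConfig(
        grid_shape=TINY_GRID,
        n_training_runs=n_training_runs,
        n_answer_runs=n_answer_runs,
        amplitude=amplitude,
        **overrides,
    )


@pytest.fixture(scope="session")
def moderate_session() -> sb.SubjectSession:
    """Six training + two answer runs at moderate SNR."""
    return sb.simulate_subject(tiny_generator(0.2, n_answer_runs=2), seed=100)


@pytest.fixture(scope="session")
def moderate_features(moderate_session) -> sb.TrialFeatures:
    h = moderate_session.masks
    mask = h.select_indices(["S1", "S2"], 10)
    return sb.extract_features(moderate_session, mask)


@pytest.fixture(scope="session")
def highsnr_session() -> sb.SubjectSession:
    """Near-noiseless subject: signal amplitude far above the noise floor."""
    return sb.simulate_subject(tiny_generator(3.0, n_answer_runs=2), seed=7)


@pytest.fixture(scope="session")
def highsnr_features(highsnr_session) -> sb.TrialFeatures:
    h = highsnr_session.masks
    mask = h.select_indices(["S1", "S2"], 10)
    return sb.extract_features(highsnr_session, mask)


@pytest.fixture(scope="session")
def highsnr_loro(highsnr_features) -> sb.DecodingResult:
    return sb.cv_leave_one_run_out(highsnr_features)
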