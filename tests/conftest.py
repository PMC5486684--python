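from __future__ import annotations

import numpy as np
import pytest

from dosegap.metrics import InjectionHistory, WindowPolicy


@pytest.fixture
def default_policy() -> WindowPolicy:
    return WindowPolicy()


def history_from_gaps(gaps, observation_end_day=731, patient_id="p1") -> InjectionHistory:
    """Build a history from consecutive gap lengths (first injection at 0)."""
    days = [0]
    for gap in gaps:
        days.append(days[-1] + gap)
    return InjectionHistory(
        patient_id=patient_id,
        injection_days=tuple(days),
        observation_end_day=max(observation_end_day, days[-1]),
    )


def random_history(rng: np.random.Generator, max_span: int = 1000) -> InjectionHistory:
    """A random valid history with span at most ``max_span`` days."""
    n_inj = int(rng.integers(1, 7))
    gaps = rng.integers(1, 300, size=n_inj - 1)
    days = [0, *np.cumsum(gaps).tolist()]
    days = [d for d in days if d <= max_span]
    end = int(rng.integers(max(days[-1], 1), max_span + 1))
    return InjectionHistory(patient_id="r", injection_days=tuple(days), observation_end_day=end)


def mcr_day_grid_oracle(history: InjectionHistory, span_days: int = 183, horizon_days: int = 731) -> float:
    """Brute-force MCR: enumerate each day and check coverage."""
    end = min(horizon_days, history.observation_end_day)
    covered = sum(
        1
        for t in range(end)
        if any(d <= t < d + span_days for d in history.injection_days)
    )
    return 100.0 * covered / end
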