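from datetime import datetime, timedelta

import numpy as np
import pytest

from newsfio2 import Admission, LabeledObservation, ObservationSet

BASE_TIME = datetime(2020, 3, 1, 8, 0)


@pytest.fixture
def make_obs():
    """Factory for a complete, all-normal observation set with overrides."""

    def _make(**kw) -> ObservationSet:
        defaults = dict(
            admission_id="A1",
            timestamp=BASE_TIME,
            hr=70.0, rr=16.0, sbp=120.0, spo2=98.0, temp=36.8,
            avpu="A", device="room_air",
        )
        defaults.update(kw)
        return ObservationSet(**defaults)

    return _make


@pytest.fixture
def make_admission():
    def _make(**kw) -> Admission:
        defaults = dict(
            admission_id="A1",
            patient_id="P1",
            age_years=60,
            admit_time=BASE_TIME,
            discharge_time=BASE_TIME + timedelta(days=5),
        )
        defaults.update(kw)
        return Admission(**defaults)

    return _make


@pytest.fixture
def make_labeled(make_obs):
    def _make(fio2: float, label: bool, tte: float | None = None, **kw) -> LabeledObservation:
        return LabeledObservation(make_obs(**kw), label, fio2,
                                  time_to_event_h=tte if label else None)

    return _make


def brute_force_cut_triple(fio2, labels):
    """Independent oracle: exhaustively minimise total weighted Gini over all
    cut triples taken from midpoints between adjacent distinct values."""
    x = np.asarray(fio2, float)
    y = np.asarray(labels, bool)
    order = np.argsort(x)
    x, y = x[order], y[order]
    vals = np.unique(x)
    mids = (vals[:-1] + vals[1:]) / 2.0
    best, best_cost = None, np.inf
    for i in range(len(mids)):
        for j in range(i + 1, len(mids)):
            for k in range(j + 1, len(mids)):
                cuts = (mids[i], mids[j], mids[k])
                idx = np.searchsorted(np.asarray(cuts), x, side="left")
                cost = 0.0
                for band in range(4):
                    m = idx == band
                    n = int(m.sum())
                    if n == 0:
                        continue
                    p = y[m].mean()
                    cost += n * 2.0 * p * (1.0 - p)
                # ties prefer the lexicographically smallest (lowest-FiO2) triple
                if cost < best_cost - 1e-12:
                    best, best_cost = cuts, cost
    return best


def partition_gini_cost(fio2, labels, cuts):
    """Total weighted Gini impurity of the four bands induced by the cuts."""
    x = np.asarray(fio2, float)
    y = np.asarray(labels, bool)
    idx = np.searchsorted(np.asarray(sorted(cuts)), x, side="left")
    cost = 0.0
    for band in range(len(cuts) + 1):
        m = idx == band
        n = int(m.sum())
        if n:
            p = y[m].mean()
            cost += n * 2.0 * p * (1.0 - p)
    return cost


def brute_force_auroc(scores, labels):
    """All positive/negative pairs, ties counted one half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)
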