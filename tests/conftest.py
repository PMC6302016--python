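"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the library's own code paths: AUC by
exhaustive positive-negative pair counting, dual-rule optimization by a
naive double loop over the full threshold grid, the Wilson interval by
its closed form.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import norm

from uroscreen import (
    Cohort,
    CultureLabelConfig,
    GeneratorConfig,
    UrineSample,
    default_device_profile,
    generate_cohort,
    optimize_dual,
)


# ------------------------------------------------------------------ oracles

def pair_count_auc(values, truth) -> float:
    """P(X_pos > X_neg) + 1/2 P(X_pos = X_neg) by exhaustive pair counting."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(truth, dtype=bool)
    pos = v[t]
    neg = v[~t]
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (pos.size * neg.size))


def naive_dual_optimize(b, w, t, criterion="youden", se_target=None):
    """Double loop over every (t_bac, t_wbc) grid pair; same tie-break order
    as the implementation (score, then se, then t_bac, then t_wbc, all max)."""
    b = np.asarray(b, float)
    w = np.asarray(w, float)
    t = np.asarray(t, bool)
    grid_b = np.r_[np.unique(b), np.inf]
    grid_w = np.r_[np.unique(w), np.inf]
    n_pos = t.sum()
    n_neg = (~t).sum()
    best = None
    for tb in grid_b:
        for tw in grid_w:
            screen = (b >= tb) | (w >= tw)
            se = np.sum(t & screen) / n_pos
            sp = (n_neg - np.sum(~t & screen)) / n_neg
            if criterion == "youden":
                score = se + sp - 1.0
            else:
                score = sp if se >= se_target else -np.inf
            key = (score, se, tb, tw)
            if best is None or key > best[0]:
                best = (key, float(tb), float(tw), float(se), float(sp))
    _, tb, tw, se, sp = best
    return tb, tw, se, sp


def wilson_interval(k: int, n: int, level: float = 0.95):
    """Closed-form Wilson score interval."""
    z = norm.ppf(0.5 + level / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return centre - half, centre + half


def random_instance(rng, n_max=50):
    """Small random marker instance with both truth classes present."""
    n = int(rng.integers(4, n_max + 1))
    b = np.round(rng.lognormal(2.0, 1.2, n), 2)
    w = np.round(rng.lognormal(1.5, 1.0, n), 2)
    t = rng.random(n) < rng.uniform(0.2, 0.6)
    if not t.any():
        t[int(rng.integers(n))] = True
    if t.all():
        t[int(rng.integers(n))] = False
    return b, w, t


# ----------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def cohort_a() -> Cohort:
    """Synthetic device-A cohort at the default study conditions, n=5000."""
    return generate_cohort(GeneratorConfig(n=5000, seed=1))


@pytest.fixture(scope="session")
def cohort_a_shifted() -> Cohort:
    """Same draws as a device-A cohort but with a −2 log-scale count shift."""
    base = default_device_profile("A")
    prof = type(base)(
        name="Ashift", bac_model=base.bac_model, wbc_model=base.wbc_model,
        scale_shift=-2.0,
    )
    return generate_cohort(GeneratorConfig(n=5000, seed=1, device=prof))


@pytest.fixture(scope="session")
def cohort_b() -> Cohort:
    """Synthetic device-B cohort (lower count scale, lower bacteria AUC)."""
    return generate_cohort(
        GeneratorConfig(n=5000, seed=2, device=default_device_profile("B"))
    )


@pytest.fixture(scope="session")
def floor_opt_a(cohort_a):
    """se_floor(0.95)-optimal dual rule on the device-A cohort (cached)."""
    return optimize_dual(cohort_a, criterion="se_floor", se_target=0.95)


@pytest.fixture()
def hand_cohort() -> Cohort:
    """8-sample cohort whose confusion cells under rule (100, 50) are known:
    tp=2, fn=1, fp=3, tn=2 (sample 7 is a contaminated culture at 3e5 CFU/mL)."""
    rows = [
        ("s1", 150.0, 10.0, 2e5, False),
        ("s2", 50.0, 80.0, 1e5, False),
        ("s3", 20.0, 10.0, 5e5, False),
        ("s4", 120.0, 5.0, 1e3, False),
        ("s5", 10.0, 60.0, 1e2, False),
        ("s6", 5.0, 5.0, 1e4, False),
        ("s7", 200.0, 100.0, 3e5, True),
        ("s8", 30.0, 20.0, 1e4, False),
    ]
    samples = [
        UrineSample(sample_id=sid, device="A", bacteria_per_uL=b,
                    wbc_per_uL=w, culture_cfu_per_mL=cfu, contaminated=cont)
        for sid, b, w, cfu, cont in rows
    ]
    return Cohort(samples=samples, label_config=CultureLabelConfig())
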