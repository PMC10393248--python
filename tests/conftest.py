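"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use naive O(N^2) loops and per-line scans,
independent of the vectorized implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from tensoreeg.features import FeatureConfig, cohort_feature_table
from tensoreeg.simulate import CohortSimSpec, simulate_eeg_cohort
from tensoreeg.tensor import build_tensor


# ---------------------------------------------------------------------------
# brute-force oracles


def sampen_bruteforce(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """O(N^2) template-counting sample entropy, explicit loops."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = r_frac * float(np.std(x))
    templates = [x[i : i + m + 1] for i in range(n - m)]
    a = b = 0
    for i in range(len(templates)):
        for j in range(i + 1, len(templates)):
            d_m = max(abs(templates[i][k] - templates[j][k]) for k in range(m))
            if d_m <= r:
                b += 1
                if max(d_m, abs(templates[i][m] - templates[j][m])) <= r:
                    a += 1
    if b == 0:
        return float("nan")
    if a == 0:
        return float("inf")
    return float(-np.log(a / b))


def diagonal_lengths_bruteforce(mat: np.ndarray, theiler: int = 1) -> list[int]:
    """Per-diagonal run scan of a binary recurrence plot."""
    n = mat.shape[0]
    lengths = []
    for k in range(-(n - 1), n):
        if abs(k) < theiler:
            continue
        run = 0
        for v in np.diagonal(mat, offset=k):
            if bool(v):
                run += 1
            elif run:
                lengths.append(run)
                run = 0
        if run:
            lengths.append(run)
    return lengths


def vertical_lengths_bruteforce(mat: np.ndarray, value: bool) -> list[int]:
    """Per-column run scan (LOI included) of recurrent or white runs."""
    lengths = []
    for j in range(mat.shape[1]):
        run = 0
        col = mat[:, j] if value else ~mat[:, j]
        for v in col:
            if bool(v):
                run += 1
            elif run:
                lengths.append(run)
                run = 0
        if run:
            lengths.append(run)
    return lengths


def rqa_bruteforce(mat: np.ndarray, theiler: int = 1, lmin: int = 2, vmin: int = 2) -> dict:
    """All nine recurrence measures by exhaustive run-length enumeration."""
    n = mat.shape[0]
    off = int(mat.sum() - np.diagonal(mat).sum())
    diag = np.array(diagonal_lengths_bruteforce(mat, theiler))
    diag_long = diag[diag >= lmin] if len(diag) else diag
    vert = np.array(vertical_lengths_bruteforce(mat, True))
    vert_long = vert[vert >= vmin] if len(vert) else vert
    white = np.array(vertical_lengths_bruteforce(mat, False))

    def entropy(lengths):
        if len(lengths) == 0:
            return 0.0
        _, c = np.unique(lengths, return_counts=True)
        p = c / c.sum()
        return float(-(p * np.log(p)).sum())

    return {
        "RR": off / (n * (n - 1)),
        "DET": float(diag_long.sum() / diag.sum()) if diag.sum() else 0.0,
        "LAM": float(vert_long.sum() / vert.sum()) if vert.sum() else 0.0,
        "TT": float(vert_long.mean()) if len(vert_long) else 0.0,
        "Lentr": entropy(diag_long),
        "Lmax": float(diag_long.max()) if len(diag_long) else 0.0,
        "Lmean": float(diag_long.mean()) if len(diag_long) else 0.0,
        "VertEnt": entropy(vert_long),
        "AvgVertWhiteLen": float(white.mean()) if len(white) else 0.0,
    }


def random_recurrence_plot(rng: np.random.Generator, n: int, density: float = None) -> np.ndarray:
    """Random symmetric binary plot with True LOI."""
    density = density if density is not None else rng.uniform(0.05, 0.5)
    m = rng.random((n, n)) < density
    m = m | m.T
    np.fill_diagonal(m, True)
    return m


# ---------------------------------------------------------------------------
# shared synthetic cohorts (expensive; built once per session)

#: analysis scale used by the end-to-end tests: 6-s segments, 8 channels,
#: embedding capped at 600 points — full study conditions (19 ch, 30 s)
#: are exercised shape-wise in cheap unit tests
E2E_FEATURE_CONFIG = FeatureConfig(max_points=600)


@pytest.fixture(scope="session")
def separated_cohort():
    """n=40 two-group cohort with a strong regularity separation."""
    spec = CohortSimSpec(
        group_sizes={"healthy_control": 20, "anxiety": 20},
        n_channels=8, fs=500.0, duration=6.0,
        group_effect=1.0, age_effect=0.0, seed=2,
    )
    recordings, ptable = simulate_eeg_cohort(spec)
    table = cohort_feature_table(recordings, E2E_FEATURE_CONFIG)
    tensor, supervision = build_tensor(
        table, participant_table=ptable, covariates=(),
        contrast=("anxiety", "healthy_control"), standardize=False,
    )
    return tensor, supervision


@pytest.fixture(scope="session")
def age_cohort():
    """n=80 single-group cohort with a full-strength age gradient."""
    ages = [[1, 3, 5, 7][i % 4] for i in range(80)]
    spec = CohortSimSpec(
        group_sizes={"healthy_control": 80}, ages=ages,
        n_channels=8, fs=500.0, duration=6.0,
        age_effect=1.0, group_effect=0.0, seed=11,
    )
    recordings, _ = simulate_eeg_cohort(spec)
    table = cohort_feature_table(recordings, E2E_FEATURE_CONFIG)
    tensor, _ = build_tensor(table)
    agemap = {r.participant_id: r.age_code for r in recordings}
    ages_vec = np.array([agemap[p] for p in tensor.participants], dtype=float)
    return tensor, ages_vec
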