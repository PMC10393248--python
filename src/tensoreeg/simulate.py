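"""Synthetic data with known ground truth.

Two generators stand in for restricted cohort data:

* :func:`simulate_supcp_tensor` draws tensors from the SupCP generative
  model itself (scores U = Y B + F, rank-R structure plus entrywise
  Gaussian noise), so factorization recovery can be tested against known
  factors.

* :func:`simulate_eeg_cohort` builds multichannel EEG-like signals as a
  per-band mixture of band-limited Gaussian noise plus a shared
  deterministic component (sinusoid + logistic-map chaos) whose relative
  weight decreases with a synthetic age gradient (raising signal
  complexity, emulating developmental complexification) and shifts with
  group membership (altering regularity).  Recurrence measures respond
  strongly to the deterministic fraction, which is why the mixture is
  parameterized this way.  No physiological realism (dipoles, artifacts)
  is attempted; group/age effect sizes are free parameters, not cohort
  estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from tensoreeg.bands import CANONICAL_EDGES
from tensoreeg.eeg_io import CANONICAL_1020, EEGRecording
from tensoreeg.supcp import SupCPModel, cp_reconstruct
from tensoreeg.tensor import FeatureTensor, SupervisionMatrix, encode_covariates

#: relative amplitude of the band-limited noise components (1/f-like)
_BAND_WEIGHTS = {
    "delta": 1.0,
    "theta": 0.7,
    "alpha": 0.6,
    "beta": 0.4,
    "gamma": 0.25,
    "gamma+": 0.15,
}

#: group signatures: opposing shifts so a merged "atypical" class is
#: heterogeneous (its two halves move regularity in opposite directions)
_GROUP_SIGN = {"healthy_control": 0.0, "anxiety": 1.0, "externalizing": -1.0}


@dataclass
class TensorSimSpec:
    """Specification for a supervised low-rank tensor simulation.

    coeff_matrix B maps supervision columns (class indicator first, then
    the configured covariates) to latent scores; score_sd / noise_sd are
    the residual score spread sigma_f and the entrywise noise sigma_e.
    """

    n_participants: int
    mode_dims: tuple[int, ...]
    rank: int
    coeff_matrix: np.ndarray
    score_sd: float = 1.0
    noise_sd: float = 0.1
    covariates: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.coeff_matrix = np.asarray(self.coeff_matrix, dtype=float)
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if any(d < 1 for d in self.mode_dims):
            raise ValueError("all mode dimensions must be >= 1")
        if self.score_sd < 0 or self.noise_sd < 0:
            raise ValueError("score_sd and noise_sd must be >= 0")
        if self.rank > min(self.mode_dims):
            raise ValueError(
                f"rank {self.rank} exceeds the smallest mode dimension "
                f"{min(self.mode_dims)}; factors would be degenerate"
            )
        q = 1 + len(self.covariates)
        if self.coeff_matrix.shape != (q, self.rank):
            raise ValueError(
                f"coeff_matrix must be ({q}, {self.rank}) for contrast + "
                f"covariates {self.covariates}"
            )


def _synthetic_participants(n: int, rng: np.random.Generator,
                            groups: tuple[str, ...] = ("healthy_control", "anxiety")) -> pd.DataFrame:
    """Balanced two-group participant table with study-like covariates."""
    group = np.array([groups[i % len(groups)] for i in range(n)])
    return pd.DataFrame(
        {
            "id": [f"P{i:04d}" for i in range(n)],
            "group": group,
            "age_code": 5,
            "sex": rng.integers(0, 2, size=n),
            "birthweight": rng.normal(3541.0, 701.0, size=n).round(0),
            "age_initial": rng.normal(7.92, 2.75, size=n).round(2),
        }
    )


def simulate_supcp_tensor(
    spec: TensorSimSpec,
) -> tuple[FeatureTensor, SupervisionMatrix, SupCPModel]:
    """Draw a tensor from the SupCP generative model.

    Returns (tensor, supervision, truth): the tensor is a sum of R rank-1
    terms with scores U = Y B + F plus entrywise noise; ``truth`` records
    the generating loadings, B, sigma_f, sigma_e and scores.
    Reproducible from spec.seed; supervision uses the same encoding path
    as the tensor builder (class indicator + covariates).
    """
    rng = np.random.default_rng(spec.seed)
    n, dims, r = spec.n_participants, tuple(spec.mode_dims), spec.rank
    ptable = _synthetic_participants(n, rng)
    supervision = encode_covariates(
        ptable, covariates=spec.covariates, contrast=("anxiety", "healthy_control")
    )
    factors = []
    for d in dims:
        a = rng.standard_normal((d, r))
        a = np.linalg.qr(a)[0][:, :r] if r <= d else a / np.linalg.norm(a, axis=0)
        factors.append(a)
    f_resid = spec.score_sd * rng.standard_normal((n, r))
    scores = supervision.Y @ spec.coeff_matrix + f_resid
    clean = cp_reconstruct(scores, factors)
    noise = spec.noise_sd * rng.standard_normal(clean.shape)
    array = clean + noise
    if len(dims) == 3:
        axis_names = ("participant", "measure", "channel", "band")
    else:
        axis_names = ("participant",) + tuple(f"mode{k+1}" for k in range(len(dims)))
    axis_labels = {axis_names[0]: supervision.participants}
    for name, d in zip(axis_names[1:], dims):
        axis_labels[name] = [f"{name}{j}" for j in range(d)]
    tensor = FeatureTensor(array=array, axis_names=axis_names, axis_labels=axis_labels)
    truth = SupCPModel(
        rank=r,
        factor_matrices=factors,
        coeff_matrix=spec.coeff_matrix.copy(),
        score_var=np.full(r, spec.score_sd**2),
        noise_var=spec.noise_sd**2,
        scores=scores,
        loglik_trace=np.empty(0),
        column_names=list(supervision.column_names),
    )
    return tensor, supervision, truth


# ---------------------------------------------------------------------------
# EEG-like cohort generator


@dataclass
class CohortSimSpec:
    """Specification for a synthetic EEG cohort.

    group_sizes maps group name -> participant count; ages gives the age
    code(s) per participant (an int, or an iterable of ints for
    longitudinal recordings; default age 5 for everyone).  age_effect
    scales how strongly within-band signal roughness rises with age
    (raising complexity); group_effect scales the group shift of that
    roughness (positive signature = anxiety = more regular, negative =
    externalizing = less regular, so the merged "atypical" class is
    heterogeneous).
    """

    group_sizes: dict[str, int]
    ages: list | None = None
    age_effect: float = 1.0
    group_effect: float = 0.5
    n_channels: int = 19
    fs: float = 500.0
    duration: float = 30.0
    det_weight: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if any(v < 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if sum(self.group_sizes.values()) < 1:
            raise ValueError("cohort must contain at least one participant")
        if self.ages is not None and len(self.ages) != sum(self.group_sizes.values()):
            raise ValueError("ages must have one entry per participant")


def _channel_labels(n: int) -> list[str]:
    if n <= len(CANONICAL_1020):
        return list(CANONICAL_1020[:n])
    if n == 129:
        # HydroCel-style export: 128 net electrodes plus the vertex reference
        return [f"E{i+1}" for i in range(128)] + ["Cz"]
    return [f"E{i+1}" for i in range(n)]


def _band_noise(rng: np.random.Generator, n: int, fs: float, roughness: float = 0.5) -> np.ndarray:
    """Sum of band-limited Gaussian noise components, one per canonical band.

    Each band mixes a bottom-edge (smooth, predictable within the band)
    and a full-band (rough) filtered-noise component:

        (1 - roughness) * bottom-third + roughness * full-band.

    ``roughness`` is therefore a within-band regularity dial: raising it
    enriches every band's top edge, which raises sample entropy and
    lowers determinism / DFA exponents of the wavelet sub-band series —
    the generator's complexity mechanism.
    """
    out = np.zeros(n)
    nyq = fs / 2.0
    for band, (lo, hi) in CANONICAL_EDGES.items():
        hi_c = min(hi, 0.95 * nyq)
        if hi_c <= lo:
            continue
        mid = lo + 0.35 * (hi_c - lo)
        sos_lo = sp_signal.butter(4, [lo / nyq, mid / nyq], btype="band", output="sos")
        sos_full = sp_signal.butter(4, [lo / nyq, hi_c / nyq], btype="band", output="sos")
        smooth = sp_signal.sosfilt(sos_lo, rng.standard_normal(n))
        rough = sp_signal.sosfilt(sos_full, rng.standard_normal(n))
        smooth /= smooth.std()
        rough /= rough.std()
        out += _BAND_WEIGHTS[band] * ((1.0 - roughness) * smooth + roughness * rough)
    return out


def _logistic_map(rng: np.random.Generator, n: int) -> np.ndarray:
    """Fully chaotic logistic-map orbit (r = 4), centred, unit variance."""
    x = np.empty(n)
    x[0] = rng.uniform(0.1, 0.9)
    for k in range(1, n):
        x[k] = 4.0 * x[k - 1] * (1.0 - x[k - 1])
    x = (x - 0.5) * 2.0
    return x / x.std()


def _deterministic_component(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Shared sinusoid + slow logistic-map chaos, unit variance.

    The logistic map is stepped at ~fs/16 and linearly interpolated, so
    this component is smooth at the sample scale while deterministic-
    chaotic at longer horizons; it gives channels common oscillatory
    structure.
    """
    t = np.arange(n) / fs
    f0 = rng.uniform(7.0, 11.0)  # alpha-range oscillation
    phase = rng.uniform(0, 2 * np.pi)
    sine = np.sin(2 * np.pi * f0 * t + phase)
    step = 16
    n_map = n // step + 2
    x = _logistic_map(rng, n_map)
    chaos = np.interp(np.arange(n) / step, np.arange(n_map), x)
    d = sine + 0.5 * chaos
    return d / d.std()


def simulate_eeg_cohort(spec: CohortSimSpec) -> tuple[list[EEGRecording], pd.DataFrame]:
    """Generate a labeled synthetic EEG cohort.

    Returns one recording per (participant, age code) and a participant
    table (id, group, age_code of the first recording, sex, birthweight,
    age_initial).  Each channel mixes independent per-band noise with a
    recording-wide smooth deterministic component; the within-band
    roughness of the noise

        c = 0.5 + 0.6 * age_effect * ((age - 1) / 6 - 0.5) - 0.3 * group_effect * sign(group)

    rises with age (complexity increases: sample entropy up, determinism
    down) and falls for a positive-signature group (anxiety: more
    regular), clipped to [0.05, 0.95].
    """
    rng = np.random.default_rng(spec.seed)
    n_total = sum(spec.group_sizes.values())
    groups: list[str] = []
    for g, cnt in spec.group_sizes.items():
        groups.extend([g] * cnt)
    ages = spec.ages if spec.ages is not None else [5] * n_total
    if len(ages) != n_total:
        raise ValueError("ages must have one entry per participant")
    n_samples = int(round(spec.duration * spec.fs))
    labels = _channel_labels(spec.n_channels)

    recordings: list[EEGRecording] = []
    rows = []
    for i, (group, age_entry) in enumerate(zip(groups, ages)):
        pid = f"S{i:04d}"
        age_list = [age_entry] if np.isscalar(age_entry) else list(age_entry)
        sign = _GROUP_SIGN.get(group, 1.0)
        sex = int(rng.integers(0, 2))
        bw = float(np.round(rng.normal(3541.0, 701.0)))
        age_init = float(np.round(rng.normal(7.92, 2.75), 2))
        for age in age_list:
            age_norm = (float(age) - 1.0) / 6.0
            # smooth shared oscillation, mildly fading with age
            w_det = spec.det_weight * (1.0 - 0.3 * spec.age_effect * age_norm)
            # within-band roughness: the complexity dial.  It rises with
            # age (complexification) and falls for a positive-signature
            # (more regular) group.
            rough = 0.5 + 0.6 * spec.age_effect * (age_norm - 0.5)
            rough -= 0.3 * spec.group_effect * sign
            rough = float(np.clip(rough, 0.05, 0.95))
            det = _deterministic_component(rng, n_samples, spec.fs)
            data = np.empty((spec.n_channels, n_samples))
            for c in range(spec.n_channels):
                gain = 1.0 + 0.1 * rng.standard_normal()
                data[c] = 10.0 * (
                    _band_noise(rng, n_samples, spec.fs, roughness=rough)
                    + w_det * gain * det
                )
            recordings.append(
                EEGRecording(
                    data=data,
                    fs=spec.fs,
                    channel_labels=labels,
                    participant_id=pid,
                    age_code=int(age),
                )
            )
        rows.append(
            {
                "id": pid,
                "group": group,
                "age_code": int(age_list[0]),
                "sex": sex,
                "birthweight": bw,
                "age_initial": age_init,
            }
        )
    return recordings, pd.DataFrame(rows)
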