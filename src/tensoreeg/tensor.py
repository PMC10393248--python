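"""Multiway feature-tensor assembly and supervision-matrix encoding.

The long-format feature table (participant, age_code, channel, band,
measure, value) is pivoted into a participant x measure x channel x band
array, with an additional trailing age mode when more than one recording
age enters the analysis.  Participants missing any required age or any
feature cell are dropped (complete case); surviving cells are z-scored
across participants, with the standardization constants kept so that
cross-validation can standardize held-out data from training-fold
statistics only.

The supervision matrix Y holds one binary class-contrast column plus the
configured covariates (recording-age code, sex assigned at birth coded
0/1, birthweight in grams).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tensoreeg.bands import BAND_NAMES
from tensoreeg.features import MEASURE_NAMES

#: named covariate configurations (the class contrast column is always first)
COVARIATE_CONFIGS = {
    "eeg_only": (),
    "eeg_sex": ("sex",),
    "eeg_bw_sex": ("birthweight", "sex"),
}


@dataclass
class FeatureTensor:
    """Axis-labeled multiway feature array.

    ``array`` has shape (participants, measures, channels, bands[, ages]);
    ``axis_labels`` names every position on every axis; ``cell_mean`` /
    ``cell_sd`` record the per-cell standardization constants (shape =
    array.shape[1:], or None when unstandardized).
    """

    array: np.ndarray
    axis_names: tuple[str, ...]
    axis_labels: dict[str, list]
    cell_mean: np.ndarray | None = None
    cell_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.array.ndim != len(self.axis_names):
            raise ValueError("axis_names must match array dimensionality")
        for name, dim in zip(self.axis_names, self.array.shape):
            if len(self.axis_labels[name]) != dim:
                raise ValueError(f"axis {name!r}: {len(self.axis_labels[name])} labels for dim {dim}")

    @property
    def participants(self) -> list:
        return self.axis_labels[self.axis_names[0]]

    def standardized(self) -> "FeatureTensor":
        """Z-score every cell across participants (axis 0)."""
        mean = self.array.mean(axis=0)
        sd = self.array.std(axis=0, ddof=0)
        return self.standardized_with(mean, sd)

    def standardized_with(self, mean: np.ndarray, sd: np.ndarray) -> "FeatureTensor":
        """Standardize with externally supplied constants (e.g. training fold)."""
        sd_safe = np.where(sd > 0, sd, 1.0)
        return FeatureTensor(
            array=(self.array - mean) / sd_safe,
            axis_names=self.axis_names,
            axis_labels={k: list(v) for k, v in self.axis_labels.items()},
            cell_mean=mean,
            cell_sd=sd,
        )

    def subset(self, idx: np.ndarray) -> "FeatureTensor":
        labels = {k: list(v) for k, v in self.axis_labels.items()}
        pk = self.axis_names[0]
        labels[pk] = [labels[pk][i] for i in np.atleast_1d(idx)]
        return FeatureTensor(
            array=self.array[np.atleast_1d(idx)],
            axis_names=self.axis_names,
            axis_labels=labels,
        )

    def save(self, stem: str | Path) -> tuple[Path, Path]:
        """Serialize as flat binary (.npy) + JSON sidecar (.json)."""
        stem = Path(stem)
        npy = stem.with_suffix(".npy")
        meta = stem.with_suffix(".json")
        np.save(npy, self.array)
        sidecar = {
            "axis_names": list(self.axis_names),
            "axis_labels": {k: list(map(_jsonable, v)) for k, v in self.axis_labels.items()},
            "cell_mean": None if self.cell_mean is None else self.cell_mean.tolist(),
            "cell_sd": None if self.cell_sd is None else self.cell_sd.tolist(),
        }
        meta.write_text(json.dumps(sidecar))
        return npy, meta

    @classmethod
    def load(cls, stem: str | Path) -> "FeatureTensor":
        stem = Path(stem)
        array = np.load(stem.with_suffix(".npy"))
        sidecar = json.loads(stem.with_suffix(".json").read_text())
        return cls(
            array=array,
            axis_names=tuple(sidecar["axis_names"]),
            axis_labels={k: list(v) for k, v in sidecar["axis_labels"].items()},
            cell_mean=None if sidecar["cell_mean"] is None else np.asarray(sidecar["cell_mean"]),
            cell_sd=None if sidecar["cell_sd"] is None else np.asarray(sidecar["cell_sd"]),
        )


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


@dataclass
class SupervisionMatrix:
    """Per-participant supervision: class contrast column(s) + covariates."""

    Y: np.ndarray
    column_names: list[str]
    participants: list

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2 or self.Y.shape[1] != len(self.column_names):
            raise ValueError("Y must be participants x named columns")
        if self.Y.shape[0] != len(self.participants):
            raise ValueError("Y rows must align with participants")

    def subset(self, idx: np.ndarray) -> "SupervisionMatrix":
        idx = np.atleast_1d(idx)
        return SupervisionMatrix(
            Y=self.Y[idx],
            column_names=list(self.column_names),
            participants=[self.participants[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Y, columns=self.column_names, index=self.participants)


def encode_covariates(
    participant_table: pd.DataFrame,
    covariates: tuple[str, ...] | str = (),
    contrast: tuple[str, str] | None = None,
) -> SupervisionMatrix:
    """Encode class indicator and covariate columns.

    Parameters
    ----------
    participant_table : DataFrame with columns ``id``, ``group`` and any of
        ``age_code`` (integer recording age: 1 infancy, 3, 5, 7 years),
        ``sex`` (0/1 or 'F'/'M'), ``birthweight`` (grams), ``age_initial``
        (exact age at the first recording, months).
    covariates : covariate names to append, or a named configuration key
        ('eeg_only', 'eeg_sex', 'eeg_bw_sex').
    contrast : (positive_group, reference_group); when given, a 0/1 class
        column for positive_group is the first column of Y.

    Raises ``KeyError`` for unknown covariates and ``ValueError`` naming the
    participant on a missing value.
    """
    if isinstance(covariates, str):
        if covariates not in COVARIATE_CONFIGS:
            raise KeyError(f"unknown covariate configuration {covariates!r}")
        covariates = COVARIATE_CONFIGS[covariates]
    cols: list[np.ndarray] = []
    names: list[str] = []
    table = participant_table
    if contrast is not None:
        pos, ref = contrast
        keep = table["group"].isin([pos, ref])
        table = table.loc[keep]
        cols.append((table["group"] == pos).to_numpy(dtype=float))
        names.append(f"class:{pos}")
    for cov in covariates:
        if cov not in {"age_code", "sex", "birthweight", "age_initial"}:
            raise KeyError(f"unknown covariate {cov!r}")
        if cov not in table.columns:
            raise ValueError(f"participant table lacks covariate column {cov!r}")
        col = table[cov]
        if col.isna().any():
            missing_ids = table.loc[col.isna(), "id"].tolist()
            raise ValueError(f"missing {cov!r} for participants {missing_ids}")
        if cov == "sex":
            col = col.map(lambda v: {"F": 0, "M": 1, "f": 0, "m": 1}.get(v, v))
        cols.append(col.to_numpy(dtype=float))
        names.append(cov)
    if not cols:
        raise ValueError("no class contrast and no covariates requested")
    return SupervisionMatrix(
        Y=np.column_stack(cols),
        column_names=names,
        participants=table["id"].tolist(),
    )


def build_tensor(
    feature_table: pd.DataFrame,
    ages_required: list[int] | None = None,
    participant_table: pd.DataFrame | None = None,
    covariates: tuple[str, ...] | str = (),
    contrast: tuple[str, str] | None = None,
    standardize: bool = True,
) -> tuple[FeatureTensor, SupervisionMatrix | None]:
    """Pivot the long feature table into a labeled multiway array.

    With one required age the array is 4-way (participant, measure,
    channel, band); with several it gains a trailing age mode ordered by
    age code.  Complete case: participants lacking any required age or any
    cell are dropped.  Cells are z-scored across participants when
    ``standardize`` (full-sample constants; cross-validation instead calls
    :meth:`FeatureTensor.standardized_with` with training-fold constants).
    """
    required_cols = {"participant", "age_code", "channel", "band", "measure", "value"}
    if not required_cols.issubset(feature_table.columns):
        raise ValueError(f"feature table must have columns {sorted(required_cols)}")
    df = feature_table
    cross_sectional = ages_required is None
    if cross_sectional:
        # each participant contributes a slice at their own (single) age
        per_part_ages = df.groupby("participant")["age_code"].nunique()
        if (per_part_ages > 1).any():
            raise ValueError(
                "participants have multiple recording ages; pass ages_required "
                "to build a tensor with an age mode"
            )
        ages_required = [0]  # placeholder: no age filtering, no age mode
    else:
        ages_required = sorted(int(a) for a in ages_required)
        df = df[df["age_code"].isin(ages_required)]

    measures = [m for m in MEASURE_NAMES if m in set(df["measure"])]
    channels = sorted(df["channel"].unique())
    bands = [b for b in BAND_NAMES if b in set(df["band"])]
    n_cells = len(measures) * len(channels) * len(bands) * len(ages_required)

    counts = df.groupby("participant").size()
    complete = sorted(counts.index[counts == n_cells])
    if not complete:
        raise ValueError(
            "no participant has a complete feature set for the requested ages"
        )
    df = df[df["participant"].isin(complete)]

    axis_names = ["participant", "measure", "channel", "band"]
    index_levels = {
        "participant": complete,
        "measure": measures,
        "channel": channels,
        "band": bands,
    }
    if not cross_sectional and len(ages_required) > 1:
        axis_names.append("age")
        index_levels["age"] = ages_required

    shape = tuple(len(index_levels[a]) for a in axis_names)
    array = np.full(shape, np.nan)
    locators = {a: {v: i for i, v in enumerate(index_levels[a])} for a in axis_names}
    idx = [df[c].map(locators[c]).to_numpy() for c in ("participant", "measure", "channel", "band")]
    if "age" in locators:
        idx.append(df["age_code"].map(locators["age"]).to_numpy())
    array[tuple(idx)] = df["value"].to_numpy(dtype=float)
    if np.isnan(array).any():
        raise AssertionError("complete-case filtering left NaN cells")

    tensor = FeatureTensor(
        array=array,
        axis_names=tuple(axis_names),
        axis_labels=index_levels,
    )
    if standardize:
        tensor = tensor.standardized()

    supervision = None
    if participant_table is not None:
        ptab = participant_table.set_index("id").loc[complete].reset_index()
        ptab = ptab.rename(columns={"index": "id"})
        supervision = encode_covariates(ptab, covariates=covariates, contrast=contrast)
        if supervision.participants != list(tensor.participants):
            # contrast filtering may drop participants; subset tensor to match
            keep = [i for i, p in enumerate(tensor.participants) if p in set(supervision.participants)]
            tensor = tensor.subset(np.asarray(keep))
            order = {p: i for i, p in enumerate(supervision.participants)}
            if [order[p] for p in tensor.participants] != list(range(len(order))):
                raise AssertionError("supervision rows misaligned with tensor")
    return tensor, supervision
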