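"""Feature-table assembly and covariate correction.

Each subject contributes hippocampal volumes (left/right/total, ml) and,
per classification ROI, one TBM and one or two VBM features.  Regional
measures depend on age, sex and head size, so every feature is corrected
with an ordinary-least-squares model of age, sex (0 = female, 1 = male) and
intracranial volume fitted on healthy reference subjects only — using
patients would remove disease variance.  Corrected values are standardized
by the reference residual mean/SD, so the reference cohort itself comes out
with exactly zero mean and unit standard deviation per feature.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imgio import SubjectRecord

COVARIATE_COLUMNS = ("age", "sex01", "icv")


@dataclass
class FeatureTable:
    """Subjects × named features plus covariates and group labels."""

    df: pd.DataFrame
    feature_names: list[str]

    def __post_init__(self) -> None:
        required = {"id", "group", "age", "sex", "icv"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"feature table missing columns {sorted(missing)}")
        if self.df["id"].duplicated().any():
            dup = self.df.loc[self.df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate subject id {dup!r}")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        unknown = set(self.feature_names) - set(self.df.columns)
        if unknown:
            raise ValueError(f"feature columns {sorted(unknown)} not in table")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sex01(self) -> np.ndarray:
        return (self.df["sex"] == "male").to_numpy(dtype=float)

    def covariate_matrix(self) -> np.ndarray:
        """Design matrix [1, age, sex01, icv]."""
        return np.column_stack(
            [
                np.ones(len(self.df)),
                self.df["age"].to_numpy(dtype=float),
                self.sex01,
                self.df["icv"].to_numpy(dtype=float),
            ]
        )

    def values(self, features: Sequence[str] | None = None) -> np.ndarray:
        return self.df[list(features or self.feature_names)].to_numpy(dtype=float)

    def subset(self, groups: Sequence[str]) -> "FeatureTable":
        sub = self.df[self.df["group"].isin(list(groups))].reset_index(drop=True)
        return FeatureTable(sub.copy(), list(self.feature_names))

    def dropna_rows(self, features: Sequence[str] | None = None) -> "FeatureTable":
        cols = list(features or self.feature_names)
        sub = self.df.dropna(subset=cols).reset_index(drop=True)
        return FeatureTable(sub.copy(), list(self.feature_names))

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        df = self.df.copy()
        df.attrs = {}
        df.to_csv(path, sep="\t", index=False)
        meta = {"feature_names": self.feature_names}
        Path(str(path) + ".meta.json").write_text(json.dumps(meta))
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", dtype={"id": str})
        meta_path = Path(str(path) + ".meta.json")
        if meta_path.exists():
            names = json.loads(meta_path.read_text())["feature_names"]
        else:
            names = [c for c in df.columns if c not in ("id", "group", "age", "sex", "icv", "mmse")]
        return cls(df, list(names))


def assemble_feature_table(
    records: Sequence[SubjectRecord],
    hippocampal_volumes: Mapping[str, tuple[float, float]],
    tbm_features: Mapping[str, Mapping[str, float]],
    vbm_features: Mapping[str, Mapping[str, float]],
    vbm_mod_features: Mapping[str, Mapping[str, float]] | None = None,
    roi_names: Sequence[str] = (),
) -> FeatureTable:
    """Build the subjects × features table.

    ``hippocampal_volumes`` maps subject id -> (left_ml, right_ml); the
    TBM/VBM mappings are subject id -> {roi name -> value}.  Missing entries
    become NaN (excluded listwise at classification time).
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject id in records")
    roi_names = list(roi_names) or sorted(
        {roi for d in tbm_features.values() for roi in d}
    )
    feature_names = ["HV_left", "HV_right", "HV_total"]
    feature_names += [f"TBM_{r}" for r in roi_names]
    feature_names += [f"VBM_{r}" for r in roi_names]
    if vbm_mod_features is not None:
        feature_names += [f"VBMmod_{r}" for r in roi_names]

    rows = []
    for rec in records:
        row: dict[str, object] = {
            "id": rec.id, "group": rec.group, "age": rec.age,
            "sex": rec.sex, "icv": rec.icv,
        }
        hv = hippocampal_volumes.get(rec.id)
        row["HV_left"] = hv[0] if hv else np.nan
        row["HV_right"] = hv[1] if hv else np.nan
        row["HV_total"] = (hv[0] + hv[1]) if hv else np.nan
        for roi in roi_names:
            row[f"TBM_{roi}"] = tbm_features.get(rec.id, {}).get(roi, np.nan)
            row[f"VBM_{roi}"] = vbm_features.get(rec.id, {}).get(roi, np.nan)
            if vbm_mod_features is not None:
                row[f"VBMmod_{roi}"] = vbm_mod_features.get(rec.id, {}).get(roi, np.nan)
        rows.append(row)
    return FeatureTable(pd.DataFrame(rows), feature_names)


@dataclass
class CovariateModel:
    """Per-feature OLS of [1, age, sex01, icv] fitted on healthy subjects,
    plus the reference residual mean/SD used for standardization."""

    feature_names: list[str]
    coefficients: np.ndarray  # shape (n_features, 4): intercept, age, sex, icv
    residual_mean: np.ndarray
    residual_sd: np.ndarray
    reference_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.residual_mean = np.asarray(self.residual_mean, dtype=float)
        self.residual_sd = np.asarray(self.residual_sd, dtype=float)
        if np.any(self.residual_sd <= 0):
            raise ValueError("residual SD must be > 0 for every feature")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "feature_names": self.feature_names,
            "coefficients": self.coefficients.tolist(),
            "residual_mean": self.residual_mean.tolist(),
            "residual_sd": self.residual_sd.tolist(),
            "reference_ids": self.reference_ids,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CovariateModel":
        d = json.loads(Path(path).read_text())
        return cls(
            d["feature_names"],
            np.asarray(d["coefficients"]),
            np.asarray(d["residual_mean"]),
            np.asarray(d["residual_sd"]),
            d.get("reference_ids", []),
        )


def fit_covariate_model(
    table: FeatureTable,
    reference_ids: Sequence[str] | None = None,
    min_reference: int = 10,
) -> CovariateModel:
    """Fit the per-feature covariate regression on the reference rows.

    The reference must contain only healthy-labelled (group C) subjects so
    no disease-specific variation is removed.
    """
    if reference_ids is None:
        ref = table.df[table.df["group"] == "C"]
    else:
        ref = table.df[table.df["id"].isin(list(reference_ids))]
    if len(ref) < min_reference:
        raise ValueError(f"need at least {min_reference} reference subjects, got {len(ref)}")
    if not (ref["group"] == "C").all():
        raise ValueError("covariate reference must contain only healthy (C) subjects")
    sub = FeatureTable(ref.reset_index(drop=True).copy(), list(table.feature_names))
    X = sub.covariate_matrix()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates in the reference cohort")
    Y = sub.values()
    if np.isnan(Y).any():
        raise ValueError("reference cohort has missing feature values")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    mean = resid.mean(axis=0)
    sd = resid.std(axis=0, ddof=0)
    degenerate = np.where(sd <= 0)[0]
    if degenerate.size:
        # a feature with zero residual variance carries no information (e.g.
        # an ROI with an empty weight image); its corrected values become 0
        bad = [table.feature_names[i] for i in degenerate]
        warnings.warn(f"zero residual variance for feature(s) {bad}; standardizing to 0",
                      stacklevel=2)
        sd = sd.copy()
        sd[degenerate] = 1.0
        beta[:, degenerate] = 0.0
        mean = mean.copy()
        mean[degenerate] = Y[:, degenerate].mean(axis=0)
    return CovariateModel(
        list(table.feature_names), beta.T, mean, sd, list(sub.df["id"]),
    )


def correct_features(table: FeatureTable, model: CovariateModel) -> FeatureTable:
    """Apply the covariate correction and reference standardization:
    value -> (value − Xβ − residual_mean) / residual_SD.

    Rows with a missing covariate are flagged (``covariates_missing``) and
    their features set to NaN so they drop out of classification.
    """
    if list(model.feature_names) != list(table.feature_names):
        raise ValueError("model features do not match the table")
    df = table.df.copy()
    cov_ok = (
        df["age"].notna() & df["sex"].isin(["male", "female"]) & df["icv"].notna()
    ).to_numpy()
    work = FeatureTable(df.copy(), list(table.feature_names))
    X = work.covariate_matrix()
    Y = work.values()
    pred = X @ model.coefficients.T
    corrected = (Y - pred - model.residual_mean) / model.residual_sd
    corrected[~cov_ok, :] = np.nan
    df.loc[:, table.feature_names] = corrected
    df["covariates_missing"] = ~cov_ok
    return FeatureTable(df, list(table.feature_names))
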