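"""Per-subject QEEG feature records and the feature-combination grid.

A full per-subject record holds 19 channels x 6 bands of absolute band
power (log10-transformed by default) and 171 channel pairs x 6 bands of
coherence - 1,140 QEEG values. Feature matrices are assembled for one
combination of {parameter, band set, IQ-adjustment}: the QEEG parameter is
PSD (19 features/band), FC (171 features/band) or PSD+FC (190/band); the
band set is a single band or all six ("whole"); covariates age, sex and
years of education always enter, IQ optionally. Column counts therefore
run from 22 (PSD, delta, no IQ) to 1,144 (PSD+FC, whole, with IQ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import UndefinedCoherenceError, ValidationError
from .montage import DEFAULT_MONTAGE
from .spectral import DEFAULT_BANDS, BandDefinition, CrossSpectrum

PSD, FC, PSD_FC = "PSD", "FC", "PSD+FC"
PARAMETERS = (PSD, FC, PSD_FC)

BASE_COVARIATES = ("age", "sex", "education")
IQ = "iq"
LOG_EPS = 1e-12


# ---------------------------------------------------------------- covariates


def validate_covariates(covs: pd.DataFrame, require_iq: bool = True) -> pd.DataFrame:
    """Validate a covariate table (columns age, sex, education[, iq]).

    Sex is coded male=1 / female=0. Ages must lie in the 18-70 analysis
    eligibility range and all values must be finite.
    """
    needed = list(BASE_COVARIATES) + ([IQ] if require_iq else [])
    missing = [c for c in needed if c not in covs.columns]
    if missing:
        raise ValidationError(f"covariate table missing columns: {missing}")
    sub = covs[needed]
    if not np.all(np.isfinite(sub.to_numpy(dtype=float))):
        bad = covs.index[~np.isfinite(sub.to_numpy(dtype=float)).all(axis=1)]
        raise ValidationError(f"non-finite covariates for subjects: {list(bad)}")
    if ((covs["age"] < 18) | (covs["age"] > 70)).any():
        bad = covs.index[(covs["age"] < 18) | (covs["age"] > 70)]
        raise ValidationError(f"ages outside 18-70 for subjects: {list(bad)}")
    return covs


# ---------------------------------------------------------------- combinations


@dataclass(frozen=True)
class FeatureCombination:
    """One cell of the combination grid: parameter x band set x IQ flag."""

    parameter: str
    bands: tuple[str, ...]
    adjust_iq: bool = False

    def __post_init__(self):
        if self.parameter not in PARAMETERS:
            raise ValidationError(f"unknown parameter {self.parameter!r}")
        known = {b.name for b in DEFAULT_BANDS}
        bands = tuple(self.bands)
        if not bands or any(b not in known for b in bands):
            raise ValidationError(f"bands must be a nonempty subset of {sorted(known)}")
        object.__setattr__(self, "bands", bands)

    @property
    def is_whole(self) -> bool:
        return len(self.bands) == len(DEFAULT_BANDS)

    @property
    def n_columns(self) -> int:
        per_band = 0
        if self.parameter in (PSD, PSD_FC):
            per_band += len(DEFAULT_MONTAGE)
        if self.parameter in (FC, PSD_FC):
            per_band += len(DEFAULT_MONTAGE.pairs())
        return per_band * len(self.bands) + len(BASE_COVARIATES) + int(self.adjust_iq)

    def label(self) -> str:
        bands = "whole" if self.is_whole else "+".join(self.bands)
        return f"{self.parameter}/{bands}" + ("/iq" if self.adjust_iq else "")


def enumerate_combination_grid(adjust_iq: bool = False) -> list[FeatureCombination]:
    """The 21-cell grid: {PSD, FC, PSD+FC} x {six single bands, whole}."""
    whole = tuple(b.name for b in DEFAULT_BANDS)
    grid = []
    for parameter in PARAMETERS:
        for bands in [*((b,) for b in whole), whole]:
            grid.append(FeatureCombination(parameter, bands, adjust_iq))
    return grid


# ---------------------------------------------------------------- extraction


def psd_column(band: str, channel: str) -> str:
    return f"psd_{band}_{channel}"


def coh_column(band: str, x: str, y: str) -> str:
    return f"coh_{band}_{x}_{y}"


def parse_column(name: str) -> tuple[str, str, tuple[str, ...]]:
    """Invert the column naming: -> (parameter, band, channel(s))."""
    kind, _, rest = name.partition("_")
    if kind == "psd":
        band, _, channel = rest.rpartition("_")
        return PSD, band, (channel,)
    if kind == "coh":
        parts = rest.split("_")
        band, x, y = "_".join(parts[:-2]), parts[-2], parts[-1]
        return FC, band, (x, y)
    if kind == "cov":
        return "covariate", "", (rest,)
    raise ValueError(f"unparseable feature column {name!r}")


def extract_subject_features(
    cs: CrossSpectrum,
    transform: str = "log10",
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> pd.Series:
    """Full per-subject QEEG record: 114 band powers + 1,026 coherences.

    Band powers are log10(power + 1e-12) by default (``transform="raw"``
    for untransformed microvolts-squared); coherences are never
    transformed. Returns a named Series keyed psd_<band>_<ch> /
    coh_<band>_<x>_<y>.
    """
    if transform not in ("log10", "raw"):
        raise ValueError(f"unknown transform {transform!r}")
    labels = cs.montage.labels
    C = len(labels)
    iu, ju = np.triu_indices(C, k=1)
    names: list[str] = []
    values: list[float] = []
    for band in bands:
        mask = band.bin_mask(cs.bin_freqs)
        power = cs.norm * cs.auto_power[:, mask].sum(axis=1) / cs.n_windows
        if transform == "log10":
            power = np.log10(power + LOG_EPS)
        names.extend(psd_column(band.name, ch) for ch in labels)
        values.extend(power.tolist())
    for band in bands:
        mask = band.bin_mask(cs.bin_freqs)
        num = (
            cs.cross_real[iu, ju][:, mask] ** 2 + cs.cross_imag[iu, ju][:, mask] ** 2
        )
        denom = cs.auto_power[iu][:, mask] * cs.auto_power[ju][:, mask]
        dead = (denom <= 0).all(axis=1)
        if dead.any():
            k = int(np.flatnonzero(dead)[0])
            raise UndefinedCoherenceError(
                f"zero auto-power over every {band.name} bin for pair "
                f"({labels[iu[k]]}, {labels[ju[k]]})"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            coh_bins = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
        coh = np.nanmean(coh_bins, axis=1)
        names.extend(coh_column(band.name, labels[i], labels[j]) for i, j in zip(iu, ju))
        values.extend(coh.tolist())
    return pd.Series(values, index=names, dtype=float)


# ---------------------------------------------------------------- matrices


@dataclass
class FeatureMatrix:
    """Subjects x named features for one combination, plus binary labels."""

    X: pd.DataFrame
    y: np.ndarray
    combination: FeatureCombination | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate feature columns")
        if not np.all(np.isfinite(self.X.to_numpy())):
            raise ValueError("feature matrix contains missing values")

    @property
    def subjects(self) -> list:
        return list(self.X.index)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path) -> None:
        out = self.X.copy()
        out.insert(0, "label", self.y)
        out.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="subject_id")
        y = df.pop("label").to_numpy()
        return cls(df, y)


class CombinationSelector(BaseEstimator, TransformerMixin):
    """Transformer selecting one combination's columns from full records.

    Input is a DataFrame of full per-subject records joined with
    ``cov_``-prefixed covariate columns; output keeps the QEEG columns of
    the combination (parameter x bands) followed by the covariates.
    """

    def __init__(self, combination: FeatureCombination | None = None):
        self.combination = combination

    def fit(self, X: pd.DataFrame, y=None):
        combo = self.combination or FeatureCombination(PSD_FC, tuple(b.name for b in DEFAULT_BANDS))
        cols: list[str] = []
        if combo.parameter in (PSD, PSD_FC):
            for band in combo.bands:
                cols += [psd_column(band, ch) for ch in DEFAULT_MONTAGE.labels]
        if combo.parameter in (FC, PSD_FC):
            for band in combo.bands:
                cols += [coh_column(band, x, y_) for x, y_ in DEFAULT_MONTAGE.pairs()]
        cols += [f"cov_{c}" for c in BASE_COVARIATES]
        if combo.adjust_iq:
            cols.append(f"cov_{IQ}")
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise ValidationError(f"records missing columns: {missing[:5]}...")
        self.columns_ = cols
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.columns_]


def build_feature_matrix(
    records: pd.DataFrame,
    covs: pd.DataFrame,
    combo: FeatureCombination,
    labels: np.ndarray | pd.Series | None = None,
) -> FeatureMatrix:
    """Assemble the feature matrix for one combination.

    ``records`` holds one full QEEG record per subject (rows aligned with
    ``covs``); ``labels`` may alternatively live in a ``label`` column of
    ``covs``. Subject order is preserved exactly.
    """
    validate_covariates(covs, require_iq=combo.adjust_iq)
    if labels is None:
        if "label" not in covs.columns:
            raise ValidationError("labels not given and covariate table has no 'label' column")
        labels = covs["label"]
    labels = np.asarray(labels, dtype=int)
    missing = [s for s in records.index if s not in covs.index]
    if missing:
        raise ValidationError(f"subjects missing covariates: {missing}")
    covs = covs.loc[records.index]
    joined = records.copy()
    for c in (*BASE_COVARIATES, IQ):
        if c in covs.columns:
            joined[f"cov_{c}"] = covs[c].to_numpy(dtype=float)
    X = CombinationSelector(combo).fit(joined).transform(joined)
    fm = FeatureMatrix(X, labels, combination=combo)
    assert fm.n_features == combo.n_columns
    return fm
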