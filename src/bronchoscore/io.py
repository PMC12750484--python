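"""Readers and writers for the ratings CSV dialect and YAML configs.

Ratings CSV (long format, UTF-8, comma-separated, integer scores):

    subject_id,group,rater_id,feature_id,lobe,score

Unknown extra columns are preserved on read but ignored downstream.
Validation failures name the offending row (1-based, counting the header
as row 1).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .pipeline import StudyConfig
from .registry import GROUPS, LOBES, FeatureRegistry, default_registry
from .simulate import FeatureSim, RaterSpec, SimulationConfig

RATINGS_COLUMNS = ["subject_id", "group", "rater_id", "feature_id", "lobe",
                   "score"]
COMPOSITE_COLUMNS = ["subject_id", "group", "rater_id", "feature_id",
                     "composite"]


class RatingsValidationError(ValueError):
    """A ratings file violated the dialect or the registry's scales."""


def read_ratings(
    path,
    registry: Optional[FeatureRegistry] = None,
    *,
    validate: bool = True,
) -> pd.DataFrame:
    """Read and validate a long-format ratings CSV.

    Checks: required columns, integer scores, known lobe codes, group
    constant within subject, scores within the feature's per-lobe range
    (when the feature is in the registry), and uniqueness of
    (subject, rater, feature, lobe).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing:
        raise RatingsValidationError(
            f"{path}: missing column(s) {missing}; "
            f"expected header {','.join(RATINGS_COLUMNS)}"
        )
    if not validate:
        df["score"] = pd.to_numeric(df["score"]).astype(int)
        return df

    registry = registry or default_registry()
    rownum = df.index + 2  # 1-based with header

    score_num = pd.to_numeric(df["score"], errors="coerce")
    bad = score_num.isna() | (score_num % 1 != 0)
    if bad.any():
        i = bad.idxmax()
        raise RatingsValidationError(
            f"{path}: row {rownum[i]}: non-integer score "
            f"{df.loc[i, 'score']!r} (feature {df.loc[i, 'feature_id']})"
        )
    df["score"] = score_num.astype(int)

    bad = ~df["lobe"].isin(LOBES)
    if bad.any():
        i = bad.idxmax()
        raise RatingsValidationError(
            f"{path}: row {rownum[i]}: unknown lobe {df.loc[i, 'lobe']!r}; "
            f"expected one of {', '.join(LOBES)}"
        )

    for fid, sub in df.groupby("feature_id", sort=False):
        if fid not in registry:
            raise RatingsValidationError(
                f"{path}: row {rownum[sub.index[0]]}: unknown feature_id "
                f"{fid!r}"
            )
        lmax = registry[fid].per_lobe_max
        bad = (sub["score"] < 0) | (sub["score"] > lmax)
        if bad.any():
            i = bad.idxmax()
            raise RatingsValidationError(
                f"{path}: row {rownum[i]}: score {df.loc[i, 'score']} out of "
                f"range [0, {lmax}] for feature {fid!r}"
            )

    dup = df.duplicated(
        subset=["subject_id", "rater_id", "feature_id", "lobe"], keep="first"
    )
    if dup.any():
        i = dup.idxmax()
        raise RatingsValidationError(
            f"{path}: row {rownum[i]}: duplicate "
            f"(subject={df.loc[i, 'subject_id']}, "
            f"rater={df.loc[i, 'rater_id']}, "
            f"feature={df.loc[i, 'feature_id']}, lobe={df.loc[i, 'lobe']})"
        )

    ngroups = df.groupby("subject_id")["group"].nunique()
    incons = ngroups[ngroups > 1]
    if len(incons):
        raise RatingsValidationError(
            f"{path}: group label not constant within subject(s) "
            f"{incons.index.tolist()}"
        )
    return df


def write_ratings(df: pd.DataFrame, path) -> None:
    """Write a ratings table in canonical column order (row order kept)."""
    extra = [c for c in df.columns if c not in RATINGS_COLUMNS]
    df[RATINGS_COLUMNS + extra].to_csv(path, index=False)


def write_composites(df: pd.DataFrame, path) -> None:
    df[COMPOSITE_COLUMNS].to_csv(path, index=False)


def read_composites(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COMPOSITE_COLUMNS if c not in df.columns]
    if missing:
        raise RatingsValidationError(
            f"{path}: missing column(s) {missing}"
        )
    df["composite"] = pd.to_numeric(df["composite"]).astype(int)
    return df


def demo_ratings_path() -> Path:
    """Packaged three-subject demonstration ratings file (synthetic,
    hand-written)."""
    from importlib import resources

    return Path(
        str(resources.files("bronchoscore.data").joinpath("demo_ratings.csv"))
    )


def load_simulation_config(path) -> SimulationConfig:
    """Parse a simulation YAML into a SimulationConfig."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    raters = tuple(
        RaterSpec(
            rater_id=r["rater_id"],
            bias=float(r.get("bias", 0.0)),
            noise_sd=float(r.get("noise_sd", 0.5)),
        )
        for r in doc["raters"]
    )
    features = tuple(
        FeatureSim(
            feature_id=f["feature_id"],
            per_lobe_max=int(f["per_lobe_max"]),
            cutpoints=tuple(float(c) for c in f["cutpoints"]),
            mu_cf=float(f.get("mu_cf", 0.0)),
            mu_noncf=float(f.get("mu_noncf", 0.0)),
        )
        for f in doc["features"]
    )
    return SimulationConfig(
        n_subjects=int(doc["n_subjects"]),
        raters=raters,
        features=features,
        seed=int(doc["seed"]),
        group_split=float(doc.get("group_split", 0.625)),
        severity_sd=float(doc.get("severity_sd", 1.0)),
        lobe_sd=float(doc.get("lobe_sd", 0.5)),
    )


def load_study_config(path) -> StudyConfig:
    """Parse a study-analysis YAML into a StudyConfig."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    strata = doc.get("strata")
    return StudyConfig(
        weights_kind=doc.get("weights_kind", "ordinal"),
        unit_of_analysis=doc.get("unit_of_analysis", "composite"),
        strata=tuple(strata) if strata else None,
        reference_values=doc.get("reference_values"),
        plugging_binary=bool(doc.get("plugging_binary", False)),
        missing_lobes=doc.get("missing_lobes", "strict"),
        alpha=float(doc.get("alpha", 0.05)),
        fpc=float(doc.get("fpc", 0.0)),
    )
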