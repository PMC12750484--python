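"""Composite scoring: per-lobe ordinal ratings -> per-recording composites.

Two aggregation rules are implemented:

* ``composite_threshold`` — the 50%-of-lobes rule.  With five lobes: composite
  0 means every lobe is 0; a severity level seen in at least one lobe
  contributes its own value; a level reached by *more than half* of the lobes
  (three or more of five) is promoted one step.  The composite is the maximum
  contribution over levels, so the range is ``0..per_lobe_max + 1``.
* ``composite_maximum`` — the maximum across lobes, used for secretion colour
  on the 0-8 Murray chart.

Counting uses lobes rated *at or above* each level, which reproduces the
pure single-level cases of the instrument's rulebook and extends monotonely
to mixed vectors and to any ordinal scale length.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .registry import LOBES, Aggregation, FeatureRegistry


class ScoringError(ValueError):
    """Raised for invalid per-lobe score inputs."""


def _as_scores(scores: Iterable[int], per_lobe_max: int) -> np.ndarray:
    arr = np.asarray(list(scores))
    if arr.size == 0:
        raise ScoringError("no lobes: at least one per-lobe score is required")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ScoringError(f"scores must be integers, got {arr.tolist()}")
        arr = arr.astype(int)
    if arr.min() < 0 or arr.max() > per_lobe_max:
        raise ScoringError(
            f"score out of range [0, {per_lobe_max}]: {arr.tolist()}"
        )
    return arr


def composite_threshold(
    scores: Sequence[int],
    per_lobe_max: int,
    majority_fraction: float = 0.5,
) -> int:
    """Threshold-based composite of per-lobe ordinal scores.

    Parameters
    ----------
    scores
        Per-lobe integer scores in ``[0, per_lobe_max]``; one entry per
        scored lobe (normally five).
    per_lobe_max
        The feature's per-lobe scale maximum ``L``.
    majority_fraction
        Fraction of lobes that must be *exceeded* for promotion; the default
        0.5 means "more than 50% of lobes", i.e. >= 3 of 5.

    Returns
    -------
    int
        Composite in ``[0, per_lobe_max + 1]``; 0 iff every lobe is 0.
    """
    arr = _as_scores(scores, per_lobe_max)
    if arr.max() == 0:
        return 0
    n_lobes = arr.size
    cutoff = majority_fraction * n_lobes
    best = 0
    for level in range(1, per_lobe_max + 1):
        n_at_or_above = int((arr >= level).sum())
        if n_at_or_above == 0:
            continue
        contribution = level + 1 if n_at_or_above > cutoff else level
        best = max(best, contribution)
    return best


def composite_maximum(scores: Sequence[int], per_lobe_max: int) -> int:
    """Maximum-across-lobes composite (secretion colour rule)."""
    arr = _as_scores(scores, per_lobe_max)
    return int(arr.max())


def _threshold_matrix(
    mat: np.ndarray, per_lobe_max: int, majority_fraction: float
) -> np.ndarray:
    """Vectorised threshold rule over rows of a (units x lobes) matrix."""
    n_lobes = mat.shape[1]
    cutoff = majority_fraction * n_lobes
    best = np.zeros(mat.shape[0], dtype=int)
    for level in range(1, per_lobe_max + 1):
        n_ge = (mat >= level).sum(axis=1)
        contribution = np.where(n_ge > cutoff, level + 1, level)
        best = np.maximum(best, np.where(n_ge > 0, contribution, 0))
    return best


def compose_all(
    ratings: pd.DataFrame,
    registry: FeatureRegistry,
    *,
    missing_lobes: str = "strict",
    plugging_binary: bool = False,
    majority_fraction: float = 0.5,
) -> pd.DataFrame:
    """Compute one composite per (subject, rater, feature).

    Parameters
    ----------
    ratings
        Long-format table with columns ``subject_id, group, rater_id,
        feature_id, lobe, score``.
    registry
        Feature definitions supplying scale maxima and aggregation rules.
    missing_lobes
        ``"strict"`` (default) requires the full five-lobe set for every
        (subject, rater, feature) and raises otherwise; ``"lenient"``
        aggregates over the lobes present, rescaling the majority cutoff to
        the observed lobe count.
    plugging_binary
        Keep the mucus-plugging composite binary (any-lobe OR) instead of
        applying the general threshold rule at L=1.

    Returns
    -------
    DataFrame with columns ``subject_id, group, rater_id, feature_id,
    composite``, sorted by (feature registry order, subject, rater).
    """
    if missing_lobes not in ("strict", "lenient"):
        raise ValueError(f"unknown missing_lobes policy: {missing_lobes!r}")

    unknown = set(ratings["feature_id"]) - set(registry.feature_ids)
    if unknown:
        raise ScoringError(f"unknown feature_id(s): {sorted(unknown)}")

    bad_lobes = set(ratings["lobe"]) - set(LOBES)
    if bad_lobes:
        raise ScoringError(f"unknown lobe code(s): {sorted(bad_lobes)}")

    group_of = (
        ratings[["subject_id", "group"]]
        .drop_duplicates()
        .set_index("subject_id")["group"]
    )
    if group_of.index.duplicated().any():
        dupes = group_of.index[group_of.index.duplicated()].tolist()
        raise ScoringError(
            f"group label not constant within subject(s): {sorted(set(dupes))}"
        )

    frames = []
    for fid in registry.feature_ids:
        sub = ratings[ratings["feature_id"] == fid]
        if sub.empty:
            continue
        feat = registry[fid]
        bad = sub[(sub["score"] < 0) | (sub["score"] > feat.per_lobe_max)]
        if not bad.empty:
            r = bad.iloc[0]
            raise ScoringError(
                f"score {r['score']} out of range [0, {feat.per_lobe_max}] "
                f"for subject={r['subject_id']} feature={fid} lobe={r['lobe']}"
            )
        wide = sub.pivot_table(
            index=["subject_id", "rater_id"],
            columns="lobe",
            values="score",
            aggfunc="first",
        ).reindex(columns=list(LOBES))
        if missing_lobes == "strict":
            incomplete = wide.index[wide.isna().any(axis=1)]
            if len(incomplete):
                listing = ", ".join(
                    f"(subject={s}, rater={r}, feature={fid})"
                    for s, r in incomplete[:5]
                )
                raise ScoringError(
                    f"incomplete lobe set for {len(incomplete)} "
                    f"(subject, rater, feature) combination(s): {listing}"
                )
            mat = wide.to_numpy(dtype=int)
            if feat.aggregation is Aggregation.MAXIMUM:
                comp = mat.max(axis=1)
            elif plugging_binary and fid == "mucus_plugging":
                comp = mat.max(axis=1)  # L=1: any-lobe OR
            else:
                comp = _threshold_matrix(
                    mat, feat.per_lobe_max, majority_fraction
                )
        else:
            comp = np.empty(len(wide), dtype=int)
            for i, (_, row) in enumerate(wide.iterrows()):
                vals = row.dropna().astype(int).tolist()
                if not vals:
                    raise ScoringError(
                        f"no lobes scored for (subject={wide.index[i][0]}, "
                        f"rater={wide.index[i][1]}, feature={fid})"
                    )
                if feat.aggregation is Aggregation.MAXIMUM or (
                    plugging_binary and fid == "mucus_plugging"
                ):
                    comp[i] = max(vals)
                else:
                    comp[i] = composite_threshold(
                        vals, feat.per_lobe_max, majority_fraction
                    )
        out = wide.index.to_frame(index=False)
        out["feature_id"] = fid
        out["composite"] = comp
        frames.append(out)

    result = pd.concat(frames, ignore_index=True)
    result["group"] = result["subject_id"].map(group_of)
    result = result[
        ["subject_id", "group", "rater_id", "feature_id", "composite"]
    ]
    order = {fid: i for i, fid in enumerate(registry.feature_ids)}
    result = result.sort_values(
        ["feature_id", "subject_id", "rater_id"],
        key=lambda col: col.map(order) if col.name == "feature_id" else col,
        kind="stable",
    ).reset_index(drop=True)
    return result
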