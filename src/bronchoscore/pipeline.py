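"""End-to-end reliability analysis of a multi-rater rating study.

Orchestrates: per-lobe ratings -> composites -> per-feature overall
agreement, agreement stratified by subject group (CF / non-CF), pairwise
rater agreement, and an optional comparison against literature coefficients
for the overlapping features of the earlier two-rater instrument.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .agreement import (
    AgreementError,
    AgreementEstimate,
    WeightMatrix,
    gwet_agreement,
    interpret_band,
    make_weights,
    pairwise_agreement,
)
from .registry import FeatureRegistry, default_registry
from .scoring import compose_all

_EST_COLUMNS = [
    "feature_id", "stratum", "rater_a", "rater_b", "method", "weights_kind",
    "coefficient", "p_a", "p_e", "se", "ci_low", "ci_high", "band",
    "n_subjects", "reason",
]


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one reliability analysis.

    ``unit_of_analysis`` is ``"composite"`` (one category per recording,
    the default: the recording is the sampling unit) or ``"per_lobe"``
    (every (recording, lobe) pair is a unit on the raw per-lobe scale).
    ``reference_values`` maps feature_id -> literature coefficient; pass
    ``"packaged"`` for the bundled two-rater weighted-kappa values.
    """

    weights_kind: str = "ordinal"
    unit_of_analysis: str = "composite"
    strata: Optional[tuple[str, ...]] = None
    reference_values: Optional[Mapping[str, float] | str] = None
    plugging_binary: bool = False
    missing_lobes: str = "strict"
    alpha: float = 0.05
    fpc: float = 0.0

    def __post_init__(self) -> None:
        if self.unit_of_analysis not in ("composite", "per_lobe"):
            raise ValueError(
                f"unknown unit_of_analysis: {self.unit_of_analysis!r}"
            )
        if self.strata is not None:
            object.__setattr__(self, "strata", tuple(self.strata))


@dataclass
class StudyReport:
    """Tidy result tables of one study analysis."""

    overall: pd.DataFrame
    by_stratum: pd.DataFrame
    pairwise: pd.DataFrame
    comparison: Optional[pd.DataFrame]
    metadata: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def records(df: pd.DataFrame) -> list[dict]:
            out = []
            for rec in df.to_dict(orient="records"):
                out.append(
                    {k: (None if isinstance(v, float) and np.isnan(v) else v)
                     for k, v in rec.items()}
                )
            return out

        doc = {
            "metadata": self.metadata,
            "overall": records(self.overall),
            "by_stratum": records(self.by_stratum),
        }
        if len(self.pairwise):
            doc["pairwise"] = records(self.pairwise)
        if self.comparison is not None and len(self.comparison):
            doc["comparison"] = records(self.comparison)
        return doc

    @classmethod
    def from_json_dict(cls, doc: dict) -> "StudyReport":
        def frame(key: str, columns: Sequence[str]) -> pd.DataFrame:
            rows = doc.get(key, [])
            if not rows:
                return pd.DataFrame(columns=list(columns))
            return pd.DataFrame(rows)[list(columns)]

        comparison = None
        if "comparison" in doc:
            comparison = pd.DataFrame(doc["comparison"])
        return cls(
            overall=frame("overall", _EST_COLUMNS),
            by_stratum=frame("by_stratum", _EST_COLUMNS),
            pairwise=frame("pairwise", _EST_COLUMNS),
            comparison=comparison,
            metadata=doc.get("metadata", {}),
        )


def load_reference_values() -> pd.DataFrame:
    """Bundled literature weighted-kappa coefficients (two expert raters,
    earlier pediatric bronchitis instrument) for the six overlapping
    features.  These are published values shipped for comparison output;
    they are never recomputed here."""
    with resources.files("bronchoscore.data").joinpath(
        "reference_weighted_kappa.csv"
    ).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def _estimate_row(
    feature_id: str,
    stratum: str,
    est: Optional[AgreementEstimate],
    *,
    rater_a: Optional[str] = None,
    rater_b: Optional[str] = None,
    reason: Optional[str] = None,
    n_subjects: Optional[int] = None,
    weights_kind: Optional[str] = None,
) -> dict:
    if est is None:
        return {
            "feature_id": feature_id, "stratum": stratum,
            "rater_a": rater_a, "rater_b": rater_b,
            "method": None, "weights_kind": weights_kind,
            "coefficient": np.nan, "p_a": np.nan, "p_e": np.nan,
            "se": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            "band": None, "n_subjects": n_subjects, "reason": reason,
        }
    d = est.to_dict()
    return {
        "feature_id": feature_id, "stratum": stratum,
        "rater_a": rater_a, "rater_b": rater_b,
        "method": d["method"], "weights_kind": d["weights_kind"],
        "coefficient": d["coefficient"], "p_a": d["p_a"], "p_e": d["p_e"],
        "se": d["se"], "ci_low": d["ci_low"], "ci_high": d["ci_high"],
        "band": d["band"], "n_subjects": d["n_subjects"], "reason": None,
    }


def _wide_units(
    ratings: pd.DataFrame,
    registry: FeatureRegistry,
    config: StudyConfig,
) -> tuple[dict[str, pd.DataFrame], dict[str, int], pd.Series]:
    """Per feature: units x raters category table, category count q, and the
    unit -> group mapping."""
    if config.unit_of_analysis == "composite":
        comp = compose_all(
            ratings, registry,
            missing_lobes=config.missing_lobes,
            plugging_binary=config.plugging_binary,
        )
        value_col, unit_col = "composite", "subject_id"
        data = comp
    else:
        data = ratings.copy()
        data["unit_id"] = (
            data["subject_id"].astype(str) + "::" + data["lobe"].astype(str)
        )
        value_col, unit_col = "score", "unit_id"

    group_of = (
        data[[unit_col, "group"]]
        .drop_duplicates()
        .set_index(unit_col)["group"]
    )
    raters = sorted(data["rater_id"].unique())
    wide_by_feature: dict[str, pd.DataFrame] = {}
    q_by_feature: dict[str, int] = {}
    for fid in registry.feature_ids:
        sub = data[data["feature_id"] == fid]
        if sub.empty:
            continue
        missing_raters = set(raters) - set(sub["rater_id"].unique())
        if missing_raters:
            raise AgreementError(
                f"feature {fid!r} missing for rater(s) "
                f"{sorted(missing_raters)}"
            )
        wide = sub.pivot_table(
            index=unit_col, columns="rater_id", values=value_col,
            aggfunc="first",
        ).reindex(columns=raters).sort_index()
        wide_by_feature[fid] = wide
        if config.unit_of_analysis == "composite":
            q_by_feature[fid] = registry[fid].n_composite_categories(
                plugging_binary=config.plugging_binary
            )
        else:
            q_by_feature[fid] = registry[fid].per_lobe_max + 1
    return wide_by_feature, q_by_feature, group_of


def analyze_study(
    ratings: pd.DataFrame,
    registry: Optional[FeatureRegistry] = None,
    config: Optional[StudyConfig] = None,
) -> StudyReport:
    """Full study analysis: overall, stratified, pairwise and comparison.

    Deterministic given inputs and config.  Strata are computed
    independently on the subject subsets; a stratum with fewer than two
    units is flagged absent rather than estimated.
    """
    registry = registry or default_registry()
    config = config or StudyConfig()
    raters = sorted(ratings["rater_id"].unique())
    if len(raters) < 2:
        raise AgreementError("study analysis needs at least 2 raters")

    wide_by_feature, q_by_feature, group_of = _wide_units(
        ratings, registry, config
    )
    features = list(wide_by_feature)

    strata = config.strata
    if strata is None:
        seen = list(dict.fromkeys(group_of))
        strata = tuple(seen)
    else:
        known = set(group_of)
        bad = [s for s in strata if s not in known]
        if bad:
            raise ValueError(f"strata not present in ratings: {bad}")

    from .agreement import counts_from_assignments  # local to avoid cycle

    def estimate(wide: pd.DataFrame, q: int) -> AgreementEstimate:
        w = make_weights(config.weights_kind, q)
        counts = counts_from_assignments(wide.to_numpy(dtype=float), q)
        return gwet_agreement(
            counts, w, alpha=config.alpha, fpc=config.fpc
        )

    overall_rows, stratum_rows, pair_rows = [], [], []
    for fid in features:
        wide = wide_by_feature[fid]
        q = q_by_feature[fid]
        overall_rows.append(
            _estimate_row(fid, "all", estimate(wide, q))
        )
        for stratum in strata:
            units = group_of.index[group_of == stratum]
            sub = wide.loc[wide.index.intersection(units)]
            if len(sub) < 2:
                stratum_rows.append(
                    _estimate_row(
                        fid, stratum, None,
                        reason=f"stratum has {len(sub)} unit(s); "
                               "need at least 2",
                        n_subjects=len(sub),
                        weights_kind=config.weights_kind,
                    )
                )
                continue
            stratum_rows.append(_estimate_row(fid, stratum, estimate(sub, q)))
        w = make_weights(config.weights_kind, q)
        for a, b, est, reason in pairwise_agreement(
            wide, w, alpha=config.alpha
        ):
            pair_rows.append(
                _estimate_row(
                    fid, "all", est, rater_a=a, rater_b=b, reason=reason,
                    weights_kind=config.weights_kind,
                )
            )

    overall = pd.DataFrame(overall_rows, columns=_EST_COLUMNS)
    by_stratum = pd.DataFrame(stratum_rows, columns=_EST_COLUMNS)
    pairwise = pd.DataFrame(pair_rows, columns=_EST_COLUMNS)

    comparison = None
    ref = config.reference_values
    if ref is not None:
        if isinstance(ref, str):
            if ref != "packaged":
                raise ValueError(
                    "reference_values must be a mapping or 'packaged'"
                )
            ref_df = load_reference_values()
            ref_map = dict(zip(ref_df["feature_id"], ref_df["coefficient"]))
        else:
            ref_map = dict(ref)
        comp_rows = []
        this = overall.set_index("feature_id")
        for fid in features:
            if fid not in ref_map:
                continue
            coef = this.loc[fid, "coefficient"]
            comp_rows.append(
                {
                    "feature_id": fid,
                    "reference_coefficient": float(ref_map[fid]),
                    "reference_band": interpret_band(ref_map[fid]),
                    "this_study_coefficient": float(coef),
                    "this_study_band": interpret_band(coef),
                }
            )
        comparison = pd.DataFrame(comp_rows)

    n_by_stratum = {
        s: int((group_of == s).sum()) for s in strata
    }
    metadata = {
        "weights_kind": config.weights_kind,
        "unit_of_analysis": config.unit_of_analysis,
        "n_units": int(len(group_of)),
        "n_units_by_stratum": n_by_stratum,
        "raters": raters,
        "features": features,
        "plugging_binary": config.plugging_binary,
        "alpha": config.alpha,
    }
    return StudyReport(overall, by_stratum, pairwise, comparison, metadata)


def _forest_lines(df: pd.DataFrame, title: str) -> list[str]:
    width = 50  # columns spanning [0, 1]; reference line at 0.6
    ref_col = int(round(0.6 * width))
    lines = [title, "-" * len(title)]
    axis = [" "] * (width + 1)
    axis[0], axis[width // 2], axis[width] = "0", ".5", "1"
    lines.append(" " * 26 + "".join(axis))

    def col(x: float) -> int:
        return int(round(min(max(x, 0.0), 1.0) * width))

    for _, row in df.iterrows():
        label = f"{row['feature_id']:<24.24}"
        if row.get("reason") and not np.isfinite(row["coefficient"]):
            lines.append(f"{label}  [absent: {row['reason']}]")
            continue
        track = [" "] * (width + 1)
        track[ref_col] = "|"
        lo, hi = row["ci_low"], row["ci_high"]
        if np.isfinite(lo) and np.isfinite(hi):
            for c in range(col(lo), col(hi) + 1):
                if track[c] == " ":
                    track[c] = "-"
        track[col(row["coefficient"])] = "*"
        lines.append(
            f"{label}  {''.join(track)}  "
            f"{row['coefficient']:.2f} ({lo:.2f}, {hi:.2f}) {row['band']}"
        )
    lines.append("")
    return lines


def render_report(report: StudyReport, outdir) -> dict:
    """Write CSV, JSON and a text forest summary; returns the paths.

    Output is a deterministic function of the report: stable row order and
    fixed float formatting.  Empty sections are omitted, not emitted as
    empty tables.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sections = [("overall", report.overall), ("by_stratum", report.by_stratum)]
    if len(report.pairwise):
        sections.append(("pairwise", report.pairwise))
    tidy = pd.concat(
        [df.assign(section=name) for name, df in sections if len(df)],
        ignore_index=True,
    )[["section"] + _EST_COLUMNS]
    csv_path = outdir / "agreement.csv"
    tidy.to_csv(csv_path, index=False, float_format="%.10g")

    json_path = outdir / "report.json"
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(report.to_json_dict(), fh, indent=1)
        fh.write("\n")

    lines = _forest_lines(
        report.overall,
        f"Inter-rater agreement, all raters "
        f"({report.metadata.get('weights_kind', '?')} weights; "
        f"'|' marks 0.6)",
    )
    for stratum in report.by_stratum["stratum"].unique():
        sub = report.by_stratum[report.by_stratum["stratum"] == stratum]
        lines += _forest_lines(sub, f"Stratum: {stratum}")
    forest_path = outdir / "forest.txt"
    forest_path.write_text("\n".join(lines), encoding="utf-8")

    paths = {"csv": csv_path, "json": json_path, "forest": forest_path}
    if report.comparison is not None and len(report.comparison):
        comp_path = outdir / "comparison.csv"
        report.comparison.to_csv(
            comp_path, index=False, float_format="%.10g"
        )
        paths["comparison"] = comp_path
    return paths


def plot_forest(report: StudyReport, path) -> None:
    """Optional graphical forest plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.overall.iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(df) + 1.5))
    y = np.arange(len(df))
    ax.errorbar(
        df["coefficient"], y,
        xerr=[
            df["coefficient"] - df["ci_low"],
            df["ci_high"] - df["coefficient"],
        ],
        fmt="o", color="black", capsize=3,
    )
    ax.axvline(0.6, linestyle="--", color="grey")
    ax.set_yticks(y, df["feature_id"])
    ax.set_xlabel("Agreement coefficient (95% CI)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
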