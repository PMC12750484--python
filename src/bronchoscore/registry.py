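"""Feature registry for the modified pediatric bronchoscopy score.

The instrument rates ten visual airway features, each scored per lobe on an
ordinal scale from 0 to a feature-specific maximum, in five bronchial
territories (right upper/middle/lower, left upper/lower).  Six features come
from the earlier pediatric bronchitis score (secretion colour and amount,
mucosal edema, ridging, erythema, pallor); four are CF-specific additions
(secretion viscosity, bleeding, vascular drawing, mucus plugging).

Per-recording composites are formed either by the 50%-of-lobes threshold
algorithm (most features) or by the maximum across lobes (secretion colour,
on the 0-8 Murray sputum colour chart).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Mapping, Optional, Sequence

import yaml

#: Canonical lobe codes: right upper, right middle, right lower, left upper,
#: left lower.  The lingula and trachea are not scored.
LOBES: tuple[str, ...] = ("RUL", "RML", "RLL", "LUL", "LLL")

#: Subject group labels recognised in ratings tables.
GROUPS: tuple[str, ...] = ("CF", "nonCF", "other")


class Aggregation(str, Enum):
    """How per-lobe scores are collapsed into a per-recording composite."""

    THRESHOLD = "threshold"
    MAXIMUM = "maximum"


@dataclass(frozen=True)
class FeatureDefinition:
    """One scored visual feature: its per-lobe scale and aggregation rule.

    Parameters
    ----------
    feature_id
        Short machine identifier, e.g. ``"mucus_plugging"``.
    display_name
        Human-readable name used in reports.
    per_lobe_max
        Maximum per-lobe ordinal score (scale is ``0..per_lobe_max``).
    aggregation
        ``threshold`` for the 50%-of-lobes rule, ``maximum`` for the
        max-across-lobes rule.
    level_labels
        Optional ordered labels, one per scale level (``per_lobe_max + 1``
        entries).
    """

    feature_id: str
    display_name: str
    per_lobe_max: int
    aggregation: Aggregation
    level_labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.per_lobe_max < 1:
            raise ValueError(
                f"{self.feature_id}: per_lobe_max must be >= 1, "
                f"got {self.per_lobe_max}"
            )
        if self.level_labels is not None:
            expected = self.per_lobe_max + 1
            if len(self.level_labels) != expected:
                raise ValueError(
                    f"{self.feature_id}: expected {expected} level labels, "
                    f"got {len(self.level_labels)}"
                )
        # normalise string -> enum so YAML round-trips cleanly
        if not isinstance(self.aggregation, Aggregation):
            object.__setattr__(self, "aggregation", Aggregation(self.aggregation))

    @property
    def composite_max(self) -> int:
        """Largest attainable composite score.

        The threshold rule can promote one level past the per-lobe maximum
        (majority of lobes at the top level), so its range is
        ``0..per_lobe_max + 1``; the maximum rule stays on the per-lobe scale.
        """
        if self.aggregation is Aggregation.THRESHOLD:
            return self.per_lobe_max + 1
        return self.per_lobe_max

    def n_composite_categories(self, *, plugging_binary: bool = False) -> int:
        """Number of composite categories (the agreement category space *q*).

        The category space is the instrument's full theoretical composite
        range, not merely the categories observed in a sample.
        """
        if plugging_binary and self.feature_id == "mucus_plugging":
            return 2
        return self.composite_max + 1


_MILD_MODERATE = ("normal", "mild", "moderate-severe")

_DEFAULT_FEATURES: tuple[FeatureDefinition, ...] = (
    FeatureDefinition(
        "secretion_color", "Secretion color", 8, Aggregation.MAXIMUM
    ),
    FeatureDefinition(
        "secretion_amount", "Secretion amount", 3, Aggregation.THRESHOLD
    ),
    FeatureDefinition(
        "mucosal_edema", "Mucosal edema", 2, Aggregation.THRESHOLD,
        _MILD_MODERATE,
    ),
    FeatureDefinition(
        "mucosal_ridging", "Mucosal ridging", 2, Aggregation.THRESHOLD,
        _MILD_MODERATE,
    ),
    FeatureDefinition(
        "erythema", "Erythema", 2, Aggregation.THRESHOLD, _MILD_MODERATE
    ),
    FeatureDefinition(
        "mucosal_pallor", "Mucosal pallor", 2, Aggregation.THRESHOLD,
        _MILD_MODERATE,
    ),
    FeatureDefinition(
        "viscosity", "Viscosity of secretion", 2, Aggregation.THRESHOLD,
        ("normal (watery)", "loose (moves with suction)",
         "viscous (thick, tenacious mucus)"),
    ),
    FeatureDefinition(
        "bleeding", "Bleeding", 2, Aggregation.THRESHOLD,
        ("none", "after manipulation", "spontaneously"),
    ),
    FeatureDefinition(
        "vascular_drawing", "Vascular drawing", 2, Aggregation.THRESHOLD,
        ("normal (faint submucosal vessels)",
         "light (prominent submucosal vessels)",
         "severe (engorged vascular pattern)"),
    ),
    FeatureDefinition(
        "mucus_plugging", "Mucus plugging", 1, Aggregation.THRESHOLD,
        ("no plugging", "present (obstruction)"),
    ),
)


class FeatureRegistry(Mapping[str, FeatureDefinition]):
    """Ordered mapping ``feature_id -> FeatureDefinition``."""

    def __init__(self, features: Sequence[FeatureDefinition]):
        ids = [f.feature_id for f in features]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature_id in registry")
        self._features: dict[str, FeatureDefinition] = {
            f.feature_id: f for f in features
        }

    def __getitem__(self, feature_id: str) -> FeatureDefinition:
        try:
            return self._features[feature_id]
        except KeyError:
            raise KeyError(f"unknown feature_id: {feature_id!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._features)

    def __len__(self) -> int:
        return len(self._features)

    @property
    def feature_ids(self) -> list[str]:
        return list(self._features)

    def to_dict(self) -> list[dict]:
        out = []
        for f in self._features.values():
            d = {
                "feature_id": f.feature_id,
                "display_name": f.display_name,
                "per_lobe_max": f.per_lobe_max,
                "aggregation": f.aggregation.value,
            }
            if f.level_labels is not None:
                d["level_labels"] = list(f.level_labels)
            out.append(d)
        return out

    @classmethod
    def from_dict(cls, items: Sequence[dict]) -> "FeatureRegistry":
        feats = []
        for d in items:
            labels = d.get("level_labels")
            feats.append(
                FeatureDefinition(
                    feature_id=d["feature_id"],
                    display_name=d.get("display_name", d["feature_id"]),
                    per_lobe_max=int(d["per_lobe_max"]),
                    aggregation=Aggregation(d["aggregation"]),
                    level_labels=tuple(labels) if labels else None,
                )
            )
        return cls(feats)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"features": self.to_dict()}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureRegistry":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data["features"])


def default_registry() -> FeatureRegistry:
    """The canonical ten-feature registry of the modified score."""
    return FeatureRegistry(_DEFAULT_FEATURES)
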