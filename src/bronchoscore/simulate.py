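"""Synthetic multi-rater bronchoscopy rating studies.

The generative model is a latent-trait ordinal model: each subject carries a
feature-specific latent severity, each lobe perturbs it, each rater observes
it through an additive bias and Gaussian noise, and ordered cutpoints
discretize the observation into the per-lobe ordinal score:

    theta_if  ~ Normal(mu_group(f), severity_sd)        subject severity
    x_ifl     = theta_if + Normal(0, lobe_sd)           lobe-level variation
    y_ifjl    = x_ifl + bias_j + Normal(0, noise_sd_j)  rater observation
    score     = #{cutpoints below y_ifjl}

Rater agreement is controlled by ``noise_sd`` and ``bias`` (zero noise and
bias make raters identical); marginal imbalance is controlled by where the
cutpoints sit relative to the severity means — cutpoints well above the mean
give the rare-finding regime where most scores are 0, the situation in which
prevalence-sensitive coefficients such as kappa become paradoxical.

Defaults emulate an 80-recording study (62.5% CF), rated by four raters of
mixed experience (one noisier trainee, three experts), on the ten-feature
registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .registry import LOBES, FeatureRegistry, default_registry


@dataclass(frozen=True)
class RaterSpec:
    """One simulated rater: additive bias and observation noise."""

    rater_id: str
    bias: float = 0.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"{self.rater_id}: noise_sd must be >= 0")


@dataclass(frozen=True)
class FeatureSim:
    """Latent-to-ordinal mapping for one simulated feature.

    ``cutpoints`` are strictly increasing with length ``per_lobe_max``; a
    latent observation above the j-th cutpoint scores at least j+1.
    ``mu_cf`` / ``mu_noncf`` shift the severity distribution per group.
    """

    feature_id: str
    per_lobe_max: int
    cutpoints: tuple[float, ...]
    mu_cf: float = 0.0
    mu_noncf: float = 0.0

    def __post_init__(self) -> None:
        cp = tuple(float(c) for c in self.cutpoints)
        if len(cp) != self.per_lobe_max:
            raise ValueError(
                f"{self.feature_id}: need {self.per_lobe_max} cutpoints, "
                f"got {len(cp)}"
            )
        if any(b <= a for a, b in zip(cp, cp[1:])):
            raise ValueError(
                f"{self.feature_id}: cutpoints must be strictly increasing"
            )
        object.__setattr__(self, "cutpoints", cp)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic rater study.  Seed is mandatory."""

    n_subjects: int
    raters: tuple[RaterSpec, ...]
    features: tuple[FeatureSim, ...]
    seed: int
    group_split: float = 0.625  # fraction CF
    severity_sd: float = 1.0
    lobe_sd: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.group_split <= 1.0:
            raise ValueError("group_split must be in [0, 1]")
        if self.severity_sd < 0 or self.lobe_sd < 0:
            raise ValueError("severity_sd and lobe_sd must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        object.__setattr__(self, "raters", tuple(self.raters))
        object.__setattr__(self, "features", tuple(self.features))

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


# Default latent means: secretion-related findings are more pronounced in CF
# airways; mucosal findings shift less.  Cutpoints sit above the population
# mean so that 0 dominates the marginals (rare-finding regime).
_SECRETION = {"secretion_color", "secretion_amount", "viscosity",
              "mucus_plugging"}


def _default_feature_sims(
    registry: FeatureRegistry,
) -> tuple[FeatureSim, ...]:
    sims = []
    for fid in registry.feature_ids:
        feat = registry[fid]
        L = feat.per_lobe_max
        if L == 1:
            cut = (1.5,)
        elif L == 2:
            cut = (1.0, 2.2)
        elif L == 3:
            cut = (0.8, 1.8, 2.8)
        else:
            cut = tuple(np.round(np.linspace(0.2, 3.0, L), 6))
        mu_cf = 1.0 if fid in _SECRETION else 0.5
        sims.append(
            FeatureSim(fid, L, cut, mu_cf=mu_cf, mu_noncf=0.0)
        )
    return tuple(sims)


def default_raters() -> tuple[RaterSpec, ...]:
    """Four raters of mixed experience: one trainee, three experts."""
    return (
        RaterSpec("student", bias=0.3, noise_sd=0.8),
        RaterSpec("expert1", bias=0.0, noise_sd=0.5),
        RaterSpec("expert2", bias=-0.1, noise_sd=0.5),
        RaterSpec("expert3", bias=0.1, noise_sd=0.6),
    )


def default_config(
    seed: int,
    *,
    n_subjects: int = 80,
    registry: Optional[FeatureRegistry] = None,
) -> SimulationConfig:
    """Study-shaped default: 80 subjects (62.5% CF), 4 raters, 10 features."""
    registry = registry or default_registry()
    return SimulationConfig(
        n_subjects=n_subjects,
        raters=default_raters(),
        features=_default_feature_sims(registry),
        seed=seed,
    )


def simulate_ratings(config: SimulationConfig) -> pd.DataFrame:
    """Draw one study; returns the long ratings table.

    Columns: ``subject_id, group, rater_id, feature_id, lobe, score``.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    n_cf = int(round(n * config.group_split))
    width = max(3, len(str(n)))
    subjects = [f"s{i + 1:0{width}d}" for i in range(n)]
    groups = np.array(["CF"] * n_cf + ["nonCF"] * (n - n_cf))
    n_lobes = len(LOBES)

    frames = []
    for feat in config.features:
        mu = np.where(groups == "CF", feat.mu_cf, feat.mu_noncf)
        theta = mu + config.severity_sd * rng.standard_normal(n)
        x = theta[:, None] + config.lobe_sd * rng.standard_normal(
            (n, n_lobes)
        )
        cut = np.asarray(feat.cutpoints)
        for rater in config.raters:
            y = x + rater.bias
            if rater.noise_sd > 0:
                y = y + rater.noise_sd * rng.standard_normal((n, n_lobes))
            score = np.searchsorted(cut, y.ravel(), side="left").reshape(
                n, n_lobes
            )
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": np.repeat(subjects, n_lobes),
                        "group": np.repeat(groups, n_lobes),
                        "rater_id": rater.rater_id,
                        "feature_id": feat.feature_id,
                        "lobe": np.tile(LOBES, n),
                        "score": score.ravel(),
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out[["subject_id", "group", "rater_id", "feature_id", "lobe",
                "score"]]


def paradox_fixture() -> np.ndarray:
    """Two-rater binary cross table exhibiting the kappa prevalence paradox.

    Counts (rows rater 1, columns rater 2): [[90, 5], [4, 1]].  Percent
    agreement is 0.91 and AC1 about 0.90, yet Cohen's kappa is about 0.13 —
    the paradox that motivates prevalence-robust coefficients for findings
    with strongly imbalanced marginals.
    """
    return np.array([[90, 5], [4, 1]])
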