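"""Synthetic multi-theme country indicator tables with planted risk tiers.

The generator emulates the structure the analysis pipeline assumes: every
country belongs to a latent risk tier, and each theme's indicators are
Gaussian draws around tier-specific means.  Cross-theme concordance is
controlled explicitly — the first theme realizes the reference tier
exactly, while each other theme keeps the reference tier with probability
``1 - discordance`` and otherwise resamples it uniformly from the remaining
tiers.  The planted tiers are returned as ground truth, so cluster
recovery, worst-tier Jaccard, and elbow selection can all be scored
against a known answer.

Per-variable tier means are spaced ``tier_separation`` within-tier SDs
apart, signed by a severity direction flag (+1: the variable rises with
risk, -1: it falls), with base means and SDs drawn once per dataset from
broad uniform ranges on the scales typical of diet/health indicator
tables.  The exact ranges are module constants and are a modelling choice,
not a claim about any real data source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import IndicatorTable, ThemeSpec
from .errors import ConfigurationError

#: Base mean range for synthetic indicators (protein-like scales).
MEAN_RANGE: tuple[float, float] = (10.0, 70.0)
#: Within-tier SD range.
SD_RANGE: tuple[float, float] = (1.0, 8.0)

_DEFAULT_THEME_SPECS: tuple[tuple[str, int], ...] = (("NAD", 14), ("HAD", 8), ("HALE", 3))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    ``tier_separation`` is the distance between adjacent tier means in
    within-tier SD units; ``discordance`` is the probability that a
    non-reference theme's tier is resampled away from the reference tier.
    """

    n_countries: int
    n_tiers: int = 3
    theme_specs: tuple[tuple[str, int], ...] = _DEFAULT_THEME_SPECS
    tier_separation: float = 6.0
    discordance: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ConfigurationError(f"n_countries must be positive, got {self.n_countries}")
        if self.n_tiers < 2:
            raise ConfigurationError(f"n_tiers must be >= 2, got {self.n_tiers}")
        if not self.theme_specs:
            raise ConfigurationError("theme_specs must name at least one theme")
        for name, p in self.theme_specs:
            if p < 1:
                raise ConfigurationError(f"theme {name!r} needs >= 1 variable, got {p}")
        if self.tier_separation < 0:
            raise ConfigurationError(f"tier_separation must be >= 0, got {self.tier_separation}")
        if not 0.0 <= self.discordance <= 1.0:
            raise ConfigurationError(f"discordance must lie in [0, 1], got {self.discordance}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated table plus per-theme ground-truth tiers.

    ``true_tiers`` maps theme name -> country -> tier in 1..n_tiers (tier
    ``n_tiers`` is the highest-risk by convention); ``reference_tiers`` is
    the latent tier before per-theme discordance.  ``directions`` records
    each variable's severity direction for risk-ordering.
    """

    table: IndicatorTable
    true_tiers: Mapping[str, Mapping[str, int]]
    reference_tiers: Mapping[str, int]
    directions: Mapping[str, int]
    config: SyntheticConfig

    def worst_tier_set(self, theme: str) -> frozenset[str]:
        worst = self.config.n_tiers
        return frozenset(c for c, t in self.true_tiers[theme].items() if t == worst)

    def tiers_frame(self) -> pd.DataFrame:
        rows = [
            (c, theme, t)
            for theme, mapping in self.true_tiers.items()
            for c, t in sorted(mapping.items())
        ]
        return pd.DataFrame(rows, columns=["country", "theme", "tier"])

    def to_csv(self, table_path: str | Path, tiers_path: str | Path | None = None) -> None:
        """Emit the indicator CSV (and optionally the ground-truth sidecar)
        in the dialect the reader consumes."""
        out = self.table.values.copy()
        out.insert(0, "country", out.index)
        out.to_csv(table_path, index=False)
        if tiers_path is not None:
            self.tiers_frame().to_csv(tiers_path, index=False)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one synthetic dataset; deterministic given ``config.seed``.

    The dataset's pseudo-random stream is split into independent substreams
    for tier draws, per-variable means, observation noise, and masking, so
    e.g. toggling ``missing_rate`` never perturbs the planted tiers.
    """
    tier_rng, mean_rng, noise_rng, mask_rng = [
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(4)
    ]
    n, T = config.n_countries, config.n_tiers
    countries = [f"Country-{i:04d}" for i in range(1, n + 1)]

    reference = tier_rng.integers(1, T + 1, size=n)
    true_tiers: dict[str, dict[str, int]] = {}
    for t_index, (theme_name, _) in enumerate(config.theme_specs):
        if t_index == 0:
            realized = reference.copy()
        else:
            realized = reference.copy()
            flip = tier_rng.random(n) < config.discordance
            for i in np.flatnonzero(flip):
                others = [t for t in range(1, T + 1) if t != reference[i]]
                realized[i] = others[tier_rng.integers(len(others))]
        true_tiers[theme_name] = dict(zip(countries, (int(t) for t in realized)))

    themes: list[ThemeSpec] = []
    columns: dict[str, np.ndarray] = {}
    directions: dict[str, int] = {}
    for theme_name, p in config.theme_specs:
        var_names = tuple(f"{theme_name}_var{j:02d}" for j in range(1, p + 1))
        themes.append(ThemeSpec(theme_name, var_names))
        realized = np.array([true_tiers[theme_name][c] for c in countries])
        for var in var_names:
            base = mean_rng.uniform(*MEAN_RANGE)
            sigma = mean_rng.uniform(*SD_RANGE)
            direction = 1 if mean_rng.random() < 0.5 else -1
            directions[var] = direction
            # tier t mean: base + direction * (t - (T+1)/2) * separation * sigma
            offsets = direction * (realized - (T + 1) / 2.0) * config.tier_separation * sigma
            columns[var] = base + offsets + noise_rng.normal(0.0, sigma, size=n)

    values = pd.DataFrame(columns, index=pd.Index(countries, name="country"))
    if config.missing_rate > 0:
        mask = mask_rng.random(values.shape) < config.missing_rate
        values = values.mask(mask)
    table = IndicatorTable(values=values, themes=tuple(themes))
    return SyntheticDataset(
        table=table,
        true_tiers=true_tiers,
        reference_tiers=dict(zip(countries, (int(t) for t in reference))),
        directions=directions,
        config=config,
    )
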