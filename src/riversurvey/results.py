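"""Result containers shared by the line and strip estimators."""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


@dataclass(frozen=True)
class StratumEstimate:
    """Density/abundance estimate for one habitat (x stratum) cell.

    ``stratum`` is None when strata are pooled within habitat (the
    pre-survey habitat stratification without geographic post-stratification).
    CV fields are NaN where undefined (zero sightings, single transect).
    Abundance fields stay NaN until an area is applied.
    """

    habitat: str
    stratum: str | None
    protocol: str  # "line" | "strip"
    n_groups: int
    effort_km: float
    mean_group_size: float
    cv_group_size: float
    encounter_rate: float  # groups per km (uncorrected)
    cv_encounter_rate: float
    density: float  # individuals / km^2
    cv_density: float
    abundance: float = math.nan
    se_abundance: float = math.nan
    area_km2: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan

    @property
    def se_density(self) -> float:
        return self.density * self.cv_density

    @property
    def cv_abundance(self) -> float:
        # N = D * A with A known, so CV(N) = CV(D)
        return self.cv_density

    def with_abundance(self, abundance: float, se: float, area_km2: float) -> "StratumEstimate":
        return replace(self, abundance=abundance, se_abundance=se, area_km2=area_km2)

    def with_ci(self, low: float, high: float) -> "StratumEstimate":
        return replace(self, ci_low=low, ci_high=high)
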