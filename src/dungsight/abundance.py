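"""Convert dung (pellet-group) density into animal density and abundance.

A standing crop of pellet groups reflects accumulation and decay in steady
state: D_dung = D_animal * r * T, with r the defecation rate (pellet groups
per animal per day) and T the mean time to decay (days).  Inverting this
relation turns a fitted pellet-group density into an animal density, and
multiplying by the surveyed area gives abundance.  Uncertainty combines
the CVs of the three inputs assuming independence (lognormal delta
method), with a seeded parametric bootstrap as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ConversionRates", "dung_to_animal", "abundance"]


@dataclass(frozen=True)
class ConversionRates:
    """Defecation and decay parameters with optional uncertainty.

    ``decay_days`` defaults to the midpoint of a plausible arid-environment
    persistence range; when only a (lo, hi) range is known, use
    ``from_decay_range`` which treats the half-range as ±2 SE.
    """

    defecation_rate: float              # pellet groups / animal / day
    decay_days: float                   # mean persistence time
    defecation_se: float = 0.0
    decay_se: float = 0.0

    def __post_init__(self):
        if self.defecation_rate <= 0 or self.decay_days <= 0:
            raise ValueError("defecation and decay rates must be > 0")
        if self.defecation_se < 0 or self.decay_se < 0:
            raise ValueError("rate SEs must be >= 0")

    @classmethod
    def from_decay_range(cls, defecation_rate: float, decay_lo: float,
                         decay_hi: float, defecation_se: float = 0.0):
        mid = 0.5 * (decay_lo + decay_hi)
        half = 0.5 * (decay_hi - decay_lo)
        return cls(defecation_rate=defecation_rate, decay_days=mid,
                   defecation_se=defecation_se, decay_se=half / 2.0)


def dung_to_animal(dung_density: float, rates: ConversionRates) -> float:
    """Animal density from pellet-group density: D_animal = D_dung / (r T)."""
    if dung_density < 0:
        raise ValueError("dung density must be >= 0")
    return dung_density / (rates.defecation_rate * rates.decay_days)


def abundance(animal_density: float, area: float, *,
              density_cv: float = 0.0, rates: ConversionRates | None = None,
              level: float = 0.95, method: str = "delta",
              n_boot: int = 10_000, seed: int = 0) -> dict:
    """Abundance N = D * area with a confidence interval.

    ``density_cv`` is the CV of the (animal or dung) density estimate; rate
    CVs are taken from ``rates`` when provided.  ``method="delta"`` combines
    the squared CVs on the log scale assuming independence and returns a
    lognormal interval; ``method="bootstrap"`` resamples density and rates
    as independent lognormals (seeded) and returns percentile bounds.
    Density and area must share units (e.g. animals/km^2 and km^2).
    """
    if area <= 0:
        raise ValueError("area must be > 0")
    if animal_density < 0:
        raise ValueError("density must be >= 0")
    n_hat = animal_density * area
    cvs = [density_cv]
    if rates is not None:
        cvs.append(rates.defecation_se / rates.defecation_rate)
        cvs.append(rates.decay_se / rates.decay_days)
    cv2 = float(np.sum(np.square(cvs)))
    if n_hat == 0 or cv2 == 0:
        return {"n": n_hat, "ci_lo": n_hat, "ci_hi": n_hat, "cv": 0.0,
                "method": method}
    alpha = 1.0 - level
    if method == "delta":
        # lognormal interval: N / C, N * C with C = exp(z * sqrt(ln(1+cv^2)))
        sig = np.sqrt(np.log1p(cv2))
        c = np.exp(stats.norm.ppf(1.0 - alpha / 2.0) * sig)
        lo, hi = n_hat / c, n_hat * c
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = np.full(n_boot, n_hat, float)
        for cv in cvs:
            if cv > 0:
                sig = np.sqrt(np.log1p(cv ** 2))
                # mean-1 lognormal multiplier per independent error source
                draws *= rng.lognormal(-0.5 * sig ** 2, sig, n_boot)
        lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return {"n": n_hat, "ci_lo": float(lo), "ci_hi": float(hi),
            "cv": float(np.sqrt(cv2)), "method": method}
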