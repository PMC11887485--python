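"""Protonation-state fractions over pH and microspecies/response overlays.

Each ionizable site follows Henderson-Hasselbalch behavior: the
protonated fraction is 1/(1 + 10^(pH - pKa)) for both acid (HA <-> A-)
and base (BH+ <-> B) sites.  Multi-site molecules are treated with an
independent-site approximation: a microspecies (one protonation
microstate) gets the product of its per-site fractions, so fractions
sum to 1 at every pH.  Site coupling is ignored; pKa values are inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .sar import CorrelationResult, pearson_correlation

__all__ = [
    "ProtonationSite",
    "MicrospeciesProfile",
    "fraction_protonated",
    "microspecies_profile",
    "overlay_transition",
    "DEFAULT_PH_GRID",
]

#: Default grid covering the experimental range, pH 2-13 in 0.1 steps.
DEFAULT_PH_GRID = np.round(np.arange(2.0, 13.0 + 1e-9, 0.1), 10)


@dataclass(frozen=True)
class ProtonationSite:
    """One ionizable site with its pKa and acid/base class."""

    site_id: str
    pKa: float
    site_class: str = "base"  # acid (HA<->A-) | base (BH+<->B)

    def __post_init__(self) -> None:
        if not np.isfinite(self.pKa):
            raise ValueError(f"pKa for site {self.site_id!r} must be finite")
        if self.site_class not in ("acid", "base"):
            raise ValueError(f"unknown site class {self.site_class!r}")


@dataclass(frozen=True)
class MicrospeciesProfile:
    """Per-microspecies fractions evaluated on a pH grid.

    ``states[k]`` is a tuple of protonation flags, one per site, in the
    order the sites were given; ``fractions[k]`` the matching curve.
    """

    pH_grid: np.ndarray
    states: tuple[tuple[bool, ...], ...]
    fractions: np.ndarray  # shape (n_states, n_pH)

    def fraction(self, index: int) -> np.ndarray:
        return self.fractions[index]


def fraction_protonated(site: ProtonationSite, pH) -> np.ndarray | float:
    """Henderson-Hasselbalch protonated fraction at the given pH.

    For a base site this is the BH+ fraction; for an acid site, HA.
    """
    pH = np.asarray(pH, dtype=float)
    if not np.isfinite(pH).all():
        raise ValueError("pH must be finite")
    frac = 1.0 / (1.0 + 10.0 ** (pH - site.pKa))
    return float(frac) if frac.ndim == 0 else frac


def microspecies_profile(
    sites: list[ProtonationSite],
    pH_grid=DEFAULT_PH_GRID,
) -> MicrospeciesProfile:
    """Independent-site microspecies fractions on a pH grid.

    Each of the 2^k microstates gets the product of per-site fractions
    (protonated or deprotonated); columns sum to 1 by construction.
    """
    if not sites:
        raise ValueError("need at least one protonation site")
    if len(sites) > 12:
        raise ValueError(f"{len(sites)} sites would give 2^{len(sites)} microstates")
    grid = np.asarray(pH_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("pH grid is empty")
    prot = np.vstack([fraction_protonated(s, grid) for s in sites])  # (k, n)
    states = tuple(itertools.product((True, False), repeat=len(sites)))
    fractions = np.empty((len(states), grid.size))
    for k, state in enumerate(states):
        f = np.ones(grid.size)
        for sfrac, is_prot in zip(prot, state):
            f = f * (sfrac if is_prot else 1.0 - sfrac)
        fractions[k] = f
    return MicrospeciesProfile(pH_grid=grid, states=states, fractions=fractions)


def overlay_transition(
    response_vs_pH,
    profile: MicrospeciesProfile,
    microspecies_index: int,
) -> CorrelationResult:
    """Correlate dF(pH) data with one microspecies fraction curve.

    ``response_vs_pH`` is a sequence of (pH, dF) pairs.  The selected
    microspecies curve is linearly interpolated onto the measured pH
    values and the Pearson correlation across pH is returned.  A flat
    response (zero variance) is reported as non-correlatable via the
    underlying error.
    """
    pairs = np.asarray(response_vs_pH, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("response_vs_pH must be (pH, dF) pairs")
    lo, hi = profile.pH_grid[0], profile.pH_grid[-1]
    inside = (pairs[:, 0] >= lo) & (pairs[:, 0] <= hi)
    pairs = pairs[inside]
    if pairs.shape[0] < 3:
        raise ValueError(
            f"only {pairs.shape[0]} pH points overlap the profile grid; need >= 3"
        )
    frac = np.interp(pairs[:, 0], profile.pH_grid, profile.fraction(microspecies_index))
    return pearson_correlation(frac, pairs[:, 1])
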