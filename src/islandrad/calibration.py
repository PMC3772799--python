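"""Molecular-clock calibrations from island ages and COI divergence rates.

Hotspot archipelagos offer two independent routes to calibrating a clock
without fossils.  Island calibrations place a normal prior on the age of a
node whose daughter taxa straddle an old-island/young-island split, with the
mean at the younger island's emergence (end of shield building).  Rate
calibrations derive a COI divergence rate from uncorrected p-distances
between taxon pairs split across an island pair of known age: outlying pairs
are excluded, the retained distances averaged, and the average divided by
the island age.  A pairwise divergence rate of r %/my corresponds to a
per-lineage substitution rate of r/2/100 substitutions/site/my — the mean of
a normal prior on the relaxed-clock mean-rate parameter (ucld.mean).

This module builds those priors as declarative documents; it does not run
any dating engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DivergencePair",
    "RateEstimate",
    "CalibrationPrior",
    "p_distance",
    "derive_rate",
    "rate_to_clock_prior",
    "island_calibration",
    "priors_to_json",
]

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class DivergencePair:
    """One taxon pair with its uncorrected pairwise divergence."""

    pair_id: str
    id1: str
    id2: str
    p_distance: float
    islands: tuple[str, str] | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_distance <= 1.0):
            raise ValueError("p-distance must lie in [0, 1]")


@dataclass(frozen=True)
class RateEstimate:
    """Divergence rate derived from taxon pairs over a calibration age T.

    ``rate_pct_per_my = 100 * mean_divergence / T`` (pairwise scale) and
    ``per_lineage_rate = rate_pct_per_my / 2 / 100`` (substitutions/site/my).
    """

    pairs: tuple[DivergencePair, ...]
    retained: np.ndarray = field(repr=False)  # boolean mask, True = kept
    mean_divergence: float
    calibration_age_my: float
    rate_pct_per_my: float
    per_lineage_rate: float
    outlier_rule: str


@dataclass(frozen=True)
class CalibrationPrior:
    """A normal prior on a node age (my) or clock-rate parameter."""

    target: str
    mean: float
    sd: float
    units: str
    family: str = "normal"

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("prior SD must be positive")

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "family": self.family,
            "mean": self.mean,
            "sd": self.sd,
            "units": self.units,
        }


def p_distance(seq1: str, seq2: str, *, pairwise_deletion: bool = True) -> float:
    """Uncorrected proportion of differing sites between two aligned sequences.

    With ``pairwise_deletion`` (default) any column where either sequence has
    a gap or ambiguity code (anything outside A/C/G/T) is dropped before
    counting; otherwise only columns where both are unambiguous bases or both
    are gaps are tolerated and gaps are treated as a fifth state.
    """
    s1, s2 = seq1.upper(), seq2.upper()
    if len(s1) != len(s2):
        raise ValueError("sequences must be aligned to equal length")
    mismatches = 0
    compared = 0
    for a, b in zip(s1, s2):
        if pairwise_deletion and (a not in _UNAMBIGUOUS or b not in _UNAMBIGUOUS):
            continue
        compared += 1
        if a != b:
            mismatches += 1
    if compared == 0:
        raise ValueError("no comparable sites between the two sequences")
    return mismatches / compared


def _outlier_mask(values: np.ndarray, rule: str) -> np.ndarray:
    """True where a value is retained under the exclusion rule."""
    if rule == "none":
        return np.ones(len(values), dtype=bool)
    if rule == "iqr":
        q1, q3 = np.quantile(values, [0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        return (values >= lo) & (values <= hi)
    if rule == "zscore":
        sd = values.std(ddof=1) if len(values) > 1 else 0.0
        if sd == 0:
            return np.ones(len(values), dtype=bool)
        z = np.abs(values - values.mean()) / sd
        return z <= 2.0
    raise ValueError(f"unknown outlier rule {rule!r}")


def derive_rate(
    pairs: list[DivergencePair],
    T: float,
    *,
    outlier_rule: str = "iqr",
) -> RateEstimate:
    """Average retained pairwise divergences and divide by the island age T.

    ``outlier_rule`` is ``"iqr"`` (Tukey fences at 1.5 x IQR, default),
    ``"zscore"`` (exclude |z| > 2) or ``"none"``.  The retained mask is part
    of the result so exclusions are auditable.
    """
    if T <= 0:
        raise ValueError("calibration age T must be positive")
    if not pairs:
        raise ValueError("at least one divergence pair is required")
    values = np.array([p.p_distance for p in pairs], dtype=float)
    mask = _outlier_mask(values, outlier_rule)
    if not mask.any():
        raise ValueError("all pairs excluded as outliers")
    mean_div = float(values[mask].mean())
    rate = 100.0 * mean_div / T
    return RateEstimate(
        pairs=tuple(pairs),
        retained=mask,
        mean_divergence=mean_div,
        calibration_age_my=float(T),
        rate_pct_per_my=rate,
        per_lineage_rate=rate / 2.0 / 100.0,
        outlier_rule=outlier_rule,
    )


def rate_to_clock_prior(
    rate_pct_per_my: float,
    sd: float,
    *,
    target: str = "ucld.mean",
) -> CalibrationPrior:
    """Convert a pairwise divergence rate (%/my) into a clock-rate prior.

    Pairwise divergence accumulates along two lineages, so the per-lineage
    substitution rate is half the pairwise rate; the percentage is also
    rescaled to a proportion: mean = rate / 2 / 100 substitutions/site/my.
    """
    if rate_pct_per_my <= 0:
        raise ValueError("divergence rate must be positive")
    return CalibrationPrior(
        target=target,
        mean=rate_pct_per_my / 2.0 / 100.0,
        sd=sd,
        units="subst/site/my",
    )


def island_calibration(node: str, island_age: float, sd: float) -> CalibrationPrior:
    """Normal prior on a node age, centred on an island's emergence age."""
    if island_age <= 0:
        raise ValueError("island age must be positive")
    return CalibrationPrior(target=node, mean=island_age, sd=sd, units="my")


def priors_to_json(priors: list[CalibrationPrior], *, indent: int = 2) -> str:
    """Serialize a calibration scheme as a declarative JSON document."""
    return json.dumps({"priors": [p.to_dict() for p in priors]}, indent=indent)
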