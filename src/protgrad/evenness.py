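"""Modified Shannon evenness of protection along a gradient.

Given the per-class values x_j of one protection measure along a gradient
histogram (either FRAC_PROT, diagnosing *fraction* representativeness, or
AREA_PROT, diagnosing *quota* representativeness), the index is

    V_j = x_j / Σ_j x_j                    (normalized shares)
    H   = Σ_j V_j · ln V_j                 (raw Shannon sum, ≤ 0)
    H'  = H / (n · min_j V_j · ln V_j)     (normalized index)

with n the number of (nonempty) histogram classes used. Both H and the
denominator are negative, so H' lies in [0, 1]; H' = 1 when x is constant
along the gradient — a perfectly even protection profile — and H' → 0 as
protection concentrates into a single class.

Conventions: 0·ln 0 := 0, and zero-share classes are excluded from the min
term (otherwise any class without protection would force the denominator to
0 and degenerate the index). If a single class holds all mass, H' := 0, the
continuity limit of vanishing mass elsewhere.

Note one quirk inherited from the normalization: the index returns exactly 1
for any vector whose nonzero shares all have the same value of V·ln V, e.g.
(0.5, 0.25, 0.25) — the function V ln V is not injective on (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import DegenerateDataError
from .histograms import Histogram

FRAC_PROT = "FRAC_PROT"
AREA_PROT = "AREA_PROT"


@dataclass(frozen=True)
class EvennessResult:
    measure: str
    x: np.ndarray           # input vector
    v: np.ndarray           # normalized shares, sum to 1
    h: float                # raw Shannon sum, <= 0
    h_prime: float          # normalized index in [0, 1]
    n: int                  # number of classes used


def normalize_shares(x) -> np.ndarray:
    """Transform a nonnegative vector into shares V_j = x_j / Σ x."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DegenerateDataError("need a 1-D vector of length >= 2")
    if not np.isfinite(x).all():
        raise DegenerateDataError("non-finite entries in input vector")
    if (x < 0).any():
        raise DegenerateDataError("negative entries are not admissible shares")
    total = x.sum()
    if total <= 0:
        raise DegenerateDataError("no protection along gradient (all entries zero)")
    return x / total


def evenness(x, measure: str = FRAC_PROT) -> EvennessResult:
    """Modified Shannon evenness H' of a nonnegative vector."""
    x = np.asarray(x, dtype=float)
    v = normalize_shares(x)
    n = v.size
    nz = v > 0
    terms = v[nz] * np.log(v[nz])      # 0·ln 0 := 0 handled by exclusion
    h = float(terms.sum())
    if nz.sum() == 1:
        h_prime = 0.0                   # total concentration convention
    else:
        h_prime = float(h / (n * terms.min()))
    h_prime = min(max(h_prime, 0.0), 1.0)  # guard FP overshoot only
    return EvennessResult(measure=measure, x=x, v=v, h=h, h_prime=h_prime, n=n)


class RepresentativenessComparison(NamedTuple):
    h_prime_fraction: float
    h_prime_quota: float
    ratio: float | None     # fraction / quota; None when quota evenness is 0


def compare_representativeness(histogram: Histogram) -> RepresentativenessComparison:
    """H' of FRAC_PROT vs H' of AREA_PROT over the nonempty classes of one histogram.

    The ratio > 1 means protection tracks a constant *fraction* of each
    environment more closely than a constant absolute *area* per environment.
    """
    classes = histogram.nonempty
    if len(classes) < 2:
        raise DegenerateDataError(
            f"histogram {histogram.variable}/{histogram.region} has fewer than 2 nonempty classes"
        )
    frac = np.array([c.frac_prot for c in classes])
    quota = np.array([c.area_prot for c in classes])
    h_frac = evenness(frac, measure=FRAC_PROT).h_prime
    h_quota = evenness(quota, measure=AREA_PROT).h_prime
    ratio = h_frac / h_quota if h_quota > 0 else None
    return RepresentativenessComparison(h_frac, h_quota, ratio)
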