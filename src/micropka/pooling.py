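"""Multi-instance pooling of per-atom micro-pKa into macro-pKa.

A molecule is a bag whose instances are its ionizable atoms.  The bag-level
(macro) value is tied to the instance-level (micro) values by the exact
algebra of competing ionizations:

* most-acidic:  pKa = -log10( sum_i 10^(-pKa_i) )  over acidic sites P
* most-basic:   pKa =  log10( sum_i 10^(+pKa_i) )  over basic sites Q

Non-site atoms are masked to +inf (acidic) or -inf (basic), i.e. they
contribute 10^(-inf) = 0 to the sum; we implement the mask as exclusion from
the sum, which is mathematically identical and keeps gradients clean.  The
sums are computed with a shifted-exponent (log-sum-exp) scheme so that any
micro value a model can emit pools without overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "MicroPkaVector",
    "MacroPka",
    "NO_SITE",
    "apply_mask",
    "pool_acidic",
    "pool_basic",
    "pool",
    "duality_check",
]

_LN10 = np.log(10.0)

#: Sentinel macro value for molecules without any site of the given mode.
NO_SITE = "no-site"


@dataclass(frozen=True)
class MicroPkaVector:
    """Per-atom micro-pKa values with the mode's site mask applied.

    ``values`` is aligned to graph atom order; entries outside ``sites``
    are +inf (acidic) / -inf (basic) and contribute nothing downstream.
    """

    values: np.ndarray
    mode: str
    sites: frozenset

    @property
    def site_values(self) -> np.ndarray:
        idx = sorted(self.sites)
        return self.values[idx]


@dataclass(frozen=True)
class MacroPka:
    """Pooled molecule-level pKa; ``value`` is NO_SITE for empty bags."""

    value: object  # float or NO_SITE
    mode: str
    contributing_sites: frozenset

    @property
    def is_defined(self) -> bool:
        return self.value is not NO_SITE


def apply_mask(raw: Sequence[float], sites: Iterable[int], mode: str) -> MicroPkaVector:
    """Mask non-site atoms of a raw per-atom prediction vector.

    Site atoms keep their raw value; the rest are set to the mode's
    absorbing element (+inf acidic, -inf basic).
    """
    raw = np.asarray(raw, dtype=np.float64)
    sites = frozenset(int(i) for i in sites)
    n = raw.shape[0]
    for i in sites:
        if not 0 <= i < n:
            raise IndexError(f"site index {i} out of range for {n} atoms")
    fill = np.inf if mode == "acidic" else -np.inf
    if mode not in ("acidic", "basic"):
        raise ValueError(f"mode must be 'acidic' or 'basic', got {mode!r}")
    values = np.full(n, fill, dtype=np.float64)
    idx = sorted(sites)
    values[idx] = raw[idx]
    return MicroPkaVector(values=values, mode=mode, sites=sites)


def _stable_neg_log10_sum_pow10(neg_x: np.ndarray) -> float:
    # log10( sum 10^neg_x ) via max-shift; neg_x finite, non-empty
    m = neg_x.max()
    return float(m + np.log1p(np.sum(np.exp(_LN10 * (neg_x - m))) - 1.0) / _LN10)


def pool_acidic(masked: MicroPkaVector) -> MacroPka:
    """Most-acidic macro-pKa: ``-log10 sum_{i in P} 10^(-pKa_i)``.

    Equals the smallest micro value minus a crowding term; for an empty
    site set the macro value is undefined and NO_SITE is returned.
    """
    if masked.mode != "acidic":
        raise ValueError("pool_acidic requires an acidic-mode vector")
    if not masked.sites:
        return MacroPka(NO_SITE, "acidic", frozenset())
    v = masked.site_values
    val = -_stable_neg_log10_sum_pow10(-v)
    return MacroPka(val, "acidic", masked.sites)


def pool_basic(masked: MicroPkaVector) -> MacroPka:
    """Most-basic macro-pKa: ``log10 sum_{i in Q} 10^(pKa_i)``."""
    if masked.mode != "basic":
        raise ValueError("pool_basic requires a basic-mode vector")
    if not masked.sites:
        return MacroPka(NO_SITE, "basic", frozenset())
    v = masked.site_values
    val = _stable_neg_log10_sum_pow10(v)
    return MacroPka(val, "basic", masked.sites)


def pool(masked: MicroPkaVector) -> MacroPka:
    return pool_acidic(masked) if masked.mode == "acidic" else pool_basic(masked)


def pool_values(values: Sequence[float], mode: str) -> Optional[float]:
    """Pool a bare list of site micro values; None when the list is empty."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        return None
    if mode == "acidic":
        return -_stable_neg_log10_sum_pow10(-values)
    if mode == "basic":
        return _stable_neg_log10_sum_pow10(values)
    raise ValueError(f"mode must be 'acidic' or 'basic', got {mode!r}")


def duality_check(v: Sequence[float], tol: float = 1e-9) -> bool:
    """Regression guard for the sign convention.

    The two pooling formulas are mirror images: pooling ``v`` in basic mode
    must equal the negation of pooling ``-v`` in acidic mode.  Empty input
    is vacuously consistent (both sides are NO_SITE).
    """
    v = np.asarray(v, dtype=np.float64)
    n = v.shape[0]
    sites = frozenset(range(n))
    b = pool_basic(MicroPkaVector(v, "basic", sites))
    a = pool_acidic(MicroPkaVector(-v, "acidic", sites))
    if not b.is_defined and not a.is_defined:
        return True
    return abs(b.value - (-a.value)) <= tol
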