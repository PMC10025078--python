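"""Hill numbers, relative logarithmic evenness (RLE), and Shannon cover diversity.

The Hill number of order q is the effective number of species: q = 0 counts
species regardless of abundance, q = 1 is the exponential of Shannon entropy,
and q = 2 the inverse Simpson concentration, progressively down-weighting
rare species. Relative logarithmic evenness of orders 0 and 2,
RLE_{0,2} = ln(2D) / ln(0D), equals 1 for a perfectly even community and
approaches 1/0D under single-species dominance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HillProfile",
    "hill_number",
    "rle02",
    "classify_evenness",
    "shannon_cover",
    "hill_profile",
    "evenness_table",
]

EVEN_THRESHOLD = 0.65  # RLE >= this: even community
DOMINATED_THRESHOLD = 0.45  # RLE <= this: dominated community


class EmptyCommunityError(ValueError):
    pass


class UndefinedEvennessError(ValueError):
    """RLE is undefined for single-species communities (ln 0D = 0)."""


def _relative(densities) -> np.ndarray:
    p = np.asarray(densities, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D density vector")
    if np.any(p < 0):
        raise ValueError("densities must be non-negative")
    total = p.sum()
    if total <= 0:
        raise EmptyCommunityError("all-zero community")
    return p[p > 0] / total


def hill_number(densities, q: int) -> float:
    """Effective number of species at diversity order q (0, 1 or 2)."""
    p = _relative(densities)
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    if q == 2:
        return float(1.0 / np.sum(p**2))
    raise ValueError(f"order q must be 0, 1 or 2, got {q}")


def rle02(densities) -> float:
    """Relative logarithmic evenness ln(2D)/ln(0D); requires >= 2 species."""
    d0 = hill_number(densities, 0)
    if d0 < 2:
        raise UndefinedEvennessError("RLE undefined for a single-species community")
    return float(np.log(hill_number(densities, 2)) / np.log(d0))


def classify_evenness(rle: float) -> str:
    """Classify an RLE value: even (>=0.65), uneven, or dominated (<=0.45)."""
    if not (0.0 < rle <= 1.0):
        raise ValueError(f"RLE must lie in (0, 1], got {rle}")
    if rle >= EVEN_THRESHOLD:
        return "even"
    if rle <= DOMINATED_THRESHOLD:
        return "dominated"
    return "uneven"


def shannon_cover(cover_fractions) -> float:
    """Shannon diversity (nats) of a land-cover composition.

    Fractions must be non-negative with a positive sum; they are renormalized
    so percentage or proportion inputs are equivalent.
    """
    p = np.asarray(cover_fractions, dtype=float)
    if np.any(p < 0):
        raise ValueError("cover fractions must be non-negative")
    if p.sum() <= 0:
        raise ValueError("cover fractions sum to zero")
    p = p[p > 0] / p.sum()
    return float(-np.sum(p * np.log(p)))


@dataclass(frozen=True)
class HillProfile:
    """Hill numbers of orders 0-2 plus RLE evenness for one community."""

    D0: float
    D1: float
    D2: float
    RLE02: float | None
    evenness_class: str


def hill_profile(densities) -> HillProfile:
    """Full diversity profile; RLE is None (class "undefined") for one species."""
    d0 = hill_number(densities, 0)
    d1 = hill_number(densities, 1)
    d2 = hill_number(densities, 2)
    if d0 < 2:
        return HillProfile(d0, d1, d2, None, "undefined")
    r = float(np.log(d2) / np.log(d0))
    return HillProfile(d0, d1, d2, r, classify_evenness(min(r, 1.0)))


def evenness_table(density: pd.DataFrame) -> pd.DataFrame:
    """Per-site diversity profile for a sites x species density matrix.

    Sites with no nests get NaN profiles; single-species sites get NaN RLE
    and class "undefined" (they are excluded from evenness modeling).
    """
    rows = []
    for site, vec in density.iterrows():
        v = vec.to_numpy(dtype=float)
        if v.sum() <= 0:
            rows.append((site, np.nan, np.nan, np.nan, np.nan, "empty"))
            continue
        prof = hill_profile(v)
        rows.append(
            (site, prof.D0, prof.D1, prof.D2,
             np.nan if prof.RLE02 is None else prof.RLE02, prof.evenness_class)
        )
    return pd.DataFrame(
        rows, columns=["site", "D0", "D1", "D2", "RLE02", "class"]
    ).set_index("site")
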