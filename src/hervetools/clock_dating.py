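"""Integration dating of LTR retroelements.

Two dating approaches are implemented:

* **Molecular clock** — the two LTRs of a provirus are identical at
  integration and then diverge neutrally, so the element's age is the
  observed inter-LTR divergence divided by the rate at which that
  divergence accrues (0.3 percentage points per million years for
  HERV-E).  Note the rate is the *inter-LTR* divergence rate: each LTR
  individually mutates at half of it, so age = divergence / rate with no
  factor of two.
* **Ortholog presence/absence lower bounds** — if the orthologous
  insertion is found in the genome of a primate that split from the
  human lineage T million years ago, the integration must predate the
  split, giving a censored ">T My" estimate.  The divergence-time
  thresholds for the five reference taxa are chimpanzee 6, gorilla 8,
  orangutan 15, Old World monkeys 25 and marmoset (New World monkeys) 45
  My, as used in the eight-primate EPO whole-genome alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

from . import pairwise_align

#: inter-LTR divergence accumulation rate, percentage points per My
DEFAULT_RATE_PCT_PER_MY = 0.3

#: clock estimates above this value are reported as censored (">50 My")
DEFAULT_CAP_MY = 50

#: species -> minimum age (My) implied by a shared orthologous insertion
EPO_THRESHOLDS_MY = {
    "chimpanzee": 6,
    "gorilla": 8,
    "orangutan": 15,
    "old_world_monkey": 25,
    "marmoset": 45,
}


class UndatableElementError(ValueError):
    """Raised when an element cannot be clock-dated (e.g. a solo LTR)."""


@dataclass(frozen=True)
class AgeEstimate:
    """A point or censored ("greater than") integration age in My."""

    value_my: float
    rounded_my: int
    censored: bool
    method: str  # molecular_clock | epo_bound | literature
    note: Optional[str] = None

    def render(self) -> str:
        if self.censored:
            return f">{self.rounded_my} My"
        return f"{self.rounded_my} My"


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def estimate_age(
    divergence_pct: float,
    rate_pct_per_my: float = DEFAULT_RATE_PCT_PER_MY,
    cap_my: int = DEFAULT_CAP_MY,
) -> AgeEstimate:
    """Convert an inter-LTR divergence (in %) into an integration age.

    Ages are rounded to the nearest My (ties away from zero); values
    above ``cap_my`` are returned censored and render as ``">50 My"``.
    """
    if divergence_pct < 0:
        raise ValueError(f"divergence must be non-negative, got {divergence_pct}")
    if rate_pct_per_my <= 0:
        raise ValueError(f"rate must be positive, got {rate_pct_per_my}")
    value = divergence_pct / rate_pct_per_my
    if value > cap_my:
        return AgeEstimate(
            value_my=float(cap_my),
            rounded_my=int(cap_my),
            censored=True,
            method="molecular_clock",
        )
    return AgeEstimate(
        value_my=value,
        rounded_my=_round_half_away(value),
        censored=False,
        method="molecular_clock",
    )


def date_element(
    ltr5,
    ltr3,
    scoring: Optional[pairwise_align.ScoringScheme] = None,
    rate_pct_per_my: float = DEFAULT_RATE_PCT_PER_MY,
    cap_my: int = DEFAULT_CAP_MY,
) -> AgeEstimate:
    """Clock-date a provirus from its 5' and 3' LTR sequences.

    Raises :class:`UndatableElementError` when either LTR is missing,
    mirroring the "-" dating cells of solo-LTR elements.
    """
    if ltr5 is None or ltr3 is None:
        raise UndatableElementError("undatable: solo LTR (missing paired LTR)")
    d = pairwise_align.divergence_pct(ltr5, ltr3, scoring=scoring)
    return estimate_age(d, rate_pct_per_my=rate_pct_per_my, cap_my=cap_my)


def epo_lower_bound(presence: Mapping[str, bool]) -> AgeEstimate:
    """Age lower bound from presence of the orthologous insertion in primates.

    ``presence`` maps the five reference taxa to booleans.  The bound is
    the threshold of the most distant taxon sharing the insertion; when
    no non-human primate shares it the element is human-specific and a
    zero bound is returned with a flag note.
    """
    unknown = set(presence) - set(EPO_THRESHOLDS_MY)
    if unknown:
        raise KeyError(f"unknown species key(s): {sorted(unknown)}")
    bound = 0
    for species, thr in EPO_THRESHOLDS_MY.items():
        if presence.get(species, False):
            bound = max(bound, thr)
    if bound == 0:
        return AgeEstimate(
            value_my=0.0,
            rounded_my=0,
            censored=True,
            method="epo_bound",
            note="human-specific: no shared primate ortholog (<6 My)",
        )
    return AgeEstimate(
        value_my=float(bound), rounded_my=bound, censored=True, method="epo_bound"
    )
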