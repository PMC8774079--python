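"""Classification of SI loss and regain routes from species profiles.

Self-incompatibility can be lost by (1) duplication of the S-locus
(competitive interaction between the two haplotypes carried by the same
pollen), (2) deletion or inactivation of an S-locus component — usually
the S-RNase, or (3) deletion of the whole S-locus.  Self-compatible
lineages can then regain SI by (a) inactivation or reduced expression of
the duplicate loci, (b) deletion of the duplicates, (c) reactivation of
the S-RNase, or (d) evolution of a new SI system (type-2/3/4).

Given a species' SI phenotype, known whole-genome duplication history,
and its inventory of type-1 S-/S-like loci (active / inactive /
low-expressed, plus the S-RNase status of the remaining locus), an
ordered decision table assigns a loss route and a regain route.  Route c
is representable but never emitted by the table: no surveyed species
shows S-RNase reactivation; it is reachable only by explicit override.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from slocus_evo.locus_annotation import (
    Activity,
    LocusType,
    SIPhenotype,
    SpeciesProfile,
)

__all__ = [
    "LossRoute",
    "RegainRoute",
    "RouteProfile",
    "RouteCall",
    "infer_routes",
    "batch_infer",
    "profile_from_species",
]


class LossRoute(str, Enum):
    R1 = "R1"  # S-locus duplication (competitive interaction)
    R2 = "R2"  # deletion/inactivation of the S-RNase
    R3 = "R3"  # deletion of the whole S-locus
    NONE = "NONE"
    UNCLASSIFIED = "UNCLASSIFIED"


class RegainRoute(str, Enum):
    A = "a"  # inactivation / reduced expression of duplicates
    B = "b"  # deletion of duplicates
    C = "c"  # S-RNase reactivation (never emitted by the table)
    D = "d"  # a new SI system evolved
    NONE = "NONE"


class SRNaseStatus(str, Enum):
    INTACT = "intact"
    PSEUDOGENE = "pseudogene"
    DELETED = "deleted"
    NA = "na"


@dataclass(frozen=True)
class RouteProfile:
    """The inputs the route decision table consumes, per species."""

    species: str
    phenotype: SIPhenotype
    wgd_events: int
    n_type1_active: int
    n_type1_inactive: int
    n_type1_lowexpr: int
    s_rnase_status: SRNaseStatus = SRNaseStatus.NA

    def __post_init__(self) -> None:
        for f in ("wgd_events", "n_type1_active", "n_type1_inactive",
                  "n_type1_lowexpr"):
            if getattr(self, f) < 0:
                raise ValueError(f"{self.species}: {f} must be non-negative")

    @property
    def n_type1(self) -> int:
        return self.n_type1_active + self.n_type1_inactive + self.n_type1_lowexpr


@dataclass(frozen=True)
class RouteCall:
    species: str
    loss_route: LossRoute
    regain_route: RegainRoute
    ambiguous_alternatives: Tuple[Tuple[LossRoute, RegainRoute], ...] = ()
    rationale: str = ""


def profile_from_species(profile: SpeciesProfile,
                         s_rnase_status: SRNaseStatus | str = SRNaseStatus.NA
                         ) -> RouteProfile:
    """Condense an annotated :class:`SpeciesProfile` into route inputs."""
    type1 = [
        l
        for l in profile.loci
        if l.locus_type in (LocusType.TYPE1_S, LocusType.TYPE1_S_LIKE)
    ]
    n_low = sum(
        1 for l in type1 if l.activity is Activity.ACTIVE and l.low_expression
    )
    n_active = sum(
        1 for l in type1 if l.activity is Activity.ACTIVE and not l.low_expression
    )
    n_inactive = sum(1 for l in type1 if l.activity is Activity.INACTIVE)
    return RouteProfile(
        species=profile.species,
        phenotype=profile.si_phenotype,
        wgd_events=profile.wgd_events,
        n_type1_active=n_active,
        n_type1_inactive=n_inactive,
        n_type1_lowexpr=n_low,
        s_rnase_status=SRNaseStatus(s_rnase_status),
    )


def infer_routes(p: RouteProfile) -> RouteCall:
    """Apply the ordered loss/regain decision table; first match wins.

    The table is total: any profile outside the enumerated patterns gets
    an UNCLASSIFIED loss route with a rationale, never an exception.
    """
    ph = p.phenotype
    n = p.n_type1
    P = SIPhenotype

    # (i) type-1 SI retained after WGD with a single locus: the duplicate
    # created by the WGD must have been deleted again
    if ph is P.TYPE1_SI and p.wgd_events >= 1 and n == 1:
        return RouteCall(p.species, LossRoute.R1, RegainRoute.B,
                         rationale="single type-1 locus despite WGD/WGT: "
                                   "duplicates deleted")
    # (ii) type-1 SI with duplicate loci, all but one silenced
    if ph is P.TYPE1_SI and n >= 2 and (
        p.n_type1_inactive + p.n_type1_lowexpr == n - 1
    ):
        return RouteCall(p.species, LossRoute.R1, RegainRoute.A,
                         rationale="duplicate loci with all but one "
                                   "inactivated or lowly expressed")
    # (iii) SC with one locus whose S-RNase is gone but SLFs intact
    if (
        ph is P.SC
        and n == 1
        and p.s_rnase_status in (SRNaseStatus.DELETED, SRNaseStatus.PSEUDOGENE)
    ):
        return RouteCall(p.species, LossRoute.R2, RegainRoute.NONE,
                         rationale="S-RNase deleted or pseudogenized; "
                                   "SLFs retained")
    # (iv) SC with duplicate, fully active loci: loss by duplication,
    # never regained
    if ph is P.SC and n >= 2 and p.n_type1_active == n:
        return RouteCall(p.species, LossRoute.R1, RegainRoute.NONE,
                         rationale="duplicate active loci in an SC genome: "
                                   "competitive interaction persists")
    # (v) type-2/4 SI with no trace of a type-1 locus
    if ph in (P.TYPE2_SI, P.TYPE4_SI) and n == 0:
        return RouteCall(p.species, LossRoute.R3, RegainRoute.D,
                         rationale="no type-1 S-like locus; a new SI system "
                                   "evolved after whole-locus deletion")
    # (vi) type-3 SI with duplicated type-1 S-like loci
    if ph is P.TYPE3_SI and n >= 2:
        return RouteCall(p.species, LossRoute.R1, RegainRoute.D,
                         rationale="duplicate type-1 S-like loci retained "
                                   "under a new SI system")
    # (vii) other GSI with duplicate type-1 loci: cannot distinguish a
    # silenced-duplicate type-1 system from a new system
    if ph is P.GSI_OTHER and n >= 2:
        alts = ((LossRoute.R1, RegainRoute.A), (LossRoute.R1, RegainRoute.D))
        return RouteCall(p.species, LossRoute.R1, RegainRoute.A,
                         ambiguous_alternatives=alts,
                         rationale="GSI of unknown molecular type with "
                                   "duplicate type-1 loci: route a or d")
    # (viii) other SSI with no type-1 locus
    if ph is P.SSI_OTHER and n == 0:
        return RouteCall(p.species, LossRoute.R3, RegainRoute.D,
                         rationale="no type-1 S-like locus under a "
                                   "sporophytic system")
    # (ix) SC with no type-1 locus
    if ph is P.SC and n == 0:
        return RouteCall(p.species, LossRoute.R3, RegainRoute.NONE,
                         rationale="no type-1 locus and no SI: whole-locus "
                                   "deletion, never regained")
    return RouteCall(p.species, LossRoute.UNCLASSIFIED, RegainRoute.NONE,
                     rationale=f"no rule matches phenotype={ph.value}, "
                               f"n_type1={n}, wgd={p.wgd_events}")


def batch_infer(profiles: pd.DataFrame) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Route calls for a profile table plus a tally of species per route.

    Expects columns species, phenotype, wgd_events, n_type1_active,
    n_type1_inactive, n_type1_lowexpr, s_rnase_status.  Returns a report
    DataFrame (one row per species) and a {"loss+regain": count} summary.
    """
    if profiles.empty:
        return (
            pd.DataFrame(
                columns=["species", "loss_route", "regain_route",
                         "ambiguous_alternatives", "rationale"]
            ),
            {},
        )
    if profiles["species"].duplicated().any():
        dups = profiles.loc[profiles["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species names: {dups}")
    rows = []
    tally: Dict[str, int] = {}
    for _, r in profiles.iterrows():
        call = infer_routes(
            RouteProfile(
                species=r["species"],
                phenotype=SIPhenotype(r["phenotype"]),
                wgd_events=int(r["wgd_events"]),
                n_type1_active=int(r["n_type1_active"]),
                n_type1_inactive=int(r["n_type1_inactive"]),
                n_type1_lowexpr=int(r["n_type1_lowexpr"]),
                s_rnase_status=SRNaseStatus(r.get("s_rnase_status", "na")),
            )
        )
        key = f"{call.loss_route.value}+{call.regain_route.value}"
        tally[key] = tally.get(key, 0) + 1
        rows.append(
            {
                "species": call.species,
                "loss_route": call.loss_route.value,
                "regain_route": call.regain_route.value,
                "ambiguous_alternatives": ";".join(
                    f"{l.value}+{g.value}" for l, g in call.ambiguous_alternatives
                ),
                "rationale": call.rationale,
            }
        )
    return pd.DataFrame(rows), tally
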