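"""Crosslink-derived distance restraints and their use during assembly.

A crosslink between residue r_a of subunit A and residue r_b of subunit B is
an upper bound on a Cα–Cα distance.  With multiple copies of a subunit the
restrained pair is ambiguous: the restraint is satisfied when ANY present
copy pair realises the distance.  Each restraint carries two weights: the
experimental confidence w1 (given, default 1) and w2, the mean representative
plDDT of the two endpoint residues scaled to (0, 1].

The satisfaction ratio of a subcomplex is the weight of satisfied applicable
restraints over the weight of all applicable restraints (restraints whose
endpoint subunits are not both present are neutral).  A subcomplex's score is
multiplied by the ratio, and subcomplexes violating more than a maximal
weight fraction (default 10%) are filtered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import RestraintReferenceError
from .model_io import RestraintRecord, SubunitDefinition
from .representation import RepresentativeSubunit


@dataclass(frozen=True)
class WeightedRestraint:
    """One crosslink restraint, expanded over subunit copies at evaluation."""

    subunit_a: str
    res_a: int  # 0-based residue offset within the subunit
    subunit_b: str
    res_b: int
    max_dist: float
    w1: float
    w2: float

    @property
    def weight(self) -> float:
        return self.w1 * self.w2


def bind_restraints(
    records: Sequence[RestraintRecord],
    reps: dict[str, RepresentativeSubunit],
    definitions: Sequence[SubunitDefinition],
) -> list[WeightedRestraint]:
    """Validate records against the config and attach plDDT weights."""
    by_name = {d.name: d for d in definitions}
    out = []
    for rec in records:
        for name, res in ((rec.subunit_a, rec.res_a), (rec.subunit_b, rec.res_b)):
            if name not in by_name:
                raise RestraintReferenceError(f"unknown subunit {name!r}")
            if not 1 <= res <= by_name[name].length:
                raise RestraintReferenceError(
                    f"residue {res} outside subunit {name!r} "
                    f"(length {by_name[name].length})"
                )
        plddt_a = reps[rec.subunit_a].plddt[rec.res_a - 1]
        plddt_b = reps[rec.subunit_b].plddt[rec.res_b - 1]
        w2 = float((plddt_a + plddt_b) / 2.0 / 100.0)
        out.append(
            WeightedRestraint(
                subunit_a=rec.subunit_a,
                res_a=rec.res_a - 1,
                subunit_b=rec.subunit_b,
                res_b=rec.res_b - 1,
                max_dist=rec.max_dist,
                w1=rec.w1,
                w2=w2,
            )
        )
    return out


def _satisfied(sub, r: WeightedRestraint, reps) -> bool:
    """Any candidate copy-pair realises the distance (strict '<')."""
    units_a = [u for u in sub.placements if u[0] == r.subunit_a]
    units_b = [u for u in sub.placements if u[0] == r.subunit_b]
    for ua in units_a:
        pa = sub.placements[ua].apply(reps[r.subunit_a].ca[r.res_a])
        for ub in units_b:
            if ub == ua:
                continue
            pb = sub.placements[ub].apply(reps[r.subunit_b].ca[r.res_b])
            if float(np.linalg.norm(pa - pb)) < r.max_dist:
                return True
    return False


def satisfaction_ratio(
    sub,
    restraints: Sequence[WeightedRestraint],
    reps: dict[str, RepresentativeSubunit],
    detailed: bool = False,
):
    """Weighted fraction of applicable restraints satisfied by *sub*.

    Returns 1.0 when no restraint is applicable (both endpoint subunits must
    be present for a restraint to count).  With ``detailed=True`` returns
    (ratio, satisfied weight, total weight).
    """
    present = {name for name, _ in sub.placements}
    sat = 0.0
    tot = 0.0
    for r in restraints:
        if r.subunit_a not in present or r.subunit_b not in present:
            continue
        if r.subunit_a == r.subunit_b and sum(
            1 for u in sub.placements if u[0] == r.subunit_a
        ) < 2:
            continue  # intra-subunit crosslink needs two copies to apply
        tot += r.weight
        if _satisfied(sub, r, reps):
            sat += r.weight
    ratio = 1.0 if tot == 0.0 else sat / tot
    if detailed:
        return ratio, sat, tot
    return ratio


def apply_restraints(
    score: float,
    sub,
    restraints: Sequence[WeightedRestraint],
    reps: dict[str, RepresentativeSubunit],
    violation_max: float = 0.10,
) -> tuple[float, bool]:
    """Modulate a score by the satisfaction ratio and apply the violation filter.

    Returns ``(score * ratio, keep)`` where keep is False when the violated
    weight fraction ``1 - ratio`` exceeds ``violation_max``.
    """
    if score < 0:
        raise ValueError("score must be >= 0")
    ratio = satisfaction_ratio(sub, restraints, reps)
    return score * ratio, (1.0 - ratio) <= violation_max
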