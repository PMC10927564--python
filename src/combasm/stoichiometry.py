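"""Stoichiometry enumeration over a fixed transformation library.

The expensive inputs (representative subunits and the scored transformation
library) are computed once; candidate stoichiometries are then enumerated by
re-running only the fast assembly stage with a varied copy number for one
subunit.  Two signals identify plausible copy numbers: whether a full
assembly survives the filters at all (geometric capacity), and the predicted
confidence of the best full assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .assembly_core import AssemblyConfig, SubComplex, assemble
from .errors import ConfigFormatError
from .model_io import SubunitDefinition
from .representation import RepresentativeSubunit, ScoredTransformation

_CHAIN_POOL = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


@dataclass(frozen=True)
class StoichiometryScanSpec:
    """Scan one subunit's copy number over an inclusive range."""

    vary: str
    copy_min: int
    copy_max: int
    definitions: tuple[SubunitDefinition, ...]
    config: AssemblyConfig = field(default_factory=AssemblyConfig)

    def __post_init__(self):
        object.__setattr__(self, "definitions", tuple(self.definitions))
        if self.copy_min < 1 or self.copy_max < self.copy_min:
            raise ConfigFormatError("copy range must be non-empty with min >= 1")
        if self.vary not in {d.name for d in self.definitions}:
            raise ConfigFormatError(f"unknown subunit {self.vary!r}")


@dataclass(frozen=True)
class StoichiometryResult:
    copies: int
    assembled: bool
    confidence: Optional[float]
    best: Optional[SubComplex]


def _with_copies(
    definitions: Sequence[SubunitDefinition], vary: str, copies: int
) -> list[SubunitDefinition]:
    used = {c for d in definitions if d.name != vary for c in d.chain_names}
    pool = [c for c in _CHAIN_POOL if c not in used]
    if copies > len(pool):
        raise ConfigFormatError(f"no chain identifiers left for {copies} copies")
    out = []
    for d in definitions:
        if d.name == vary:
            out.append(
                SubunitDefinition(
                    name=d.name,
                    sequence=d.sequence,
                    chain_names=tuple(pool[:copies]),
                    start_res=d.start_res,
                )
            )
        else:
            out.append(d)
    return out


def scan_stoichiometries(
    spec: StoichiometryScanSpec,
    reps: dict[str, RepresentativeSubunit],
    library: Sequence[ScoredTransformation],
) -> list[StoichiometryResult]:
    """One assembly run per candidate copy number; deterministic.

    A copy count is ``assembled`` when a full-size assembly survives the
    clash/connectivity filters; its confidence is the best full assembly's
    predicted confidence (None when not assembled or when the complex is a
    single placement).
    """
    results = []
    for copies in range(spec.copy_min, spec.copy_max + 1):
        defs = _with_copies(spec.definitions, spec.vary, copies)
        total = sum(d.copies for d in defs)
        if total == 1:
            results.append(
                StoichiometryResult(
                    copies=copies, assembled=True, confidence=None, best=None
                )
            )
            continue
        ranked = assemble(reps, library, defs, spec.config)
        full = [s for s in ranked if s.size == total]
        if full:
            best = full[0]
            results.append(
                StoichiometryResult(
                    copies=copies,
                    assembled=True,
                    confidence=best.predicted_confidence(),
                    best=best,
                )
            )
        else:
            results.append(
                StoichiometryResult(
                    copies=copies, assembled=False, confidence=None, best=None
                )
            )
    return results
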