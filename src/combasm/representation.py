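"""Unified representation: representative subunits and scored transforms.

From a pool of predicted models covering pairs (or larger subsets) of
subunits, this stage selects one representative structure per subunit (the
placement with maximal mean plDDT) and extracts a library of pairwise rigid
transformations between representative frames, each scored from the
inter-subunit PAE as ``max{1, 100 - P^2/4}``.

The extracted transform for an interacting pair (A, B) is computed by
superposing the representative A' onto the modelled A (transform T1) and B'
onto the modelled B (transform T2); the library entry is the composition
that maps B' directly into A''s reference frame, ``T1^-1 ∘ T2``.  Alignment
uses only confidently modelled residues: plDDT > 80, falling back to the
ceil(L/2) highest-plDDT residues when fewer than half qualify.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import CoverageError, DegenerateAlignmentError, ParameterError
from .geometry import RigidTransform, rmsd, superpose
from .model_io import Placement, PredictedModel, SubunitDefinition

INTERACTION_CUTOFF = 8.0  # Å, strict '<'
ALIGN_PLDDT_MIN = 80.0
DEDUP_RMSD = 1.0  # Å, transformed-representative RMSD merging near-duplicates
SUBSET_SEQ_BUDGET = 1800  # residues per planned prediction job
PAE_MAX = 31.0


@dataclass(frozen=True)
class RepresentativeSubunit:
    """The single highest-mean-plDDT copy of a subunit across all models."""

    name: str
    backbone: np.ndarray  # (L, 4, 3) in its own reference frame
    plddt: np.ndarray
    provenance: str  # model_id the structure was extracted from
    mean_plddt: float

    @property
    def ca(self) -> np.ndarray:
        return self.backbone[:, 1, :]

    @property
    def length(self) -> int:
        return self.backbone.shape[0]


@dataclass(frozen=True)
class ScoredTransformation:
    """Rigid transform mapping subunit_b's representative into subunit_a's frame."""

    subunit_a: str
    subunit_b: str
    transform: RigidTransform
    mean_pae: float
    score: float
    provenance: str

    def inverted(self) -> "ScoredTransformation":
        return ScoredTransformation(
            subunit_a=self.subunit_b,
            subunit_b=self.subunit_a,
            transform=self.transform.inverse(),
            mean_pae=self.mean_pae,
            score=self.score,
            provenance=self.provenance,
        )

    def to_json(self) -> dict:
        return {
            "subunit_a": self.subunit_a,
            "subunit_b": self.subunit_b,
            **self.transform.to_json(),
            "mean_pae": self.mean_pae,
            "score": self.score,
            "provenance": self.provenance,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "ScoredTransformation":
        return cls(
            subunit_a=obj["subunit_a"],
            subunit_b=obj["subunit_b"],
            transform=RigidTransform.from_json(obj),
            mean_pae=float(obj["mean_pae"]),
            score=float(obj["score"]),
            provenance=obj.get("provenance", ""),
        )


def select_representatives(
    models: Sequence[PredictedModel],
) -> dict[str, RepresentativeSubunit]:
    """Pick, per subunit, the placement with maximal mean plDDT.

    Ties are broken by (model_id, copy index) lexicographic order so the
    choice is deterministic.
    """
    best: dict[str, tuple] = {}
    seen: set[str] = set()
    for model in sorted(models, key=lambda m: m.model_id):
        for p in model.placements:
            seen.add(p.subunit)
            mean = float(np.mean(model.placement_plddt(p)))
            key = (-mean, model.model_id, p.copy_index)
            if p.subunit not in best or key < best[p.subunit][0]:
                best[p.subunit] = (key, model, p)
    reps = {}
    for name, (key, model, p) in best.items():
        # re-centre so the representative frame is its own centroid frame
        backbone = p.backbone - p.backbone.reshape(-1, 3).mean(axis=0)
        reps[name] = RepresentativeSubunit(
            name=name,
            backbone=backbone,
            plddt=model.placement_plddt(p).copy(),
            provenance=model.model_id,
            mean_plddt=-key[0],
        )
    return reps


def check_coverage(
    reps: dict[str, RepresentativeSubunit],
    definitions: Sequence[SubunitDefinition],
) -> None:
    missing = [d.name for d in definitions if d.name not in reps]
    if missing:
        raise CoverageError(
            f"subunits absent from every predicted model: {missing}"
        )


def find_interacting_pairs(
    model: PredictedModel,
) -> list[tuple[Placement, Placement]]:
    """All placement pairs with some Cα–Cα distance strictly below 8 Å."""
    pairs = []
    ps = model.placements
    for i in range(len(ps)):
        for j in range(i + 1, len(ps)):
            if cdist(ps[i].ca, ps[j].ca).min() < INTERACTION_CUTOFF:
                pairs.append((ps[i], ps[j]))
    return pairs


def _alignment_mask(plddt: np.ndarray) -> np.ndarray:
    """Residues used for superposition: plDDT > 80, else top half by plDDT."""
    mask = plddt > ALIGN_PLDDT_MIN
    half = int(np.ceil(len(plddt) / 2))
    if mask.sum() < half:
        order = np.argsort(-plddt, kind="stable")
        mask = np.zeros(len(plddt), dtype=bool)
        mask[order[:half]] = True
    return mask


def _fit_placement(
    rep: RepresentativeSubunit, placement: Placement
) -> RigidTransform:
    """Superpose the representative onto a modelled placement (high-plDDT Cα)."""
    mask = _alignment_mask(rep.plddt)
    if mask.sum() < 3:
        raise DegenerateAlignmentError(
            f"subunit {rep.name!r}: only {int(mask.sum())} usable alignment residues"
        )
    return superpose(rep.ca[mask], placement.ca[mask])


def extract_transform(
    model: PredictedModel,
    pair: tuple[Placement, Placement],
    reps: dict[str, RepresentativeSubunit],
) -> RigidTransform:
    """Transform placing rep(B) into rep(A)'s frame mimicking the modelled pair."""
    pa, pb = pair
    t1 = _fit_placement(reps[pa.subunit], pa)
    t2 = _fit_placement(reps[pb.subunit], pb)
    return t1.inverse().compose(t2)


def score_transformation(mean_pae: float) -> float:
    """PAE-derived transform score, ``max{1, 100 - P^2/4}``, in [1, 100]."""
    if not 0.0 <= mean_pae <= PAE_MAX:
        raise ParameterError(f"mean PAE {mean_pae} outside [0, {PAE_MAX}]")
    return max(1.0, 100.0 - mean_pae**2 / 4.0)


def compute_mean_pae(
    model: PredictedModel, pair: tuple[Placement, Placement]
) -> float:
    """Mean PAE over both inter-subunit blocks, all residue pairs."""
    pa, pb = pair
    ia = slice(pa.offset, pa.offset + pa.length)
    ib = slice(pb.offset, pb.offset + pb.length)
    block_ab = model.pae[ia, ib]
    block_ba = model.pae[ib, ia]
    return float(
        (block_ab.sum() + block_ba.sum()) / (block_ab.size + block_ba.size)
    )


def build_transform_library(
    models: Sequence[PredictedModel],
    reps: dict[str, RepresentativeSubunit],
) -> list[ScoredTransformation]:
    """Scored transforms for every interacting pair in every model, deduplicated.

    Entries are canonicalized to subunit_a <= subunit_b (the reverse direction
    is recovered by inversion); for homomeric pairs both orientations are
    emitted since the two copies are not interchangeable under T1^-1 ∘ T2.
    Near-duplicates (transformed-representative Cα RMSD < 1 Å) are merged,
    keeping the best-scoring entry.
    """
    raw: list[ScoredTransformation] = []
    for model in sorted(models, key=lambda m: m.model_id):
        for pa, pb in find_interacting_pairs(model):
            p = compute_mean_pae(model, (pa, pb))
            s = score_transformation(min(p, PAE_MAX))
            entries = []
            if pa.subunit <= pb.subunit:
                t = extract_transform(model, (pa, pb), reps)
                entries.append((pa.subunit, pb.subunit, t))
            else:
                t = extract_transform(model, (pb, pa), reps)
                entries.append((pb.subunit, pa.subunit, t))
            if pa.subunit == pb.subunit:
                entries.append((pa.subunit, pb.subunit, t.inverse()))
            for a, b, tr in entries:
                raw.append(
                    ScoredTransformation(
                        subunit_a=a,
                        subunit_b=b,
                        transform=tr,
                        mean_pae=p,
                        score=s,
                        provenance=model.model_id,
                    )
                )
    return deduplicate_library(raw, reps)


def deduplicate_library(
    entries: Iterable[ScoredTransformation],
    reps: dict[str, RepresentativeSubunit],
) -> list[ScoredTransformation]:
    """Merge near-duplicate transforms per subunit pair, keeping best score."""
    kept: list[ScoredTransformation] = []
    ordered = sorted(
        entries,
        key=lambda e: (e.subunit_a, e.subunit_b, -e.score, e.provenance),
    )
    for e in ordered:
        ca = reps[e.subunit_b].ca
        moved = e.transform.apply(ca)
        dup = False
        for k in kept:
            if (k.subunit_a, k.subunit_b) != (e.subunit_a, e.subunit_b):
                continue
            if rmsd(moved, k.transform.apply(ca)) < DEDUP_RMSD:
                dup = True
                break
        if not dup:
            kept.append(e)
    return kept


def write_representatives(
    reps: dict[str, RepresentativeSubunit], path: str | Path
) -> None:
    """Serialize representatives (backbone, plDDT, provenance) as JSON."""
    payload = {}
    for name, rep in sorted(reps.items()):
        payload[name] = {
            "backbone": [
                [[round(float(v), 6) for v in atom] for atom in residue]
                for residue in rep.backbone
            ],
            "plddt": [round(float(v), 4) for v in rep.plddt],
            "provenance": rep.provenance,
            "mean_plddt": round(rep.mean_plddt, 6),
        }
    Path(path).write_text(json.dumps({"representatives": payload}))


def read_representatives(path: str | Path) -> dict[str, RepresentativeSubunit]:
    with open(path) as fh:
        obj = json.load(fh)
    reps = {}
    for name, rec in obj["representatives"].items():
        reps[name] = RepresentativeSubunit(
            name=name,
            backbone=np.array(rec["backbone"], dtype=float),
            plddt=np.array(rec["plddt"], dtype=float),
            provenance=rec.get("provenance", ""),
            mean_plddt=float(rec["mean_plddt"]),
        )
    return reps


def write_library(
    entries: Sequence[ScoredTransformation], path: str | Path
) -> None:
    Path(path).write_text(
        json.dumps({"transforms": [e.to_json() for e in entries]}, indent=1)
    )


def read_library(path: str | Path) -> list[ScoredTransformation]:
    with open(path) as fh:
        obj = json.load(fh)
    return [ScoredTransformation.from_json(rec) for rec in obj["transforms"]]


def plan_subset_jobs(
    pair_scores: dict[tuple[str, str], float],
    definitions: Sequence[SubunitDefinition],
    max_jobs_per_subunit: int = 3,
    subset_sizes: tuple[int, ...] = (3, 4, 5),
    budget: int = SUBSET_SEQ_BUDGET,
) -> list[list[str]]:
    """Plan larger-subset prediction jobs from pairwise interaction scores.

    For each subunit, up to three subsets of 3–5 subunits are emitted by
    greedily adding the highest-scoring partners while the total sequence
    length stays within the 1,800-residue job budget.  Subunits whose own
    sequence exceeds the budget yield no subset jobs.
    """
    lengths = {d.name: d.length for d in definitions}
    names = [d.name for d in definitions]

    def score_of(a: str, b: str) -> float:
        return pair_scores.get(
            (a, b), pair_scores.get((b, a), float("-inf"))
        )

    jobs: list[list[str]] = []
    seen: set[tuple[str, ...]] = set()
    for name in names:
        if lengths[name] > budget:
            continue  # flagged: no subset job fits the budget
        partners = sorted(
            (n for n in names if n != name and score_of(name, n) > float("-inf")),
            key=lambda n: (-score_of(name, n), n),
        )
        emitted = 0
        for size in subset_sizes:
            if emitted >= max_jobs_per_subunit:
                break
            subset = [name]
            total = lengths[name]
            for p in partners:
                if len(subset) >= size:
                    break
                if total + lengths[p] <= budget:
                    subset.append(p)
                    total += lengths[p]
            if len(subset) < 3:
                continue
            key = tuple(sorted(subset))
            if key not in seen:
                seen.add(key)
                jobs.append(sorted(subset))
                emitted += 1
    return jobs
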