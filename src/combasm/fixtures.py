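"""Synthetic toy complexes and fabricated "predicted model" inputs.

The assembly engine consumes predicted subunit-pair structures with
per-residue confidence (plDDT) and pairwise aligned-error (PAE) matrices.
Producing such predictions needs a GPU-scale structure predictor, so this
module fabricates them from parametrically generated toy complexes: idealized
helical backbones placed on ring / chain / tree topologies, with controllable
coordinate noise, plDDT profiles, PAE levels and decoy interactions.  Every
downstream stage is exercised against the known ground truth.

All outputs are deterministic functions of the spec and its seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import GeometryError, ParameterError
from .geometry import RigidTransform, random_rotation
from .model_io import (
    Placement,
    PredictedModel,
    RestraintRecord,
    SubunitDefinition,
    write_scores,
    write_structure,
)

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CHAIN_IDS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)

CONTACT_DISTANCE = 5.0  # target min inter-subunit Cα–Cα distance, Å
MIN_BACKBONE_DISTANCE = 3.0  # closest allowed backbone-atom approach, Å
MIN_SEPARATION = 4.0  # hard lower bound between any two placed subunits, Å
NONCONTACT_DISTANCE = 8.05  # non-neighbours must stay beyond the 8 Å cutoff


@dataclass(frozen=True)
class ToySubunit:
    name: str
    sequence: str
    backbone: np.ndarray  # (L, 4, 3), atoms N, CA, C, O

    @property
    def ca(self) -> np.ndarray:
        return self.backbone[:, 1, :]

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ToyComplexSpec:
    """Parameters of one synthetic study condition.

    ``subunit_specs`` is a list of (name, length, copies).  ``pae_true`` is
    the inter-subunit PAE written for correctly modelled pairs, ``pae_decoy``
    for decoy pairs; ``coord_noise_sd`` is the RMS 3-D displacement per atom.
    """

    topology: Literal["ring", "chain", "tree"]
    subunit_specs: tuple[tuple[str, int, int], ...]
    seed: int = 0
    coord_noise_sd: float = 0.0
    plddt_core: float = 90.0
    tail_len: int = 0
    tail_plddt: float = 30.0
    pae_true: float = 2.0
    pae_decoy: float = 30.0
    pae_intra: float = 1.0
    n_decoys: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "subunit_specs", tuple(tuple(s) for s in self.subunit_specs)
        )
        for name, length, copies in self.subunit_specs:
            if length < 5:
                raise ParameterError(f"subunit {name!r}: length {length} < 5")
            if copies < 1:
                raise ParameterError(f"subunit {name!r}: copies {copies} < 1")
        # note: pae_true < pae_decoy in realistic conditions, but the inverted
        # ordering is deliberately allowed to model misleading decoys

    @property
    def units(self) -> list[tuple[str, int]]:
        """All (subunit name, copy index) placements in declared order."""
        out = []
        for name, _length, copies in self.subunit_specs:
            out.extend((name, c) for c in range(copies))
        return out


@dataclass(frozen=True)
class GroundTruth:
    """A fully placed toy complex with its exact pairwise transforms."""

    spec: ToyComplexSpec
    subunits: dict[str, ToySubunit]
    placements: dict[tuple[str, int], RigidTransform]
    contacts: tuple[tuple[tuple[str, int], tuple[str, int]], ...]

    def backbone_of(self, unit: tuple[str, int]) -> np.ndarray:
        base = self.subunits[unit[0]].backbone
        t = self.placements[unit]
        return t.apply(base.reshape(-1, 3)).reshape(base.shape)

    def ca_of(self, unit: tuple[str, int]) -> np.ndarray:
        return self.backbone_of(unit)[:, 1, :]

    def true_transform(
        self, a: tuple[str, int], b: tuple[str, int]
    ) -> RigidTransform:
        """Exact transform mapping subunit b's frame into a's frame."""
        return self.placements[a].inverse().compose(self.placements[b])

    def definitions(self, start_res: int = 1) -> list[SubunitDefinition]:
        defs = []
        cursor = 0
        for name, _length, copies in self.spec.subunit_specs:
            chain_names = _CHAIN_IDS[cursor : cursor + copies]
            cursor += copies
            defs.append(
                SubunitDefinition(
                    name=name,
                    sequence=self.subunits[name].sequence,
                    chain_names=tuple(chain_names),
                    start_res=start_res,
                )
            )
        return defs

    def representatives(self):
        """Representative subunits in the ground-truth base frames.

        Useful as the reference frame for exact transform-recovery checks;
        the production pipeline instead extracts representatives from the
        fabricated models (whose frames are arbitrary).
        """
        from .representation import RepresentativeSubunit

        return {
            name: RepresentativeSubunit(
                name=name,
                backbone=su.backbone.copy(),
                plddt=self.plddt_profile(name),
                provenance="ground_truth",
                mean_plddt=float(self.plddt_profile(name).mean()),
            )
            for name, su in self.subunits.items()
        }

    def plddt_profile(self, name: str) -> np.ndarray:
        length = self.subunits[name].length
        prof = np.full(length, self.spec.plddt_core, dtype=float)
        if self.spec.tail_len:
            prof[length - self.spec.tail_len :] = self.spec.tail_plddt
        return prof


def _name_seed(seed: int, *parts) -> np.random.Generator:
    mixed = [seed & 0x7FFFFFFF]
    for p in parts:
        if isinstance(p, str):
            mixed.append(zlib.crc32(p.encode()) & 0x7FFFFFFF)
        else:
            mixed.append(int(p) & 0x7FFFFFFF)
    return np.random.default_rng(mixed)


def make_toy_subunit(name: str, length: int, seed: int) -> ToySubunit:
    """Idealized helical backbone of *length* residues.

    Cα atoms lie on a helix with ~3.8 Å spacing between consecutive residues;
    N, C and O are placed in a local frame around each Cα.  Deterministic for
    a given (name, length, seed); different seeds give distinct (jittered)
    traces and sequences.
    """
    if length < 5:
        raise ParameterError(f"subunit length {length} < 5")
    rng = _name_seed(seed, name, length)
    sequence = "".join(rng.choice(list(_AA_ALPHABET), size=length))
    # alpha-helix Ca trace: 100 deg turn, 1.5 A rise; radius chosen so the
    # consecutive Ca-Ca distance is the canonical 3.8 A
    i = np.arange(length)
    theta = np.deg2rad(100.0) * i
    radius = np.sqrt(3.8**2 - 1.5**2) / (2.0 * np.sin(np.deg2rad(50.0)))
    ca = np.stack(
        [radius * np.cos(theta), radius * np.sin(theta), 1.5 * i], axis=1
    )
    # local frame per residue: radial (outward), tangent, axial
    radial = np.stack([np.cos(theta), np.sin(theta), np.zeros(length)], axis=1)
    tangent = np.stack([-np.sin(theta), np.cos(theta), np.zeros(length)], axis=1)
    axial = np.array([0.0, 0.0, 1.0])
    n = ca - 1.1 * tangent + 0.8 * radial - 0.5 * axial
    c = ca + 1.1 * tangent + 0.7 * radial + 0.6 * axial
    o = c + 0.9 * radial + 0.8 * axial
    backbone = np.stack([n, ca, c, o], axis=1)
    backbone = backbone - backbone.reshape(-1, 3).mean(axis=0)
    # tiny seeded jitter so distinct seeds give distinct traces
    backbone = backbone + rng.normal(scale=2e-3, size=backbone.shape)
    return ToySubunit(name=name, sequence=sequence, backbone=backbone)


def _min_ca_dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(cdist(a, b).min())


def _contact_translation(
    fixed: tuple[np.ndarray, np.ndarray],
    mobile: tuple[np.ndarray, np.ndarray],
    direction: np.ndarray,
    target: float = CONTACT_DISTANCE,
) -> np.ndarray:
    """Translation along *direction* placing mobile in surface contact.

    *fixed* and *mobile* are (Cα coordinates, flattened backbone-atom
    coordinates) pairs.  The contact sits where both the minimal Cα–Cα
    distance reaches *target* and the closest backbone atoms stay at least
    ``MIN_BACKBONE_DISTANCE`` apart, so placed pairs interact (< 8 Å) but
    never interpenetrate van-der-Waals surfaces.
    """
    fixed_ca, fixed_bb = fixed
    mobile_ca, mobile_bb = mobile
    direction = direction / np.linalg.norm(direction)
    origin = fixed_ca.mean(axis=0) - mobile_ca.mean(axis=0)

    def separated(t: float) -> bool:
        off = origin + t * direction
        if _min_ca_dist(fixed_ca, mobile_ca + off) < target:
            return False
        return _min_ca_dist(fixed_bb, mobile_bb + off) >= MIN_BACKBONE_DISTANCE

    lo, hi = 0.0, 10.0
    while not separated(hi):
        hi *= 2.0
        if hi > 1e5:
            raise GeometryError("contact placement failed to separate subunits")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if separated(mid):
            hi = mid
        else:
            lo = mid
    return origin + hi * direction


def build_ground_truth(spec: ToyComplexSpec) -> GroundTruth:
    """Place all subunit copies per the spec topology; return exact transforms.

    Ring: copy i is copy i-1 rotated by 360°/copies about the z axis.
    Chain: units placed successively along +x, adjacent units in contact.
    Tree: random spanning tree, children attached in contact with parents.
    No two subunits overlap (min inter-subunit Cα distance > 4 Å) and only
    designated neighbours are within the 8 Å interaction cutoff.
    """
    subunits = {
        name: make_toy_subunit(name, length, spec.seed)
        for name, length, _ in spec.subunit_specs
    }
    units = spec.units
    rng = _name_seed(spec.seed, "topology", spec.topology)
    placements: dict[tuple[str, int], RigidTransform] = {}
    contacts: list[tuple[tuple[str, int], tuple[str, int]]] = []

    if spec.topology == "ring":
        if len(spec.subunit_specs) != 1:
            raise GeometryError("ring topology requires a single subunit spec")
        name, _length, copies = spec.subunit_specs[0]
        if copies < 3:
            raise GeometryError("ring needs at least 3 copies")
        base_ca = subunits[name].ca
        base_bb = subunits[name].backbone.reshape(-1, 3)
        alpha = 2.0 * np.pi / copies
        rot = np.array(
            [
                [np.cos(alpha), -np.sin(alpha), 0.0],
                [np.sin(alpha), np.cos(alpha), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        # smallest radius where adjacent copies are in (non-clashing) contact
        def separated(r: float) -> bool:
            ca = base_ca + np.array([r, 0.0, 0.0])
            bb = base_bb + np.array([r, 0.0, 0.0])
            if _min_ca_dist(ca, ca @ rot.T) < CONTACT_DISTANCE:
                return False
            return _min_ca_dist(bb, bb @ rot.T) >= MIN_BACKBONE_DISTANCE

        lo, hi = 0.0, 10.0
        while not separated(hi):
            hi *= 2.0
            if hi > 1e5:
                raise GeometryError("ring radius search failed")
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if separated(mid):
                hi = mid
            else:
                lo = mid
        radius = hi
        shift = RigidTransform(np.eye(3), np.array([radius, 0.0, 0.0]))
        for c in range(copies):
            ang = alpha * c
            rc = np.array(
                [
                    [np.cos(ang), -np.sin(ang), 0.0],
                    [np.sin(ang), np.cos(ang), 0.0],
                    [0.0, 0.0, 1.0],
                ]
            )
            placements[(name, c)] = RigidTransform(rc, np.zeros(3)).compose(shift)
        contacts = [((name, c), (name, (c + 1) % copies)) for c in range(copies)]
        if copies > 3:
            # second neighbours must sit beyond the interaction cutoff
            a = placements[(name, 0)].apply(base_ca)
            b = placements[(name, 2)].apply(base_ca)
            if _min_ca_dist(a, b) < NONCONTACT_DISTANCE:
                raise GeometryError("ring too tight: non-neighbours interact")
    elif spec.topology == "chain":
        prev = None
        for j, unit in enumerate(units):
            base_ca = subunits[unit[0]].ca
            base_bb = subunits[unit[0]].backbone.reshape(-1, 3)
            rot = random_rotation(rng)
            oriented = (base_ca @ rot.T, base_bb @ rot.T)
            if prev is None:
                placements[unit] = RigidTransform(rot, np.zeros(3))
            else:
                fixed = (
                    placements[prev].apply(subunits[prev[0]].ca),
                    placements[prev].apply(
                        subunits[prev[0]].backbone.reshape(-1, 3)
                    ),
                )
                tr = _contact_translation(
                    fixed, oriented, np.array([1.0, 0.0, 0.0])
                )
                placements[unit] = RigidTransform(rot, tr)
                contacts.append((prev, unit))
            prev = unit
    elif spec.topology == "tree":
        for j, unit in enumerate(units):
            base_ca = subunits[unit[0]].ca
            base_bb = subunits[unit[0]].backbone.reshape(-1, 3)
            if j == 0:
                placements[unit] = RigidTransform(random_rotation(rng), np.zeros(3))
                continue
            placed = units[:j]
            ok = False
            for _attempt in range(200):
                parent = placed[int(rng.integers(len(placed)))]
                rot = random_rotation(rng)
                oriented_ca = base_ca @ rot.T
                direction = rng.normal(size=3)
                fixed = (
                    placements[parent].apply(subunits[parent[0]].ca),
                    placements[parent].apply(
                        subunits[parent[0]].backbone.reshape(-1, 3)
                    ),
                )
                tr = _contact_translation(
                    fixed, (oriented_ca, base_bb @ rot.T), direction
                )
                cand = oriented_ca + tr
                others_ok = all(
                    _min_ca_dist(
                        placements[u].apply(subunits[u[0]].ca), cand
                    )
                    > NONCONTACT_DISTANCE
                    for u in placed
                    if u != parent
                )
                if others_ok:
                    placements[unit] = RigidTransform(rot, tr)
                    contacts.append((parent, unit))
                    ok = True
                    break
            if not ok:
                raise GeometryError(f"could not place unit {unit} without overlap")
    else:
        raise ParameterError(f"unknown topology {spec.topology!r}")

    gt = GroundTruth(
        spec=spec,
        subunits=subunits,
        placements=placements,
        contacts=tuple(contacts),
    )
    # global sanity: nothing overlaps
    for i, u in enumerate(units):
        for v in units[i + 1 :]:
            if _min_ca_dist(gt.ca_of(u), gt.ca_of(v)) <= MIN_SEPARATION:
                raise GeometryError(f"subunits {u} and {v} overlap")
    return gt


def _pair_pae(la: int, lb: int, inter: float, intra: float) -> np.ndarray:
    n = la + lb
    pae = np.full((n, n), intra, dtype=float)
    np.fill_diagonal(pae, 0.0)
    pae[:la, la:] = inter
    pae[la:, :la] = inter
    return pae


def _pair_model(
    gt: GroundTruth,
    model_id: str,
    unit_a: tuple[str, int],
    coords_a: np.ndarray,
    unit_b: tuple[str, int],
    coords_b: np.ndarray,
    inter_pae: float,
    rng: np.random.Generator,
) -> PredictedModel:
    spec = gt.spec
    sigma = spec.coord_noise_sd / np.sqrt(3.0)
    if sigma > 0:
        coords_a = coords_a + rng.normal(scale=sigma, size=coords_a.shape)
        coords_b = coords_b + rng.normal(scale=sigma, size=coords_b.shape)
    # random global motion: the model's frame is arbitrary, as in real output
    frame = RigidTransform(random_rotation(rng), rng.normal(scale=5.0, size=3))
    coords_a = frame.apply(coords_a.reshape(-1, 3)).reshape(coords_a.shape)
    coords_b = frame.apply(coords_b.reshape(-1, 3)).reshape(coords_b.shape)
    la = coords_a.shape[0]
    lb = coords_b.shape[0]
    name_a, name_b = unit_a[0], unit_b[0]
    copy_b = 1 if name_a == name_b else 0
    placements = (
        Placement(name_a, 0, "A", coords_a, 0),
        Placement(name_b, copy_b, "B", coords_b, la),
    )
    plddt = np.concatenate([gt.plddt_profile(name_a), gt.plddt_profile(name_b)])
    pae = _pair_pae(la, lb, inter_pae, spec.pae_intra)
    return PredictedModel(model_id=model_id, placements=placements, plddt=plddt, pae=pae)


def fabricate_predictions(spec: ToyComplexSpec) -> tuple[GroundTruth, list[PredictedModel]]:
    """Fabricate pairwise "predicted models" for a toy complex.

    One model per contacting pair (ground-truth geometry plus Gaussian noise,
    inter-subunit PAE = ``pae_true``) and ``n_decoys`` decoy models (random
    relative orientation in surface contact, inter-subunit PAE =
    ``pae_decoy``).  Each model lives in its own arbitrary reference frame.
    """
    gt = build_ground_truth(spec)
    models: list[PredictedModel] = []
    # one model per geometrically distinct contact: contacts whose relative
    # transform repeats an already-emitted one (e.g. around a symmetric ring)
    # would only be merged again by library deduplication
    emitted: dict[tuple[str, str], list[RigidTransform]] = {}
    for k, (ua, ub) in enumerate(gt.contacts):
        rel = gt.true_transform(ua, ub)
        key = (ua[0], ub[0])
        if any(rel.almost_equal(t, tol=1e-6) for t in emitted.get(key, [])):
            continue
        emitted.setdefault(key, []).append(rel)
        rng = _name_seed(spec.seed, "pairmodel", k)
        models.append(
            _pair_model(
                gt,
                f"pair_{k}_{ua[0]}_{ub[0]}",
                ua,
                gt.backbone_of(ua),
                ub,
                gt.backbone_of(ub),
                spec.pae_true,
                rng,
            )
        )
    type_pairs = sorted({tuple(sorted((ua[0], ub[0]))) for ua, ub in gt.contacts})
    for d in range(spec.n_decoys):
        rng = _name_seed(spec.seed, "decoy", d)
        name_a, name_b = type_pairs[d % len(type_pairs)]
        sa, sb = gt.subunits[name_a], gt.subunits[name_b]
        rot = random_rotation(rng)
        oriented_ca = sb.ca @ rot.T
        direction = rng.normal(size=3)
        tr = _contact_translation(
            (sa.ca, sa.backbone.reshape(-1, 3)),
            (oriented_ca, sb.backbone.reshape(-1, 3) @ rot.T),
            direction,
        )
        decoy_t = RigidTransform(rot, tr)
        coords_b = decoy_t.apply(sb.backbone.reshape(-1, 3)).reshape(sb.backbone.shape)
        unit_a = (name_a, 0)
        unit_b = (name_b, 1 if name_a == name_b else 0)
        models.append(
            _pair_model(
                gt,
                f"decoy_{d}_{name_a}_{name_b}",
                unit_a,
                sa.backbone.copy(),
                unit_b,
                coords_b,
                spec.pae_decoy,
                rng,
            )
        )
    return gt, models


def write_predictions(
    models: Sequence[PredictedModel],
    gt: GroundTruth,
    out_dir: str | Path,
) -> list[tuple[Path, Path]]:
    """Write fabricated models as (PDB, scores JSON) file pairs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = []
    for m in models:
        pdb = out_dir / f"{m.model_id}.pdb"
        scores = out_dir / f"{m.model_id}_scores.json"
        chains = []
        bf = []
        for p in m.placements:
            seq = gt.subunits[p.subunit].sequence
            chains.append((p.chain_id, 1, seq, p.backbone))
            bf.append(m.placement_plddt(p))
        write_structure(chains, pdb, bfactors=bf)
        write_scores(m.plddt, m.pae, scores)
        pairs.append((pdb, scores))
    return pairs


def simulate_crosslinks(
    gt: GroundTruth,
    n: int,
    max_dist: float,
    seed: int,
) -> list[RestraintRecord]:
    """Sample *n* inter-subunit residue pairs under *max_dist* from the truth.

    Eligible pairs (residues on distinct subunit copies with ground-truth
    Cα–Cα distance below ``max_dist``) are grouped by subunit-copy pair and
    drawn round-robin across groups, uniformly at random (seeded) within
    each group — emulating crosslink coverage spread over the complex's
    interfaces rather than concentrated on the residue-richest one.  Each
    sampled pair becomes a restraint with w1 = 1.  If fewer than *n* pairs
    are eligible, all eligible pairs are returned.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    units = gt.spec.units
    by_interface: dict[tuple, list[tuple[str, int, str, int]]] = {}
    for i, u in enumerate(units):
        for v in units[i + 1 :]:
            d = cdist(gt.ca_of(u), gt.ca_of(v))
            pairs = sorted(
                {
                    (u[0], int(ri) + 1, v[0], int(rj) + 1)
                    for ri, rj in zip(*np.nonzero(d < max_dist))
                }
            )
            if pairs:
                by_interface[(u, v)] = pairs
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x5EED])
    for pairs in by_interface.values():
        rng.shuffle(pairs)
    chosen: list[tuple[str, int, str, int]] = []
    seen: set[tuple[str, int, str, int]] = set()
    depth = 0
    while len(chosen) < n:
        advanced = False
        for key in sorted(by_interface):
            pairs = by_interface[key]
            if depth < len(pairs):
                advanced = True
                cand = pairs[depth]
                if cand not in seen:
                    seen.add(cand)
                    chosen.append(cand)
                    if len(chosen) == n:
                        break
        if not advanced:
            break
        depth += 1
    return [
        RestraintRecord(a, ra, b, rb, max_dist=max_dist, w1=1.0)
        for a, ra, b, rb in chosen
    ]
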