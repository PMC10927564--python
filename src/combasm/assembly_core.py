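"""Hierarchical combinatorial assembly of subunit copies.

Starting from single placed subunits, the engine runs N iterations (N = total
subunit copies).  Iteration i builds candidate subcomplexes of size i by
merging disjoint subcomplexes of sizes k and i-k through every applicable
library transformation, then filters them (steric clashes, chain
connectivity, optional distance restraints), clusters near-identical
geometries, and keeps the K best per subunit composition for later
iterations.  If no full-size assembly survives, the largest partial
assemblies are returned.

Scores: a subcomplex's raw score is the sum of the (possibly
symmetry-rewarded) transformation scores over its assembly tree; when
restraints are given the kept score is that sum times the restraint
satisfaction ratio.  Subcomplexes with more than five copies of one subunit
related by a single repeated library transformation earn the symmetry reward
``S + S*(100-S)/100`` on the joining transformation.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from . import correspondence
from .errors import AssemblyError, ConfigFormatError
from .geometry import RigidTransform, rmsd, superpose
from .model_io import AssemblyGroupSpec, SubunitDefinition
from .representation import RepresentativeSubunit, ScoredTransformation
from .restraints import WeightedRestraint, satisfaction_ratio

# van der Waals radii of backbone atoms N, CA, C, O (Å)
_BB_RADII = np.array([1.55, 1.70, 1.70, 1.52])


@dataclass(frozen=True)
class AssemblyConfig:
    """Tunable thresholds of the assembly engine (defaults are the method's)."""

    beam_width: int = 100  # K: best subcomplexes kept per composition
    clash_penetration: float = 1.0  # Å of vdW-sphere overlap counted as a clash
    clash_fraction: float = 0.05  # tolerated fraction of clashing backbone atoms
    clash_plddt_min: float = 80.0  # only confident atoms participate in clashes
    linker_rate: float = 3.0  # Å allowed per linker residue (+1) between domains
    cluster_rmsd: float = 1.0  # Å leader-clustering threshold
    restraint_violation_max: float = 0.10  # violated-weight fraction that filters
    symmetry_min_copies: int = 6  # 'over five' identical copies earn the reward
    # search guard: at most this many candidates are materialized and filtered
    # per composition and iteration (candidates stream in descending score, so
    # only low-scoring ones can be skipped); None disables the cap
    max_eval_per_composition: int | None = 5000

    def __post_init__(self):
        if self.beam_width < 1:
            raise ConfigFormatError("beam_width must be >= 1")
        for name in (
            "clash_penetration",
            "clash_fraction",
            "clash_plddt_min",
            "linker_rate",
            "cluster_rmsd",
            "restraint_violation_max",
        ):
            if getattr(self, name) <= 0:
                raise ConfigFormatError(f"{name} must be > 0")


@dataclass(frozen=True)
class TreeNode:
    """One merge in the assembly tree."""

    lib_index: int  # identity of the library transformation used
    subunit_a: str
    subunit_b: str
    score: float  # possibly symmetry-rewarded transformation score
    size_left: int  # amino acids on the anchor (first) side
    size_right: int  # amino acids on the moved (second) side

    @property
    def weight(self) -> int:
        """Eq.-style weight: amino acids in the smaller merged side."""
        return min(self.size_left, self.size_right)


@dataclass(frozen=True)
class SubComplex:
    """A partial assembly: placed subunit copies plus the tree that built it."""

    placements: dict[tuple[str, int], RigidTransform]
    nodes: tuple[TreeNode, ...]
    raw_score: float
    restraint_ratio: float = 1.0
    satisfied_weight: float = 0.0
    total_weight: float = 0.0
    tree_repr: str = ""

    @property
    def score(self) -> float:
        return self.raw_score * self.restraint_ratio

    @property
    def size(self) -> int:
        return len(self.placements)

    @property
    def comp_counts(self) -> Counter:
        """Subunit-name multiset (cached)."""
        cached = self.__dict__.get("_comp_counts")
        if cached is None:
            cached = Counter(name for name, _ in self.placements)
            object.__setattr__(self, "_comp_counts", cached)
        return cached

    @property
    def node_lib_counts(self) -> Counter:
        """How often each library transformation occurs in the tree (cached)."""
        cached = self.__dict__.get("_node_lib_counts")
        if cached is None:
            cached = Counter(n.lib_index for n in self.nodes)
            object.__setattr__(self, "_node_lib_counts", cached)
        return cached

    @property
    def composition(self) -> tuple[tuple[str, int], ...]:
        return tuple(sorted(self.comp_counts.items()))

    def predicted_confidence(self) -> float:
        """Weighted mean of the tree's transformation scores (see scoring)."""
        if not self.nodes:
            raise AssemblyError(
                "predicted confidence is undefined for a single subunit"
            )
        w = np.array([n.weight for n in self.nodes], dtype=float)
        s = np.array([n.score for n in self.nodes], dtype=float)
        return float(np.sum(w * s) / np.sum(w))

    def metadata(self) -> dict:
        return {
            "score": self.score,
            "raw_score": self.raw_score,
            "restraint_ratio": self.restraint_ratio,
            "confidence": self.predicted_confidence() if self.nodes else None,
            "composition": [list(c) for c in self.composition],
            "tree": [
                {
                    "transform_index": n.lib_index,
                    "subunit_a": n.subunit_a,
                    "subunit_b": n.subunit_b,
                    "score": n.score,
                    "size_left": n.size_left,
                    "size_right": n.size_right,
                }
                for n in self.nodes
            ],
        }


def symmetry_reward(score: float, qualifies: bool = True) -> float:
    """Reward for symmetric subcomplexes: ``S + S*(100-S)/100``."""
    if not 1.0 <= score <= 100.0:
        raise ConfigFormatError(f"score {score} outside [1, 100]")
    if not qualifies:
        return score
    return score + score * (100.0 - score) / 100.0


def _qualifies_for_reward(
    merged_counts: Counter,
    prior_same_lib: int,
    t: ScoredTransformation,
    config: AssemblyConfig,
) -> bool:
    """More than five copies of one subunit in one orbit of a single transform."""
    if t.subunit_a != t.subunit_b:
        return False
    copies = merged_counts.get(t.subunit_a, 0)
    if copies < config.symmetry_min_copies:
        return False
    return 1 + prior_same_lib >= copies - 1


class ClashContext:
    """Precomputed per-subunit confident backbone atoms for clash tests."""

    def __init__(
        self,
        reps: dict[str, RepresentativeSubunit],
        config: AssemblyConfig,
    ):
        self.config = config
        self.atoms: dict[str, np.ndarray] = {}
        self.radii: dict[str, np.ndarray] = {}
        self.centroid: dict[str, np.ndarray] = {}
        self.bound: dict[str, float] = {}
        for name, rep in reps.items():
            mask = rep.plddt > config.clash_plddt_min
            if not mask.any():
                mask = np.ones(rep.length, dtype=bool)  # degenerate: use all
            bb = rep.backbone[mask]  # (M, 4, 3)
            atoms = bb.reshape(-1, 3)
            self.atoms[name] = atoms
            self.radii[name] = np.tile(_BB_RADII, int(mask.sum()))
            c = atoms.mean(axis=0)
            self.centroid[name] = c
            self.bound[name] = float(
                np.linalg.norm(atoms - c, axis=1).max() + _BB_RADII.max()
            )

    def pair_clash_fractions(
        self,
        name_a: str,
        transform_a: RigidTransform,
        name_b: str,
        transform_b: RigidTransform,
    ) -> tuple[float, float]:
        """Fraction of each side's confident backbone atoms clashing."""
        # bounding-sphere prescreen: far-apart subunits cannot clash
        ca = transform_a.apply(self.centroid[name_a])
        cb = transform_b.apply(self.centroid[name_b])
        if np.linalg.norm(ca - cb) > self.bound[name_a] + self.bound[name_b]:
            return 0.0, 0.0
        xa = transform_a.apply(self.atoms[name_a])
        xb = transform_b.apply(self.atoms[name_b])
        ra, rb = self.radii[name_a], self.radii[name_b]
        d = cdist(xa, xb)
        overlap = d < (ra[:, None] + rb[None, :] - self.config.clash_penetration)
        return float(overlap.any(axis=1).mean()), float(overlap.any(axis=0).mean())


def clash_filter(
    candidate: SubComplex,
    reps: dict[str, RepresentativeSubunit],
    config: AssemblyConfig,
    context: ClashContext | None = None,
    pairs: Sequence[tuple[tuple[str, int], tuple[str, int]]] | None = None,
    early_stop: bool = False,
) -> tuple[bool, dict]:
    """Steric-clash test over placement pairs.

    A backbone atom (plDDT > 80) clashes when its centre penetrates another
    subunit's van-der-Waals surface by more than ``clash_penetration``; the
    candidate is discarded when, against some other subunit, more than
    ``clash_fraction`` of a subunit's confident backbone atoms clash.
    Returns (keep, report).
    """
    ctx = context or ClashContext(reps, config)
    units = sorted(candidate.placements)
    if pairs is None:
        pairs = [
            (units[i], units[j])
            for i in range(len(units))
            for j in range(i + 1, len(units))
        ]
    worst: dict[tuple[str, int], float] = {}
    keep = True
    for ua, ub in pairs:
        fa, fb = ctx.pair_clash_fractions(
            ua[0], candidate.placements[ua], ub[0], candidate.placements[ub]
        )
        worst[ua] = max(worst.get(ua, 0.0), fa)
        worst[ub] = max(worst.get(ub, 0.0), fb)
        if fa > config.clash_fraction or fb > config.clash_fraction:
            keep = False
            if early_stop:
                break
    return keep, {"max_clash_fraction": worst}


def _chain_segments(
    definitions: Sequence[SubunitDefinition],
) -> list[tuple[SubunitDefinition, SubunitDefinition, int, str]]:
    """Consecutive same-chain subunit pairs: (first, second, n_linker, chain)."""
    by_chain: dict[str, list[tuple[int, SubunitDefinition, int]]] = defaultdict(list)
    for d in definitions:
        for copy, chain in enumerate(d.chain_names):
            by_chain[chain].append((d.start_res, d, copy))
    out = []
    for chain, entries in by_chain.items():
        entries.sort(key=lambda e: e[0])
        if len(entries) < 2:
            continue
        for (s1, d1, c1), (s2, d2, c2) in zip(entries, entries[1:]):
            n_linker = s2 - (s1 + d1.length)
            out.append(((d1, c1), (d2, c2), max(n_linker, 0), chain))
    return out


def connectivity_filter(
    candidate: SubComplex,
    definitions: Sequence[SubunitDefinition],
    config: AssemblyConfig,
    reps: dict[str, RepresentativeSubunit],
) -> bool:
    """Chain-connectivity test for subunits that are segments of one chain.

    For each present consecutive pair of same-chain segments, the distance
    between the Cα of the first segment's C-terminal residue and the Cα of
    the second segment's N-terminal residue must not exceed
    ``(n_linker + 1) * linker_rate``.  Subunits from different chains are
    never tested.  Returns True to keep.
    """
    for (d1, c1), (d2, c2), n_linker, _chain in _chain_segments(definitions):
        u1, u2 = (d1.name, c1), (d2.name, c2)
        if u1 not in candidate.placements or u2 not in candidate.placements:
            continue
        ca1 = candidate.placements[u1].apply(reps[d1.name].ca[-1])
        ca2 = candidate.placements[u2].apply(reps[d2.name].ca[0])
        if np.linalg.norm(ca1 - ca2) > (n_linker + 1) * config.linker_rate:
            return False
    return True


def merge(
    sub1: SubComplex,
    sub2: SubComplex,
    t: ScoredTransformation,
    anchor1: tuple[str, int],
    anchor2: tuple[str, int],
    lib_index: int,
    reps: dict[str, RepresentativeSubunit],
    config: AssemblyConfig | None = None,
) -> SubComplex:
    """Join two disjoint subcomplexes through one library transformation.

    ``anchor1`` (a copy of ``t.subunit_a`` in sub1) stays fixed; sub2 is moved
    rigidly so that ``anchor2`` (a copy of ``t.subunit_b``) lands where the
    transformation puts subunit_b relative to subunit_a.  sub2's copy labels
    are renumbered to avoid collisions.
    """
    config = config or AssemblyConfig()
    if anchor1[0] != t.subunit_a or anchor2[0] != t.subunit_b:
        raise AssemblyError("anchors do not match the transformation's subunits")
    motion = (
        sub1.placements[anchor1]
        .compose(t.transform)
        .compose(sub2.placements[anchor2].inverse())
    )
    new_placements = dict(sub1.placements)
    relabel: dict[tuple[str, int], tuple[str, int]] = {}
    next_copy = dict(sub1.comp_counts)
    for (name, copy) in sorted(sub2.placements):
        new_idx = next_copy.get(name, 0)
        next_copy[name] = new_idx + 1
        relabel[(name, copy)] = (name, new_idx)
    for unit, placement in sub2.placements.items():
        new_unit = relabel[unit]
        if new_unit in new_placements:
            raise AssemblyError(f"shared placement {new_unit} after merge")
        new_placements[new_unit] = motion.compose(placement)
    merged_counts = sub1.comp_counts + sub2.comp_counts
    size_left = sum(reps[name].length for name, _ in sub1.placements)
    size_right = sum(reps[name].length for name, _ in sub2.placements)
    qualifies = _qualifies_for_reward(
        merged_counts,
        sub1.node_lib_counts.get(lib_index, 0)
        + sub2.node_lib_counts.get(lib_index, 0),
        t,
        config,
    )
    node_score = symmetry_reward(t.score, qualifies)
    node = TreeNode(
        lib_index=lib_index,
        subunit_a=t.subunit_a,
        subunit_b=t.subunit_b,
        score=node_score,
        size_left=size_left,
        size_right=size_right,
    )
    tree_repr = f"({sub1.tree_repr or sub1.composition}+{sub2.tree_repr or sub2.composition}@{lib_index})"
    return SubComplex(
        placements=new_placements,
        nodes=sub1.nodes + sub2.nodes + (node,),
        raw_score=sub1.raw_score + sub2.raw_score + node_score,
        restraint_ratio=1.0,
        tree_repr=tree_repr,
    )


# ---------------------------------------------------------------------------
# clustering


def _unit_order(sub: SubComplex) -> list[tuple[str, int]]:
    return sorted(sub.placements)


def _full_ca(sub: SubComplex, order, reps) -> np.ndarray:
    return np.concatenate(
        [sub.placements[u].apply(reps[u[0]].ca) for u in order]
    )


def subcomplex_units(
    sub: SubComplex, reps: dict[str, RepresentativeSubunit]
) -> list[tuple[str, np.ndarray]]:
    """(name, placed Cα coordinates) per subunit copy, in canonical order."""
    return [
        (u[0], sub.placements[u].apply(reps[u[0]].ca)) for u in _unit_order(sub)
    ]


def correspondence_rmsd(
    a: SubComplex,
    b: SubComplex,
    reps: dict[str, RepresentativeSubunit],
) -> float:
    """Cα RMSD between same-composition subcomplexes, copies matched.

    The copy correspondence for identical subunits is resolved by the
    centroid-superposition swap heuristic (see :mod:`combasm.correspondence`),
    then the full Cα RMSD is computed under the final correspondence.
    """
    if a.composition != b.composition:
        raise AssemblyError("correspondence_rmsd requires identical compositions")
    return correspondence.min_rmsd(
        subcomplex_units(a, reps), subcomplex_units(b, reps)
    )


def _fingerprint(
    sub: SubComplex, ca_centroids: dict[str, np.ndarray]
) -> np.ndarray:
    """Sorted centroid pair distances: a cheap label- and frame-invariant key."""
    cents = np.array(
        [sub.placements[u].apply(ca_centroids[u[0]]) for u in _unit_order(sub)]
    )
    if len(cents) < 2:
        return np.zeros(1)
    d = cdist(cents, cents)
    iu = np.triu_indices(len(cents), k=1)
    return np.sort(d[iu])


def cluster_subcomplexes(
    candidates: Sequence[SubComplex],
    config: AssemblyConfig,
    reps: dict[str, RepresentativeSubunit],
    max_leaders: int | None = None,
) -> list[SubComplex]:
    """Greedy leader clustering in descending score order.

    A candidate joins the first leader within ``cluster_rmsd`` Cα RMSD
    (correspondence-resolved), otherwise it founds a new cluster.  Cluster
    leaders are returned in score order.  A sorted-centroid-distance
    fingerprint prescreens clearly different geometries before the expensive
    correspondence-resolved RMSD; ``max_leaders`` stops early once that many
    leaders exist (later candidates could only be absorbed or truncated).
    """
    ordered = sorted(
        candidates, key=lambda s: (-s.score, s.composition, s.tree_repr)
    )
    ca_centroids = {name: rep.ca.mean(axis=0) for name, rep in reps.items()}
    margin = max(4.0, 8.0 * config.cluster_rmsd)
    leaders: list[SubComplex] = []
    prints: list[np.ndarray] = []
    for cand in ordered:
        if max_leaders is not None and len(leaders) >= max_leaders:
            break
        fp = _fingerprint(cand, ca_centroids)
        joined = False
        for leader, lfp in zip(leaders, prints):
            if leader.composition != cand.composition:
                continue
            if np.abs(lfp - fp).max() > margin:
                continue
            if correspondence_rmsd(leader, cand, reps) < config.cluster_rmsd:
                joined = True
                break
        if not joined:
            leaders.append(cand)
            prints.append(fp)
    return leaders


# ---------------------------------------------------------------------------
# main driver


def _group_ok(
    counts: Counter, groups: AssemblyGroupSpec | None, full: dict[str, int]
) -> bool:
    """Group members must assemble to completion before cross-group merges."""
    if groups is None:
        return True
    for g in groups.groups:
        gset = set(g)
        inside = {n: c for n, c in counts.items() if n in gset}
        if not inside:
            continue
        complete = all(counts.get(n, 0) == full[n] for n in gset)
        only_group = set(counts) <= gset
        if not (complete or only_group):
            return False
    return True


def assemble(
    reps: dict[str, RepresentativeSubunit],
    library: Sequence[ScoredTransformation],
    definitions: Sequence[SubunitDefinition],
    config: AssemblyConfig | None = None,
    restraints: Sequence[WeightedRestraint] | None = None,
    groups: AssemblyGroupSpec | None = None,
    log: Optional[list] = None,
) -> list[SubComplex]:
    """Run the full N-iteration combinatorial assembly.

    Returns full-size assemblies ranked by predicted confidence, or the
    largest partial assemblies achieved when the complex cannot be completed.
    ``log``, when given, collects per-iteration candidate/filter/cluster
    counters.
    """
    config = config or AssemblyConfig()
    if not library:
        raise AssemblyError("empty transformation library")
    full_counts = {d.name: d.copies for d in definitions}
    if groups is not None:
        for g in groups.groups:
            for name in g:
                if name not in full_counts:
                    raise ConfigFormatError(f"group references unknown subunit {name!r}")
    n_total = sum(full_counts.values())
    ctx = ClashContext(reps, config)

    # transforms usable as a->b, indexed by (subunit_a, subunit_b)
    directed: dict[tuple[str, str], list[tuple[int, ScoredTransformation]]] = (
        defaultdict(list)
    )
    for idx, entry in enumerate(library):
        directed[(entry.subunit_a, entry.subunit_b)].append((idx, entry))
        inv = entry.inverted()
        directed[(inv.subunit_a, inv.subunit_b)].append((idx, inv))

    beams: dict[int, list[SubComplex]] = {1: []}
    for d in sorted(definitions, key=lambda d: d.name):
        if d.name not in reps:
            raise AssemblyError(f"no representative for subunit {d.name!r}")
        beams[1].append(
            SubComplex(
                placements={(d.name, 0): RigidTransform.identity()},
                nodes=(),
                raw_score=0.0,
                tree_repr=d.name,
            )
        )

    ca_centroids = {name: rep.ca.mean(axis=0) for name, rep in reps.items()}
    fp_margin = max(4.0, 8.0 * config.cluster_rmsd)

    largest = 1
    for i in range(2, n_total + 1):
        # expansion: enumerate merge jobs of disjoint kept subcomplexes.
        # A job's score is known without geometry (sum of subtree scores plus
        # the possibly rewarded new-node score), so geometry is materialized
        # lazily during the streamed filtering below.
        counters = Counter()
        jobs_by_comp: dict[tuple, list[tuple]] = defaultdict(list)
        for k in range(1, i // 2 + 1):
            small = beams.get(k, [])
            big = beams.get(i - k, [])
            for bi, base in enumerate(big):
                for si, attach in enumerate(small):
                    # equal halves: unordered pairs only (an element may merge
                    # with a relabeled copy of itself, e.g. homodimers)
                    if k == i - k and si < bi:
                        continue
                    combined = base.comp_counts + attach.comp_counts
                    if any(combined[n] > full_counts.get(n, 0) for n in combined):
                        continue
                    if not _group_ok(combined, groups, full_counts):
                        continue
                    comp = tuple(sorted(combined.items()))
                    subtree_score = base.raw_score + attach.raw_score
                    base_units = sorted(base.placements)
                    attach_units = sorted(attach.placements)
                    for ua in base_units:
                        for ub in attach_units:
                            for lib_idx, entry in directed.get(
                                (ua[0], ub[0]), ()
                            ):
                                counters["expanded"] += 1
                                qualifies = _qualifies_for_reward(
                                    combined,
                                    base.node_lib_counts.get(lib_idx, 0)
                                    + attach.node_lib_counts.get(lib_idx, 0),
                                    entry,
                                    config,
                                )
                                node_score = symmetry_reward(
                                    entry.score, qualifies
                                )
                                jobs_by_comp[comp].append(
                                    (
                                        subtree_score + node_score,
                                        base.tree_repr,
                                        attach.tree_repr,
                                        lib_idx,
                                        ua,
                                        ub,
                                        base,
                                        attach,
                                        entry,
                                    )
                                )

        # filtering + clustering, streamed in descending score order so the
        # expensive geometry/clash work stops once K leaders per composition
        # exist (any later candidate is either absorbed by a cluster or falls
        # beyond the beam).  With restraints the ratio modulates the score,
        # so every surviving candidate is materialized and fully re-ranked.
        kept: list[SubComplex] = []
        for comp in sorted(jobs_by_comp):
            jobs = jobs_by_comp[comp]
            jobs.sort(key=lambda j: (-j[0], j[1], j[2], j[3], j[4], j[5]))
            if config.max_eval_per_composition is not None:
                jobs = jobs[: config.max_eval_per_composition]
            leaders: list[SubComplex] = []
            prints: list[np.ndarray] = []
            survivors: list[SubComplex] = []  # restraints path only
            for job in jobs:
                if not restraints and len(leaders) >= config.beam_width:
                    break
                _score, _tb, _ta, lib_idx, ua, ub, base, attach, entry = job
                cand = merge(base, attach, entry, ua, ub, lib_idx, reps, config)
                if restraints:
                    ratio, sat_w, tot_w = satisfaction_ratio(
                        cand, restraints, reps, detailed=True
                    )
                    if 1.0 - ratio > config.restraint_violation_max:
                        counters["restraint_filtered"] += 1
                        continue
                    cand = replace(
                        cand,
                        restraint_ratio=ratio,
                        satisfied_weight=sat_w,
                        total_weight=tot_w,
                    )
                if not connectivity_filter(cand, definitions, config, reps):
                    counters["connectivity_filtered"] += 1
                    continue
                # incremental clash test: cross pairs only (within-side pairs
                # passed the test when their subcomplex was built)
                new_units = [
                    u for u in sorted(cand.placements)
                    if u not in base.placements
                ]
                pairs = [
                    (x, y) for x in sorted(base.placements) for y in new_units
                ]
                keep, _rep = clash_filter(
                    cand, reps, config, context=ctx, pairs=pairs,
                    early_stop=True,
                )
                if not keep:
                    counters["clash_filtered"] += 1
                    continue
                if restraints:
                    survivors.append(cand)
                    continue
                fp = _fingerprint(cand, ca_centroids)
                joined = False
                for leader, lfp in zip(leaders, prints):
                    if np.abs(lfp - fp).max() > fp_margin:
                        continue
                    if correspondence_rmsd(leader, cand, reps) < config.cluster_rmsd:
                        joined = True
                        break
                if joined:
                    counters["clustered_away"] += 1
                    continue
                leaders.append(cand)
                prints.append(fp)
            if restraints:
                leaders = cluster_subcomplexes(
                    survivors, config, reps, max_leaders=config.beam_width
                )
            kept.extend(leaders)
        counters["kept"] = len(kept)
        if log is not None:
            log.append({"iteration": i, **counters})
        if kept:
            beams[i] = kept
            largest = max(largest, i)

    result = beams.get(n_total) or beams.get(largest, [])
    def sort_key(s: SubComplex):
        conf = s.predicted_confidence() if s.nodes else 0.0
        return (-conf, -s.score, s.composition, s.tree_repr)

    return sorted(result, key=sort_key)
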