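"""Copy-correspondence resolution between structures with identical subunits.

With p identical copies of a subunit there are p! equivalent labelings, and a
naive RMSD under the wrong labeling is large for geometrically identical
structures.  Enumerating p! correspondences is intractable, so the
correspondence is resolved heuristically on a reduced representation (three
anchor points per subunit copy: N-terminal Cα, centroid, C-terminal Cα — the
extra anchors make chirality-flipped matchings of symmetric arrangements
cost nonzero, which bare centroids do not):

1. seeding — the first copy of the largest identical-copy group of one
   structure is tentatively matched to each copy of the other; each tentative
   match defines a unit-level superposition under which the remaining copies
   are assigned per group by the Hungarian algorithm; the best-seeded
   assignment (plus a rigid-motion-invariant sorted-distance signature
   assignment and the declared order) starts the refinement;
2. ICP-style refinement — alternate anchor superposition with per-group
   optimal re-assignment until stable;
3. pairwise-swap hill climbing — swap the correspondence of two identical
   copies, re-superpose, keep the swap if the anchor RMSD decreased, repeat
   until no swap helps.

The final correspondence is used for the full Cα RMSD.  With fewer than
three subunits the superposition of anchors is degenerate under relabeling
and the (at most two) correspondences are enumerated directly.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import AssemblyError
from .geometry import rmsd, superpose

Unit = tuple[str, np.ndarray]  # (subunit name, Cα coordinates)


def _check_compositions(units_a: Sequence[Unit], units_b: Sequence[Unit]):
    names_a = sorted(n for n, _ in units_a)
    names_b = sorted(n for n, _ in units_b)
    if names_a != names_b:
        raise AssemblyError("compositions differ; correspondence undefined")


def _full_rmsd(units_a, units_b, order_b) -> float:
    xa = np.concatenate([ca for _n, ca in units_a])
    xb = np.concatenate([units_b[i][1] for i in order_b])
    t = superpose(xb, xa)
    return rmsd(t.apply(xb), xa)


def _anchors(ca: np.ndarray) -> np.ndarray:
    return np.stack([ca[0], ca.mean(axis=0), ca[-1]])


def resolve_correspondence(
    units_a: Sequence[Unit], units_b: Sequence[Unit]
) -> list[int]:
    """Indices into units_b matching each unit of units_a (same subunit name)."""
    _check_compositions(units_a, units_b)
    groups: dict[str, list[int]] = defaultdict(list)
    for idx, (name, _ca) in enumerate(units_a):
        groups[name].append(idx)
    b_by_name: dict[str, list[int]] = defaultdict(list)
    for idx, (name, _ca) in enumerate(units_b):
        b_by_name[name].append(idx)
    order = [0] * len(units_a)
    taken: dict[str, int] = defaultdict(int)
    for idx, (name, _ca) in enumerate(units_a):
        order[idx] = b_by_name[name][taken[name]]
        taken[name] += 1

    n = len(units_a)
    if n < 3:
        best = _full_rmsd(units_a, units_b, order)
        best_order = list(order)
        for name, idxs in groups.items():
            if len(idxs) == 2:
                trial = list(order)
                i, j = idxs
                trial[i], trial[j] = trial[j], trial[i]
                val = _full_rmsd(units_a, units_b, trial)
                if val < best:
                    best, best_order = val, trial
        return best_order

    anch_a = np.stack([_anchors(ca) for _n, ca in units_a])  # (n, 3, 3)
    anch_b = np.stack([_anchors(ca) for _n, ca in units_b])
    cent_a = anch_a[:, 1, :]
    cent_b = anch_b[:, 1, :]

    def anchor_rmsd(ordering) -> float:
        xa = anch_a.reshape(-1, 3)
        xb = anch_b[list(ordering)].reshape(-1, 3)
        t = superpose(xb, xa)
        return rmsd(t.apply(xb), xa)

    def assign_under(transform) -> list[int]:
        """Per-group optimal assignment given a superposition of b onto a."""
        moved = transform.apply(cent_b)
        new_order = [0] * n
        for name, idxs in groups.items():
            b_idxs = b_by_name[name]
            cost = np.linalg.norm(
                cent_a[idxs][:, None, :] - moved[b_idxs][None, :, :], axis=2
            )
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                new_order[idxs[r]] = b_idxs[c]
        return new_order

    candidates: list[list[int]] = [list(order)]

    # signature-based start: match copies by sorted distances to all other
    # centroids, a rigid-motion-invariant description
    def signatures(cents):
        return {
            i: np.sort(np.delete(np.linalg.norm(cents - cents[i], axis=1), i))
            for i in range(len(cents))
        }

    sig_a = signatures(cent_a)
    sig_b = signatures(cent_b)
    sig_order = list(order)
    for name, idxs in groups.items():
        b_idxs = b_by_name[name]
        cost = np.array(
            [[np.linalg.norm(sig_a[i] - sig_b[j]) for j in b_idxs] for i in idxs]
        )
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            sig_order[idxs[r]] = b_idxs[c]
    candidates.append(sig_order)

    # seeded starts: anchor one copy of the largest group onto each of its
    # possible partners via unit-level superposition
    seed_name = max(groups, key=lambda nm: (len(groups[nm]), nm))
    seed_slot = groups[seed_name][0]
    seed_ca_a = units_a[seed_slot][1]
    for j in b_by_name[seed_name]:
        try:
            t = superpose(units_b[j][1], seed_ca_a)
        except ValueError:
            continue
        candidates.append(assign_under(t))

    best_order = min(candidates, key=anchor_rmsd)

    # ICP-style refinement
    for _ in range(20):
        xb = anch_b[best_order].reshape(-1, 3)
        t = superpose(xb, anch_a.reshape(-1, 3))
        new_order = assign_under(t)
        if new_order == best_order:
            break
        if anchor_rmsd(new_order) >= anchor_rmsd(best_order) - 1e-12:
            break
        best_order = new_order

    # pairwise-swap hill climbing
    current = anchor_rmsd(best_order)
    improved = True
    while improved:
        improved = False
        best_swap = None
        best_val = current
        for name, idxs in groups.items():
            for i, j in itertools.combinations(idxs, 2):
                trial = list(best_order)
                trial[i], trial[j] = trial[j], trial[i]
                val = anchor_rmsd(trial)
                if val < best_val - 1e-12:
                    best_val = val
                    best_swap = (i, j)
        if best_swap is not None:
            i, j = best_swap
            best_order[i], best_order[j] = best_order[j], best_order[i]
            current = best_val
            improved = True
    return best_order


def min_rmsd(units_a: Sequence[Unit], units_b: Sequence[Unit]) -> float:
    """Correspondence-resolved full Cα RMSD between two unit sets."""
    order = resolve_correspondence(units_a, units_b)
    return _full_rmsd(units_a, units_b, order)


def brute_force_min_rmsd(
    units_a: Sequence[Unit], units_b: Sequence[Unit]
) -> float:
    """Exact minimum RMSD over all per-subunit copy permutations (testing aid)."""
    _check_compositions(units_a, units_b)
    groups: dict[str, list[int]] = defaultdict(list)
    for idx, (name, _ca) in enumerate(units_a):
        groups[name].append(idx)
    b_by_name: dict[str, list[int]] = defaultdict(list)
    for idx, (name, _ca) in enumerate(units_b):
        b_by_name[name].append(idx)
    names = sorted(groups)
    best = np.inf
    for perms in itertools.product(
        *[itertools.permutations(b_by_name[name]) for name in names]
    ):
        order = [0] * len(units_a)
        for name, perm in zip(names, perms):
            for slot, b_idx in zip(groups[name], perm):
                order[slot] = b_idx
        best = min(best, _full_rmsd(units_a, units_b, order))
    return float(best)
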