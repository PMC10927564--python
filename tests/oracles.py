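"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities with plain numpy / itertools rather
than calling the code paths they check.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
from scipy.spatial.distance import cdist

from combasm.assembly_core import SubComplex, clash_filter
from combasm.geometry import RigidTransform

BB_RADII = np.array([1.55, 1.70, 1.70, 1.52])


def brute_force_clash_fractions(
    atoms_a: np.ndarray,
    radii_a: np.ndarray,
    atoms_b: np.ndarray,
    radii_b: np.ndarray,
    penetration: float,
) -> tuple[float, float]:
    """All-pairs distance check: fraction of atoms penetrating > `penetration`."""
    hit_a = np.zeros(len(atoms_a), dtype=bool)
    hit_b = np.zeros(len(atoms_b), dtype=bool)
    for i in range(len(atoms_a)):
        for j in range(len(atoms_b)):
            d = float(np.linalg.norm(atoms_a[i] - atoms_b[j]))
            if d < radii_a[i] + radii_b[j] - penetration:
                hit_a[i] = True
                hit_b[j] = True
    return float(hit_a.mean()), float(hit_b.mean())


def enumerate_assemblies(reps, library, definitions, config):
    """Exhaustive enumeration of binary assembly trees x transform choices.

    Returns every filter-surviving placement set for the full unit set as
    (score, {unit: RigidTransform}).  Feasible only for a handful of copies
    and transforms; no symmetry reward (callers stay below six copies).
    Geometry is composed here with plain matrix algebra; only the filters
    are shared with the implementation under test.
    """
    units = tuple(
        (d.name, c) for d in sorted(definitions, key=lambda d: d.name)
        for c in range(d.copies)
    )
    # directed transforms (a -> b)
    directed: dict[tuple[str, str], list[RigidTransform]] = {}
    scores: dict[tuple[str, str], list[float]] = {}
    for e in library:
        directed.setdefault((e.subunit_a, e.subunit_b), []).append(e.transform)
        scores.setdefault((e.subunit_a, e.subunit_b), []).append(e.score)
        inv = e.inverted()
        directed.setdefault((inv.subunit_a, inv.subunit_b), []).append(inv.transform)
        scores.setdefault((inv.subunit_a, inv.subunit_b), []).append(inv.score)

    def passes_filters(placements: dict) -> bool:
        sub = SubComplex(placements=dict(placements), nodes=(), raw_score=0.0)
        keep, _ = clash_filter(sub, reps, config)
        return keep

    # bottom-up over labeled unit subsets
    states: dict[frozenset, list[tuple[float, dict]]] = {}
    for u in units:
        states[frozenset([u])] = [(0.0, {u: RigidTransform.identity()})]
    all_subsets = []
    for size in range(2, len(units) + 1):
        for subset in itertools.combinations(units, size):
            fs = frozenset(subset)
            out = []
            seen = set()
            for k in range(1, size // 2 + 1):
                for part in itertools.combinations(subset, k):
                    p1 = frozenset(part)
                    p2 = fs - p1
                    key = (p1, p2) if k < size - k else tuple(sorted([p1, p2], key=sorted))
                    if key in seen:
                        continue
                    seen.add(key)
                    for s1, pl1 in states.get(p1, []):
                        for s2, pl2 in states.get(p2, []):
                            for ua in pl1:
                                for ub in pl2:
                                    for t, sc in zip(
                                        directed.get((ua[0], ub[0]), []),
                                        scores.get((ua[0], ub[0]), []),
                                    ):
                                        # motion bringing pl2 into pl1's frame
                                        m = (
                                            pl1[ua]
                                            .compose(t)
                                            .compose(pl2[ub].inverse())
                                        )
                                        placements = dict(pl1)
                                        for u, p in pl2.items():
                                            placements[u] = m.compose(p)
                                        if not passes_filters(placements):
                                            continue
                                        out.append((s1 + s2 + sc, placements))
            states[fs] = out
    return states[frozenset(units)]
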