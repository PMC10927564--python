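"""Model confidence, the pairwise-connectivity diagnostic, and evaluation.

* ``predicted_confidence`` — the amino-acid-weighted mean of the
  transformation scores in an assembly tree; each merge is weighted by the
  size (in residues) of the smaller merged side, so transformations moving
  large parts of the complex dominate the confidence.
* ``pairwise_connectivity`` — given a transformation library and the true
  complex, the fraction of amino acids in the largest connected component of
  the graph whose edges are subunit pairs with an acceptably accurate
  transform (quality > 0.23).  A single component means assembly is possible
  in principle; fragmentation means it is not.
* ``edge_quality`` — a DockQ-style interface quality composite (fraction of
  native contacts, interface RMSD, ligand RMSD with the standard constants),
  pluggable so an external implementation can be substituted.
* ``tm_score`` — length-normalised global accuracy in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from . import correspondence
from .assembly_core import SubComplex, subcomplex_units
from .errors import AssemblyError
from .fixtures import GroundTruth
from .geometry import rmsd, superpose
from .representation import RepresentativeSubunit, ScoredTransformation

CONNECTIVITY_QUALITY_MIN = 0.23
_CONTACT_DIST = 5.0  # Å, heavy-atom contact distance for fnat
_INTERFACE_DIST = 10.0  # Å, interface-residue cutoff for iRMSD


@dataclass(frozen=True)
class ConnectivityGraph:
    """Subunit-copy graph with acceptable-quality transform edges."""

    nodes: tuple[tuple[tuple[str, int], int], ...]  # (unit, amino-acid count)
    edges: tuple[tuple[tuple[str, int], tuple[str, int]], ...]

    def largest_component_fraction(self) -> float:
        g = nx.Graph()
        weights = dict(self.nodes)
        g.add_nodes_from(weights)
        g.add_edges_from(self.edges)
        total = sum(weights.values())
        best = max(
            sum(weights[n] for n in comp) for comp in nx.connected_components(g)
        )
        return best / total


def predicted_confidence(sub: SubComplex) -> float:
    """Weighted mean of tree transformation scores; weights are the amino-acid
    counts of the smaller merged side of each tree node."""
    return sub.predicted_confidence()


def _residue_contacts(bb_a: np.ndarray, bb_b: np.ndarray) -> set[tuple[int, int]]:
    """Residue pairs with any backbone-atom pair within the contact distance."""
    la, lb = bb_a.shape[0], bb_b.shape[0]
    d = cdist(bb_a.reshape(-1, 3), bb_b.reshape(-1, 3))
    hits = np.nonzero(d < _CONTACT_DIST)
    return {(int(i) // 4, int(j) // 4) for i, j in zip(*hits)}


def dockq_like(
    model_a: np.ndarray,
    model_b: np.ndarray,
    native_a: np.ndarray,
    native_b: np.ndarray,
) -> float:
    """DockQ-style composite quality of a dimer model against the native dimer.

    Inputs are (L, 4, 3) backbone arrays for the two subunits, model and
    native in corresponding residue order.  The composite is the mean of the
    native-contact fraction, a 1/(1+(iRMSD/1.5)^2) interface term and a
    1/(1+(LRMSD/8.5)^2) ligand-placement term.
    """
    native_contacts = _residue_contacts(native_a, native_b)
    model_contacts = _residue_contacts(model_a, model_b)
    fnat = (
        len(native_contacts & model_contacts) / len(native_contacts)
        if native_contacts
        else 0.0
    )

    # ligand RMSD: superpose on the receptor (first subunit), measure the second
    t = superpose(model_a.reshape(-1, 3), native_a.reshape(-1, 3))
    lrms = rmsd(t.apply(model_b[:, 1, :]), native_b[:, 1, :])

    # interface RMSD: native interface residues on both sides
    d = cdist(native_a.reshape(-1, 3), native_b.reshape(-1, 3))
    ia = sorted({i // 4 for i, j in zip(*np.nonzero(d < _INTERFACE_DIST))})
    ib = sorted({j // 4 for i, j in zip(*np.nonzero(d < _INTERFACE_DIST))})
    if len(ia) + len(ib) >= 2:
        nat_iface = np.concatenate(
            [native_a[ia].reshape(-1, 3), native_b[ib].reshape(-1, 3)]
        )
        mod_iface = np.concatenate(
            [model_a[ia].reshape(-1, 3), model_b[ib].reshape(-1, 3)]
        )
        ti = superpose(mod_iface, nat_iface)
        irms = rmsd(ti.apply(mod_iface), nat_iface)
    else:
        irms = lrms
    return float(
        (fnat + 1.0 / (1.0 + (irms / 1.5) ** 2) + 1.0 / (1.0 + (lrms / 8.5) ** 2))
        / 3.0
    )


def edge_quality(
    entry: ScoredTransformation,
    truth: GroundTruth,
    pair: tuple[tuple[str, int], tuple[str, int]],
    reps: dict[str, RepresentativeSubunit] | None = None,
) -> float:
    """Quality of a library transform against one true contacting copy pair.

    The transform-induced dimer (subunit_a fixed, subunit_b moved by the
    transform) is compared to the true relative placement of the given copy
    pair with the DockQ-style composite.  When representatives are supplied
    their coordinates build the model dimer; otherwise the ground-truth
    subunit structures are used for both.
    """
    ua, ub = pair
    if {ua[0], ub[0]} != {entry.subunit_a, entry.subunit_b}:
        raise AssemblyError("transform subunits do not match the pair")
    if ua[0] != entry.subunit_a:
        ua, ub = ub, ua
    base_a = truth.subunits[entry.subunit_a].backbone
    base_b = truth.subunits[entry.subunit_b].backbone
    rel_true = truth.true_transform(ua, ub)
    native_b = rel_true.apply(base_b.reshape(-1, 3)).reshape(base_b.shape)
    if reps is not None:
        model_a = reps[entry.subunit_a].backbone
        mb = reps[entry.subunit_b].backbone
        model_b = entry.transform.apply(mb.reshape(-1, 3)).reshape(mb.shape)
    else:
        model_a = base_a
        model_b = entry.transform.apply(base_b.reshape(-1, 3)).reshape(base_b.shape)
    return dockq_like(model_a, model_b, base_a, native_b)


def pairwise_connectivity(
    library: Sequence[ScoredTransformation],
    truth: GroundTruth,
    quality_fn: Callable[..., float] | None = None,
    threshold: float = CONNECTIVITY_QUALITY_MIN,
    reps: dict[str, RepresentativeSubunit] | None = None,
) -> tuple[float, ConnectivityGraph]:
    """Fraction of amino acids in the largest acceptably-connected component.

    An edge joins a contacting copy pair of the true complex when some
    library transform for that subunit pair has quality above *threshold*
    (default DockQ-style composite > 0.23).
    """
    qf = quality_fn or edge_quality
    units = truth.spec.units
    nodes = tuple(
        ((name, copy), truth.subunits[name].length) for name, copy in units
    )
    edges = []
    for ua, ub in truth.contacts:
        key = {ua[0], ub[0]}
        candidates = [
            e for e in library if {e.subunit_a, e.subunit_b} == key
        ]
        if any(qf(e, truth, (ua, ub), reps=reps) > threshold for e in candidates):
            edges.append((ua, ub))
    graph = ConnectivityGraph(nodes=nodes, edges=tuple(edges))
    return graph.largest_component_fraction(), graph


# ---------------------------------------------------------------------------
# global accuracy


def _tm_d0(l_ref: int) -> float:
    if l_ref <= 21:
        return 0.5
    return max(0.5, 1.24 * (l_ref - 15) ** (1.0 / 3.0) - 1.8)


def tm_score(model: np.ndarray, reference: np.ndarray) -> float:
    """TM-score of *model* against *reference* (corresponding (N, 3) Cα sets).

    d0 is set from the reference length.  The superposition maximising the
    score is searched by seeding from the full alignment and from sliding
    fragments (L/2 and L/4), each refined by iteratively re-superposing on
    the residues currently within the inclusion cutoff.
    """
    model = np.asarray(model, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if model.shape != reference.shape:
        raise AssemblyError("tm_score requires equal-length coordinate sets")
    n = model.shape[0]
    d0 = _tm_d0(n)

    def score_for(t) -> float:
        d = np.linalg.norm(t.apply(model) - reference, axis=1)
        return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))

    def refine(seed_idx: np.ndarray) -> float:
        if seed_idx.size < 3:
            return 0.0
        t = superpose(model[seed_idx], reference[seed_idx])
        best = score_for(t)
        prev_idx = None
        for _ in range(20):
            d = np.linalg.norm(t.apply(model) - reference, axis=1)
            idx = np.nonzero(d < max(d0, 4.5))[0]
            if idx.size < 3:
                break
            if prev_idx is not None and np.array_equal(idx, prev_idx):
                break
            prev_idx = idx
            t = superpose(model[idx], reference[idx])
            best = max(best, score_for(t))
        return best

    best = refine(np.arange(n))
    for frag in (max(n // 2, 3), max(n // 4, 3)):
        step = max(frag // 2, 1)
        for start in range(0, n - frag + 1, step):
            best = max(best, refine(np.arange(start, start + frag)))
    return best


def _truth_units(truth: GroundTruth) -> list[tuple[str, np.ndarray]]:
    return [(name, truth.ca_of((name, copy))) for name, copy in truth.spec.units]


def assembly_vs_truth_rmsd(
    sub: SubComplex,
    truth: GroundTruth,
    reps: dict[str, RepresentativeSubunit],
) -> float:
    """Correspondence-resolved Cα RMSD of an assembly against the ground truth."""
    return correspondence.min_rmsd(_truth_units(truth), subcomplex_units(sub, reps))


def assembly_vs_truth_tm(
    sub: SubComplex,
    truth: GroundTruth,
    reps: dict[str, RepresentativeSubunit],
) -> float:
    """Correspondence-resolved TM-score of an assembly against the ground truth."""
    units_t = _truth_units(truth)
    units_m = subcomplex_units(sub, reps)
    order = correspondence.resolve_correspondence(units_t, units_m)
    ref = np.concatenate([ca for _n, ca in units_t])
    model = np.concatenate([units_m[i][1] for i in order])
    return tm_score(model, ref)
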