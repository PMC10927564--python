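"""Input/output for subunit configs, predicted models, restraints and assemblies.

Formats
-------
* subunit config — JSON, a list (or ``{"subunits": [...]}``) of objects with
  keys ``name``, ``sequence``, ``chain_names``, ``start_res``;
* predicted models — PDB or mmCIF structures, each paired with a scores JSON
  carrying a per-residue ``plddt`` list and a square ``pae`` matrix (the
  ``predicted_aligned_error`` spelling is also accepted);
* restraints — TSV/CSV with columns
  ``subunit_a, res_a, subunit_b, res_b, max_dist[, w1]``;
* assemblies — multi-chain PDB plus a JSON metadata sidecar.

Residue numbering is 1-based author numbering at every file boundary;
internally all residue indices are 0-based offsets within a subunit.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .errors import (
    CapacityError,
    ConfigFormatError,
    RestraintReferenceError,
    ScoreDialectError,
    SequenceIdentityError,
)

MAX_TOTAL_COPIES = 128

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_AA1 = {v: k for k, v in _AA3.items()}


@dataclass(frozen=True)
class SubunitDefinition:
    """One assembly unit: a chain, or a contiguous domain of a chain.

    ``chain_names`` has one entry per copy of the subunit in the target
    complex; ``start_res`` is the author residue number of the first residue.
    """

    name: str
    sequence: str
    chain_names: tuple[str, ...]
    start_res: int = 1

    def __post_init__(self):
        object.__setattr__(self, "chain_names", tuple(self.chain_names))
        if not self.name:
            raise ConfigFormatError("subunit name must be non-empty")
        if len(self.sequence) < 1:
            raise ConfigFormatError(f"subunit {self.name!r}: empty sequence")
        if not self.chain_names:
            raise ConfigFormatError(f"subunit {self.name!r}: chain_names empty")

    @property
    def copies(self) -> int:
        return len(self.chain_names)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Placement:
    """One subunit copy inside a predicted model.

    ``backbone`` is an (L, 4, 3) array with atoms ordered N, CA, C, O;
    ``offset`` is the index of the copy's first residue in the model-wide
    residue ordering used by the plDDT vector and the PAE matrix.
    """

    subunit: str
    copy_index: int
    chain_id: str
    backbone: np.ndarray
    offset: int

    @property
    def ca(self) -> np.ndarray:
        return self.backbone[:, 1, :]

    @property
    def length(self) -> int:
        return self.backbone.shape[0]


@dataclass(frozen=True)
class PredictedModel:
    """Predicted structure of a subset of subunit copies with confidences."""

    model_id: str
    placements: tuple[Placement, ...]
    plddt: np.ndarray
    pae: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "placements", tuple(self.placements))
        total = sum(p.length for p in self.placements)
        plddt = np.asarray(self.plddt, dtype=float)
        pae = np.asarray(self.pae, dtype=float)
        if plddt.shape != (total,):
            raise ScoreDialectError(
                f"model {self.model_id!r}: plDDT length {plddt.shape[0]} "
                f"!= residue count {total}"
            )
        if pae.shape != (total, total):
            raise ScoreDialectError(
                f"model {self.model_id!r}: PAE shape {pae.shape} "
                f"!= ({total}, {total})"
            )
        if plddt.min() < 0 or plddt.max() > 100:
            raise ScoreDialectError(f"model {self.model_id!r}: plDDT outside [0, 100]")
        if pae.min() < 0 or pae.max() > 31:  # tolerate minor dialect overshoot
            raise ScoreDialectError(f"model {self.model_id!r}: PAE outside [0, 31]")
        object.__setattr__(self, "plddt", plddt)
        object.__setattr__(self, "pae", pae)

    def placement_plddt(self, placement: Placement) -> np.ndarray:
        return self.plddt[placement.offset : placement.offset + placement.length]


@dataclass(frozen=True)
class RestraintRecord:
    """Crosslink-derived Cα–Cα upper bound between two subunits.

    Residue indices are 1-based within the subunit sequence; ``w1`` is the
    experimental-confidence weight in (0, 1].
    """

    subunit_a: str
    res_a: int
    subunit_b: str
    res_b: int
    max_dist: float
    w1: float = 1.0

    def __post_init__(self):
        if self.max_dist <= 0:
            raise ConfigFormatError("restraint max_dist must be > 0")
        if not (0 < self.w1 <= 1):
            raise ConfigFormatError("restraint w1 must be in (0, 1]")


@dataclass(frozen=True)
class AssemblyGroupSpec:
    """Subunit groups to be assembled to completion before cross-group merges."""

    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        groups = tuple(tuple(g) for g in self.groups)
        object.__setattr__(self, "groups", groups)
        seen: set[str] = set()
        for g in groups:
            if len(g) < 2:
                raise ConfigFormatError("each assembly group needs >= 2 subunits")
            for name in g:
                if name in seen:
                    raise ConfigFormatError(f"subunit {name!r} in multiple groups")
                seen.add(name)


# ---------------------------------------------------------------------------
# readers


def read_subunit_config(path: str | Path) -> list[SubunitDefinition]:
    """Read and validate a subunit config JSON."""
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigFormatError(f"{path}: not valid JSON ({exc})") from exc
    if isinstance(raw, dict):
        raw = raw.get("subunits", raw)
    if isinstance(raw, dict):  # name -> record mapping
        raw = [dict(rec, name=name) for name, rec in raw.items()]
    defs: list[SubunitDefinition] = []
    names: set[str] = set()
    for rec in raw:
        try:
            d = SubunitDefinition(
                name=rec["name"],
                sequence=rec["sequence"],
                chain_names=tuple(rec["chain_names"]),
                start_res=int(rec.get("start_res", 1)),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigFormatError(f"{path}: bad subunit record {rec!r}") from exc
        if d.name in names:
            raise ConfigFormatError(f"{path}: duplicate subunit name {d.name!r}")
        names.add(d.name)
        defs.append(d)
    total = sum(d.copies for d in defs)
    if total > MAX_TOTAL_COPIES:
        raise CapacityError(
            f"{path}: {total} subunit copies exceed the supported maximum "
            f"of {MAX_TOTAL_COPIES}"
        )
    return defs


def write_subunit_config(defs: Sequence[SubunitDefinition], path: str | Path) -> None:
    payload = [
        {
            "name": d.name,
            "sequence": d.sequence,
            "chain_names": list(d.chain_names),
            "start_res": d.start_res,
        }
        for d in defs
    ]
    Path(path).write_text(json.dumps({"subunits": payload}, indent=1))


def _chain_backbone(chain: gemmi.Chain) -> tuple[str, np.ndarray]:
    """Extract sequence and (L, 4, 3) backbone from a gemmi chain."""
    seq = []
    coords = []
    prev_num = None
    for res in chain:
        one = _AA1.get(res.name)
        if one is None:
            raise SequenceIdentityError(f"unknown residue name {res.name!r}")
        if prev_num is not None and res.seqid.num != prev_num + 1:
            raise SequenceIdentityError(
                f"chain {chain.name!r}: residue numbering gap at "
                f"{prev_num} -> {res.seqid.num} (gapped models unsupported)"
            )
        prev_num = res.seqid.num
        row = []
        for atom_name in BACKBONE_ATOMS:
            atom = res.find_atom(atom_name, "*")
            if atom is None:
                raise SequenceIdentityError(
                    f"chain {chain.name!r} residue {res.seqid.num}: "
                    f"missing backbone atom {atom_name}"
                )
            row.append([atom.pos.x, atom.pos.y, atom.pos.z])
        seq.append(one)
        coords.append(row)
    return "".join(seq), np.array(coords, dtype=float)


def _load_scores(scores_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    with open(scores_path) as fh:
        obj = json.load(fh)
    if "plddt" not in obj:
        raise ScoreDialectError(f"{scores_path}: missing 'plddt' key")
    pae = obj.get("pae", obj.get("predicted_aligned_error"))
    if pae is None:
        raise ScoreDialectError(
            f"{scores_path}: missing 'pae'/'predicted_aligned_error' key"
        )
    return np.asarray(obj["plddt"], dtype=float), np.asarray(pae, dtype=float)


def read_predicted_model(
    structure_path: str | Path,
    scores_path: str | Path,
    config: Sequence[SubunitDefinition],
) -> PredictedModel:
    """Read a predicted structure plus its scores JSON into a PredictedModel.

    Chains are matched to subunits by exact sequence identity, ties broken by
    config order; the plDDT/PAE ordering must follow the concatenated chain
    order of the structure.
    """
    st = gemmi.read_structure(str(structure_path))
    st.setup_entities()
    if len(st) == 0:
        raise ConfigFormatError(f"{structure_path}: no models in structure")
    placements: list[Placement] = []
    copy_counter: dict[str, int] = {}
    offset = 0
    for chain in st[0]:
        seq, backbone = _chain_backbone(chain)
        match = next((d for d in config if d.sequence == seq), None)
        if match is None:
            raise SequenceIdentityError(
                f"{structure_path}: chain {chain.name!r} sequence matches no "
                f"configured subunit"
            )
        copy = copy_counter.get(match.name, 0)
        copy_counter[match.name] = copy + 1
        placements.append(
            Placement(match.name, copy, chain.name, backbone, offset)
        )
        offset += backbone.shape[0]
    plddt, pae = _load_scores(scores_path)
    return PredictedModel(
        model_id=Path(structure_path).stem,
        placements=tuple(placements),
        plddt=plddt,
        pae=pae,
    )


def read_restraints(
    path: str | Path, config: Sequence[SubunitDefinition] | None = None
) -> list[RestraintRecord]:
    """Read a crosslink restraint table (TSV or CSV; w1 defaults to 1)."""
    text = Path(path).read_text()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delim)
    required = {"subunit_a", "res_a", "subunit_b", "res_b", "max_dist"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise ConfigFormatError(
            f"{path}: expected columns {sorted(required)}, got {reader.fieldnames}"
        )
    known = {d.name for d in config} if config is not None else None
    records = []
    for i, row in enumerate(reader, start=2):
        try:
            rec = RestraintRecord(
                subunit_a=row["subunit_a"],
                res_a=int(row["res_a"]),
                subunit_b=row["subunit_b"],
                res_b=int(row["res_b"]),
                max_dist=float(row["max_dist"]),
                w1=float(row["w1"]) if row.get("w1") not in (None, "") else 1.0,
            )
        except ValueError as exc:
            raise ConfigFormatError(f"{path} line {i}: {exc}") from exc
        if known is not None:
            for name in (rec.subunit_a, rec.subunit_b):
                if name not in known:
                    raise RestraintReferenceError(
                        f"{path} line {i}: unknown subunit {name!r}"
                    )
        records.append(rec)
    return records


def write_restraints(records: Sequence[RestraintRecord], path: str | Path) -> None:
    lines = ["subunit_a\tres_a\tsubunit_b\tres_b\tmax_dist\tw1"]
    for r in records:
        lines.append(
            f"{r.subunit_a}\t{r.res_a}\t{r.subunit_b}\t{r.res_b}"
            f"\t{r.max_dist:g}\t{r.w1:g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_groups(path: str | Path) -> AssemblyGroupSpec:
    with open(path) as fh:
        obj = json.load(fh)
    return AssemblyGroupSpec(groups=tuple(tuple(g) for g in obj["groups"]))


# ---------------------------------------------------------------------------
# structure writing


def write_structure(
    chains: Sequence[tuple[str, int, str, np.ndarray]],
    path: str | Path,
    bfactors: Sequence[np.ndarray] | None = None,
) -> None:
    """Write backbone chains to PDB or mmCIF (by file suffix).

    Each chain is ``(chain_id, start_res, sequence, backbone)`` with backbone
    shaped (L, 4, 3), atoms N, CA, C, O.  ``bfactors`` optionally carries one
    per-residue vector per chain (e.g. plDDT).
    """
    st = gemmi.Structure()
    st.name = Path(path).stem
    model = gemmi.Model("1")
    for ci, (chain_id, start_res, seq, backbone) in enumerate(chains):
        backbone = np.asarray(backbone, dtype=float)
        if backbone.shape != (len(seq), 4, 3):
            raise ConfigFormatError(
                f"chain {chain_id!r}: backbone shape {backbone.shape} does not "
                f"match sequence length {len(seq)}"
            )
        chain = gemmi.Chain(chain_id)
        for ri, letter in enumerate(seq):
            res = gemmi.Residue()
            res.name = _AA3[letter]
            res.seqid = gemmi.SeqId(start_res + ri, " ")
            for ai, atom_name in enumerate(BACKBONE_ATOMS):
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(atom_name[0])
                atom.pos = gemmi.Position(*backbone[ri, ai])
                atom.occ = 1.0
                atom.b_iso = float(bfactors[ci][ri]) if bfactors is not None else 0.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def write_scores(
    plddt: np.ndarray, pae: np.ndarray, path: str | Path, ndigits: int = 4
) -> None:
    """Write a scores JSON in the canonical plddt/pae dialect."""
    obj = {
        "plddt": [round(float(v), ndigits) for v in np.asarray(plddt).ravel()],
        "pae": [
            [round(float(v), ndigits) for v in row] for row in np.asarray(pae)
        ],
    }
    Path(path).write_text(json.dumps(obj))


def write_assembly(
    subcomplex,
    reps: dict,
    definitions: Sequence[SubunitDefinition],
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write an assembled subcomplex as a multi-chain PDB (or mmCIF).

    Chain identifiers come from each subunit's ``chain_names`` (copy index i
    gets the i-th name); author numbering starts at ``start_res``.  A JSON
    sidecar records the score, confidence and assembly tree when
    ``metadata_path`` is given.
    """
    by_name = {d.name: d for d in definitions}
    chains = []
    bf = []
    for (name, copy), transform in sorted(subcomplex.placements.items()):
        d = by_name[name]
        if copy >= len(d.chain_names):
            raise ConfigFormatError(
                f"subunit {name!r}: copy {copy} has no chain name "
                f"(chain_names={list(d.chain_names)})"
            )
        rep = reps[name]
        coords = transform.apply(rep.backbone.reshape(-1, 3)).reshape(rep.backbone.shape)
        if not np.all(np.isfinite(coords)):
            raise ConfigFormatError(f"non-finite coordinates for {name!r} copy {copy}")
        chains.append((d.chain_names[copy], d.start_res, d.sequence, coords))
        bf.append(rep.plddt)
    write_structure(chains, path, bfactors=bf)
    if metadata_path is not None:
        Path(metadata_path).write_text(json.dumps(subcomplex.metadata(), indent=1))


def read_assembly_coords(
    path: str | Path,
) -> dict[str, np.ndarray]:
    """Read a written assembly back as ``chain_id -> (L, 4, 3)`` backbone."""
    st = gemmi.read_structure(str(path))
    out = {}
    for chain in st[0]:
        _, backbone = _chain_backbone(chain)
        out[chain.name] = backbone
    return out
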