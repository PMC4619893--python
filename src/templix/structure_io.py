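"""Structure and alignment I/O, and assembly of restraint sets.

PDB reading goes through Biopython's parser in strict mode (so malformed
records fail with the offending line identified); the in-memory model is a
flat :class:`StructureRecord` of C-alpha-era simplicity.  Alignments are a
TSV dialect carrying per-column posteriors plus global similarity and
homology probability in comment headers.

Atom-pair classes map to representative atoms: ``CA_CA`` uses the two
C-alpha atoms, ``N_O`` backbone N and O, and the side chain is represented
by C-beta for the ``SC_MC`` / ``SC_SC`` classes (glycine, lacking C-beta, is
skipped for side-chain classes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from templix.mdn import MixtureDensityNetwork
from templix.restraints import (
    AtomPairClass,
    PairId,
    RestraintItem,
    WeightedRestraintSet,
)
from templix.weighting import WeightedTemplateSet

logger = logging.getLogger(__name__)

#: representative atoms per class: (atom for residue i, atom for residue j)
CLASS_ATOMS = {
    AtomPairClass.CA_CA: ("CA", "CA"),
    AtomPairClass.N_O: ("N", "O"),
    AtomPairClass.SC_MC: ("CB", "CA"),
    AtomPairClass.SC_SC: ("CB", "CB"),
}

#: minimum |i - j| separation per class; adjacent residues are governed by
#: bonded geometry, not template restraints
DEFAULT_MIN_SEP = {
    AtomPairClass.CA_CA: 2,
    AtomPairClass.N_O: 1,
    AtomPairClass.SC_MC: 1,
    AtomPairClass.SC_SC: 1,
}


@dataclass(frozen=True)
class AtomRecord:
    res_idx: int
    res_name: str
    name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    bfactor: float = 0.0

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class StructureRecord:
    """One chain's atoms with author residue numbering preserved."""

    chain_id: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(f"non-finite coordinates for atom {a}")

    @property
    def residues(self) -> list[tuple[int, str]]:
        seen, out = set(), []
        for a in self.atoms:
            if a.res_idx not in seen:
                seen.add(a.res_idx)
                out.append((a.res_idx, a.res_name))
        return out

    def atom(self, res_idx: int, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.res_idx == res_idx and a.name == name:
                return a
        return None


def read_pdb(path, chain_id: str | None = None) -> StructureRecord:
    """Parse ATOM/HETATM records of one chain (first model).

    Alternate locations: the blank or 'A' altloc is kept, others are logged
    and dropped.  Malformed records raise with the file line identified
    (Biopython strict parsing).
    """
    import warnings as _warnings

    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

    parser = PDBParser(PERMISSIVE=False, QUIET=False)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            structure = parser.get_structure("s", str(path))
        except PDBConstructionException as exc:
            raise ValueError(f"malformed PDB record in {path}: {exc}") from exc
    model = next(iter(structure))
    chains = {c.id: c for c in model}
    if chain_id is None:
        chain = next(iter(model))
    elif chain_id in chains:
        chain = chains[chain_id]
    else:
        raise KeyError(f"chain {chain_id!r} not in {sorted(chains)}")
    atoms: list[AtomRecord] = []
    for residue in chain:
        res_idx = residue.id[1]
        for atom in residue.get_unpacked_list():
            altloc = atom.get_altloc()
            if altloc not in (" ", "A"):
                logger.info("dropping altloc %r of atom %s %d", altloc, atom.get_name(), res_idx)
                continue
            x, y, z = atom.get_coord()
            atoms.append(
                AtomRecord(
                    res_idx=res_idx,
                    res_name=residue.get_resname().strip(),
                    name=atom.get_name(),
                    element=atom.element or atom.get_name()[0],
                    x=float(x),
                    y=float(y),
                    z=float(z),
                    occupancy=float(atom.get_occupancy() or 1.0),
                    bfactor=float(atom.get_bfactor() or 0.0),
                )
            )
    return StructureRecord(chain_id=chain.id, atoms=atoms)


def write_pdb(record: StructureRecord, path) -> None:
    """Write fixed-column ATOM records (one chain, one model)."""
    lines = []
    for serial, a in enumerate(record.atoms, start=1):
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {name:<4s} {a.res_name:<3s} {record.chain_id:1s}"
            f"{a.res_idx:4d}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
            f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def coords_to_structure(
    coords: np.ndarray, chain_id: str = "A", res_name: str = "ALA"
) -> StructureRecord:
    """Wrap an (N, 3) C-alpha coordinate array as a StructureRecord."""
    atoms = [
        AtomRecord(res_idx=i + 1, res_name=res_name, name="CA", element="C",
                   x=float(x), y=float(y), z=float(z))
        for i, (x, y, z) in enumerate(np.asarray(coords, dtype=float))
    ]
    return StructureRecord(chain_id=chain_id, atoms=atoms)


# ---------------------------------------------------------------------------
# alignments


@dataclass
class PairAlignment:
    """Query-template alignment with per-column posteriors.

    ``columns`` holds (query residue i, template residue i', posterior pp);
    ``sim`` is the global sequence similarity in bits per aligned pair and
    ``p_hom`` the probability that the hit is homologous.
    """

    query_id: str
    template_id: str
    columns: list[tuple[int, int, float]]
    sim: float
    p_hom: float = 1.0

    def __post_init__(self) -> None:
        last = None
        for i, _ip, pp in self.columns:
            if last is not None and i <= last:
                raise ValueError("query indices must be strictly increasing")
            if not 0.0 <= pp <= 1.0:
                raise ValueError("pp must be in [0, 1]")
            last = i

    def template_index(self, i: int) -> int | None:
        for qi, ti, _pp in self.columns:
            if qi == i:
                return ti
        return None

    def pp_at(self, i: int) -> float | None:
        for qi, _ti, pp in self.columns:
            if qi == i:
                return pp
        return None

    def to_tsv(self) -> str:
        lines = [
            f"#query_id={self.query_id}",
            f"#template_id={self.template_id}",
            f"#sim={self.sim!r}",
            f"#p_hom={self.p_hom!r}",
            "query_idx\ttemplate_idx\tpp",
        ]
        for i, ti, pp in self.columns:
            lines.append(f"{i}\t{ti}\t{pp!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "PairAlignment":
        meta: dict[str, str] = {}
        cols = []
        header_seen = False
        for ln in text.splitlines():
            if not ln.strip():
                continue
            if ln.startswith("#"):
                key, _, val = ln[1:].partition("=")
                meta[key] = val
            elif not header_seen:
                if ln.split("\t") != ["query_idx", "template_idx", "pp"]:
                    raise ValueError("unrecognized alignment TSV header")
                header_seen = True
            else:
                i, ti, pp = ln.split("\t")
                cols.append((int(i), int(ti), float(pp)))
        return cls(
            query_id=meta.get("query_id", "query"),
            template_id=meta.get("template_id", "template"),
            columns=cols,
            sim=float(meta.get("sim", "0")),
            p_hom=float(meta.get("p_hom", "1")),
        )


# ---------------------------------------------------------------------------
# template distances and restraint assembly


def template_distances(
    structure: StructureRecord,
    alignment: PairAlignment,
    atom_class: AtomPairClass,
    min_sep: int | None = None,
):
    """Distances in the template for every restrainable aligned pair.

    Returns ``(pairs, n_skipped)`` where pairs is a list of
    ``(i, j, d_t)`` over aligned query pairs i < j whose representative atoms
    exist in the template; pairs with missing atoms (e.g. glycine C-beta for
    side-chain classes) are skipped and counted.
    """
    if min_sep is None:
        min_sep = DEFAULT_MIN_SEP[atom_class]
    atom_i_name, atom_j_name = CLASS_ATOMS[atom_class]
    aligned = [(i, ti) for i, ti, _pp in alignment.columns]
    pairs, skipped = [], 0
    for a in range(len(aligned)):
        for b in range(a + 1, len(aligned)):
            i, ti = aligned[a]
            j, tj = aligned[b]
            if abs(j - i) < min_sep:
                continue
            at_i = structure.atom(ti, atom_i_name)
            at_j = structure.atom(tj, atom_j_name)
            # glycine has no side chain: a GLY residue cannot carry the CB atom
            if at_i is None or at_j is None:
                skipped += 1
                continue
            d_t = float(np.linalg.norm(at_i.coords - at_j.coords))
            pairs.append((i, j, d_t))
    return pairs, skipped


def build_restraints(
    alignments: list[PairAlignment],
    structures: dict[str, StructureRecord],
    mdn_models: dict[AtomPairClass, MixtureDensityNetwork],
    weights: WeightedTemplateSet,
    atom_classes: list[AtomPairClass] | None = None,
    min_sep: dict[AtomPairClass, int] | None = None,
) -> list[WeightedRestraintSet]:
    """Assemble weighted restraint sets for all query pairs and templates.

    For each aligned query pair (i, j) covered by a template, the mixture
    density network of the pair's atom class is evaluated at
    ``(log d_t, pp_pair, sim)``, where ``pp_pair = min(pp_i, pp_j)``
    approximates the joint posterior that both columns are correct, and the
    result enters the pair's restraint set with the template's redundancy
    weight.  Output order is independent of template input order (sets are
    keyed and items sorted by template id).
    """
    if atom_classes is None:
        atom_classes = list(mdn_models.keys())
    sep = dict(DEFAULT_MIN_SEP)
    if min_sep:
        sep.update(min_sep)
    by_pair: dict[PairId, list[RestraintItem]] = {}
    for aln in alignments:
        try:
            w_templ = weights.weight(aln.template_id)
        except KeyError:
            raise KeyError(f"template {aln.template_id!r} has no weight") from None
        structure = structures[aln.template_id]
        for cls in atom_classes:
            model = mdn_models[cls]
            pairs, _skipped = template_distances(structure, aln, cls, min_sep=sep[cls])
            if not pairs:
                continue
            feats = np.array(
                [
                    [
                        np.log(d_t),
                        min(aln.pp_at(i), aln.pp_at(j)),
                        aln.sim,
                    ]
                    for i, j, d_t in pairs
                ]
            )
            params = model.predict_params(feats)
            atom_i, atom_j = CLASS_ATOMS[cls]
            for (i, j, _d_t), p in zip(pairs, params):
                pid = PairId(i=i, j=j, atom_i=atom_i, atom_j=atom_j, atom_class=cls)
                by_pair.setdefault(pid, []).append(
                    RestraintItem(params=p, weight=w_templ, template_id=aln.template_id)
                )
    out = []
    for pid in sorted(by_pair, key=lambda p: (p.atom_class.value, p.i, p.j)):
        items = sorted(by_pair[pid], key=lambda it: it.template_id)
        out.append(WeightedRestraintSet(pair=pid, items=items))
    return out
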