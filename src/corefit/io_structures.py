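"""PDB input/output at the Cα level.

Reads single structures and NMR multi-model ensembles through Bio.PDB, keeping
one Cα per standard residue (first/highest-occupancy altloc), and writes
superposed coordinates back out with the per-residue scales mapped into the
B-factor column so that viewers can colour the structural core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa

__all__ = [
    "CoordinateSet",
    "MatchedPair",
    "read_structure",
    "read_ensemble",
    "match_pair",
    "write_with_weights",
    "write_ensemble",
]


@dataclass(frozen=True)
class CoordinateSet:
    """Ordered Cα positions of one chain of one conformer.

    positions : (n, 3) float array, Ångström
    residue_ids : (n,) int array, strictly increasing residue numbers
    """

    positions: np.ndarray
    residue_ids: np.ndarray
    chain_id: str = "A"
    label: str = ""
    residue_names: tuple = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        ids = np.atleast_1d(np.asarray(self.residue_ids, dtype=int))
        if pos.shape[0] != ids.shape[0] or pos.shape[1] != 3:
            raise ValueError("positions must be (n, 3) with matching residue_ids")
        if pos.shape[0] < 1:
            raise ValueError("coordinate set must contain at least one position")
        if not np.all(np.isfinite(pos)):
            raise ValueError("coordinates must be finite")
        if np.any(np.diff(ids) <= 0):
            raise ValueError("residue_ids must be strictly increasing")
        names = self.residue_names
        if names is None:
            names = ("ALA",) * pos.shape[0]
        else:
            names = tuple(names)
            if len(names) != pos.shape[0]:
                raise ValueError("residue_names length mismatch")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "residue_ids", ids)
        object.__setattr__(self, "residue_names", names)

    def __len__(self) -> int:
        return self.positions.shape[0]

    def subset(self, mask: np.ndarray) -> "CoordinateSet":
        mask = np.asarray(mask, dtype=bool)
        return CoordinateSet(
            self.positions[mask],
            self.residue_ids[mask],
            self.chain_id,
            self.label,
            tuple(np.asarray(self.residue_names, dtype=object)[mask]),
        )


@dataclass(frozen=True)
class MatchedPair:
    """Two coordinate sets restricted to their common residues, in common order."""

    x: CoordinateSet
    y: CoordinateSet

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError("matched sets must have equal length")
        if not np.array_equal(self.x.residue_ids, self.y.residue_ids):
            raise ValueError("matched sets must share residue_ids")
        if len(self.x) < 3:
            raise ValueError(f"need >= 3 matched positions, got {len(self.x)}")

    @property
    def n(self) -> int:
        return len(self.x)

    def swap(self) -> "MatchedPair":
        return MatchedPair(self.y, self.x)


def _chain_calphas(chain) -> tuple[list, list, list]:
    """One Cα per standard residue; Bio.PDB's disordered-atom selection already
    keeps the highest-occupancy altloc."""
    pos, ids, names = [], [], []
    seen = set()
    for res in chain:
        if res.id[0] != " " or not is_aa(res, standard=True):
            continue
        if "CA" not in res:
            continue
        resseq = res.id[1]
        if resseq in seen:  # insertion-code duplicate: keep first occurrence
            continue
        seen.add(resseq)
        pos.append(res["CA"].coord.astype(float))
        ids.append(resseq)
        names.append(res.get_resname())
    return pos, ids, names


def _get_model(structure, model_index: int):
    models = list(structure)
    if not 0 <= model_index < len(models):
        raise ValueError(
            f"model index {model_index} out of range: file has {len(models)} model(s)"
        )
    return models[model_index]


def _select_chain(model, chain: str | None):
    if chain is not None:
        if chain not in model:
            present = ",".join(c.id for c in model)
            raise KeyError(f"chain {chain!r} not found (chains present: {present})")
        return model[chain]
    for c in model:  # default: first chain that carries Cα atoms
        if _chain_calphas(c)[0]:
            return c
    raise ValueError("no protein chain with Cα atoms found")


def read_structure(path, chain: str | None = None, model_index: int = 0) -> CoordinateSet:
    """Read the Cα trace of one chain of one model from a PDB file.

    ``chain=None`` selects the first protein chain; ``model_index`` counts
    MODEL records from 0 (X-ray entries have a single model).
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = _get_model(structure, model_index)
    c = _select_chain(model, chain)
    pos, ids, names = _chain_calphas(c)
    if not pos:
        raise ValueError(f"chain {c.id!r} contains no Cα atoms of standard residues")
    order = np.argsort(ids, kind="stable")
    return CoordinateSet(
        np.asarray(pos)[order],
        np.asarray(ids)[order],
        chain_id=c.id,
        label=str(path),
        residue_names=tuple(np.asarray(names, dtype=object)[order]),
    )


def read_ensemble(path, chain: str | None = None) -> list[CoordinateSet]:
    """Read every MODEL of a multi-model (NMR) PDB file as a CoordinateSet.

    Models are intersected on residue number, so all returned sets share an
    identical residue_id sequence.  Fails on single-model files.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    models = list(structure)
    if len(models) < 2:
        raise ValueError(f"expected a multi-model file, found {len(models)} model(s)")
    chain_id = _select_chain(models[0], chain).id
    sets = []
    for k, model in enumerate(models):
        c = _select_chain(model, chain_id)
        pos, ids, names = _chain_calphas(c)
        order = np.argsort(ids, kind="stable")
        sets.append(
            CoordinateSet(
                np.asarray(pos)[order],
                np.asarray(ids)[order],
                chain_id=chain_id,
                label=f"{path}#model{k}",
                residue_names=tuple(np.asarray(names, dtype=object)[order]),
            )
        )
    common = set(sets[0].residue_ids.tolist())
    for s in sets[1:]:
        common &= set(s.residue_ids.tolist())
    if len(common) < 3:
        raise ValueError(f"only {len(common)} residues common to all models")
    return [s.subset(np.isin(s.residue_ids, sorted(common))) for s in sets]


def match_pair(a: CoordinateSet, b: CoordinateSet) -> MatchedPair:
    """Restrict two coordinate sets to their common residue numbers."""
    common = np.intersect1d(a.residue_ids, b.residue_ids)
    if common.size < 3:
        raise ValueError(
            f"only {common.size} residues in common; need at least 3 to superpose"
        )
    return MatchedPair(
        a.subset(np.isin(a.residue_ids, common)),
        b.subset(np.isin(b.residue_ids, common)),
    )


def _scales_to_bfactors(scales: np.ndarray) -> np.ndarray:
    s = np.asarray(scales, dtype=float)
    lo, hi = s.min(), s.max()
    if hi - lo <= 0:
        return np.full(s.shape, 50.0)
    return 100.0 * (s - lo) / (hi - lo)


def _atom_line(serial, name, resname, chain, resseq, xyz, bfac) -> str:
    return (
        f"ATOM  {serial:5d} {name:^4s}{resname:>4s} {chain:1s}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{bfac:6.2f}"
        f"          {'C':>2s}\n"
    )


def write_with_weights(coords: CoordinateSet, transform, scales, path) -> None:
    """Write transformed Cα coordinates with scales in the B-factor column.

    Scales are min-max normalised to [0, 100] (PDB B-factor field width); the
    mapping is monotone, so large B-factor means large local stiffness.
    """
    s = np.asarray(scales, dtype=float)
    if s.shape != (len(coords),):
        raise ValueError("scales length must match coordinate set")
    pos = transform.apply(coords.positions)
    bfac = _scales_to_bfactors(s)
    with open(path, "w") as fh:
        for i in range(len(coords)):
            fh.write(
                _atom_line(
                    i + 1, "CA", coords.residue_names[i], coords.chain_id,
                    int(coords.residue_ids[i]), pos[i], bfac[i],
                )
            )
        fh.write("END\n")


def write_ensemble(conformers: list[CoordinateSet], path, scales=None) -> None:
    """Write conformers as a multi-model PDB (MODEL/ENDMDL blocks)."""
    if scales is not None:
        bfac = _scales_to_bfactors(np.asarray(scales, dtype=float))
    with open(path, "w") as fh:
        for k, c in enumerate(conformers):
            fh.write(f"MODEL     {k + 1:4d}\n")
            for i in range(len(c)):
                b = bfac[i] if scales is not None else 0.0
                fh.write(
                    _atom_line(
                        i + 1, "CA", c.residue_names[i], c.chain_id,
                        int(c.residue_ids[i]), c.positions[i], b,
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
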