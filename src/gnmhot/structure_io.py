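"""Read PDB files into Cα-trace chain objects and read/write hot-spot label files.

The package works on a coarse-grained view of a protein chain: one node per
residue, placed at the Cα position.  Everything downstream (the Kirchhoff
matrix, normal modes, features) is indexed by position in the retained Cα
list, while user-facing output keeps the original residue numbering.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Union

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

logger = logging.getLogger(__name__)

__all__ = [
    "CaChain",
    "LabelSet",
    "StructureError",
    "ChainNotFoundError",
    "ChainTooShortError",
    "PDBFormatError",
    "LabelFormatError",
    "read_ca_chain",
    "read_labels",
    "write_labels",
]

ResidueKey = tuple[str, int, str]  # (chain_id, residue_number, insertion_code)


class StructureError(ValueError):
    """Base class for structure and label input errors."""


class ChainNotFoundError(StructureError):
    pass


class ChainTooShortError(StructureError):
    pass


class PDBFormatError(StructureError):
    pass


class LabelFormatError(StructureError):
    pass


@dataclass(frozen=True)
class CaChain:
    """Ordered Cα trace of one protein chain.

    Parameters
    ----------
    chain_id:
        Chain label as it appears in the source file.
    residues:
        Ordered ``(residue_number, insertion_code, residue_name)`` tuples,
        following ATOM-record order.
    coords:
        ``(N, 3)`` array of Cα positions in Å.
    """

    chain_id: str
    residues: tuple[tuple[int, str, str], ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise StructureError(f"coords must be (N, 3), got {coords.shape}")
        if len(self.residues) != coords.shape[0]:
            raise StructureError(
                f"{len(self.residues)} residue ids vs {coords.shape[0]} coordinate rows"
            )
        if coords.shape[0] < 2:
            raise ChainTooShortError(
                f"chain too short: chain {self.chain_id!r} has "
                f"{coords.shape[0]} Cα residue(s), need at least 2"
            )
        keys = [(num, icode) for num, icode, _ in self.residues]
        if len(set(keys)) != len(keys):
            raise StructureError(f"duplicate residue identifiers in chain {self.chain_id!r}")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_residues

    def residue_keys(self) -> list[ResidueKey]:
        """Label-join keys, one per retained residue."""
        return [(self.chain_id, num, icode) for num, icode, _ in self.residues]


@dataclass
class LabelSet:
    """Binary hot-spot labels keyed by (chain_id, residue_number, insertion_code).

    ``1`` marks a hot spot.  Residues absent from the set default to 0 when
    joined against a chain.
    """

    labels: dict[ResidueKey, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self.labels

    def set(self, chain_id: str, residue_number: int, label: int, insertion_code: str = "") -> None:
        if label not in (0, 1):
            raise LabelFormatError(f"label must be 0 or 1, got {label!r}")
        self.labels[(chain_id, residue_number, insertion_code)] = int(label)

    def join(self, chain: CaChain, strict: bool = True) -> np.ndarray:
        """Per-residue label vector for ``chain``; unlisted residues get 0.

        With ``strict`` (default), labels recorded for this chain id that do
        not match any retained residue raise — a mismatch usually means the
        wrong chain or numbering scheme was supplied.
        """
        keys = chain.residue_keys()
        y = np.array([self.labels.get(k, 0) for k in keys], dtype=int)
        if strict:
            known = set(keys)
            orphans = [k for k in self.labels if k[0] == chain.chain_id and k not in known]
            if orphans:
                raise StructureError(
                    f"labels reference residues absent from chain {chain.chain_id!r}: "
                    f"{sorted(orphans)[:5]}"
                )
        return y

    def positive_count(self) -> int:
        return sum(self.labels.values())


def _select_ca(residue):
    """Pick the CA atom; for altlocs, highest occupancy wins, ties to the first listed."""
    if "CA" not in residue:
        return None
    atom = residue["CA"]
    if atom.is_disordered():
        children = atom.disordered_get_list()
        best = children[0]
        for child in children[1:]:
            occ_b = best.get_occupancy() or 0.0
            occ_c = child.get_occupancy() or 0.0
            if occ_c > occ_b:
                best = child
        return best
    return atom


def read_ca_chain(
    pdb_source: Union[str, IO[str]],
    chain_id: str,
    model_index: int = 0,
) -> CaChain:
    """Parse one chain of a PDB file into a :class:`CaChain`.

    Only ATOM records with a CA atom contribute; HETATM records and residues
    without a Cα are skipped (with a logged warning).  ``model_index`` selects
    a model of a multi-model file by position (default: first).
    """
    if isinstance(pdb_source, str):
        handle: IO[str] = io.StringIO(pdb_source) if "\n" in pdb_source else open(pdb_source)
    else:
        handle = pdb_source
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure("input", handle)
    except PDBConstructionException as exc:
        raise PDBFormatError(f"PDB format error: {exc}") from exc
    finally:
        if isinstance(pdb_source, str):
            handle.close()

    models = list(structure)
    if not models:
        raise PDBFormatError("PDB source contains no models")
    if model_index >= len(models):
        raise PDBFormatError(
            f"model index {model_index} out of range ({len(models)} model(s) present)"
        )
    model = models[model_index]

    chain = None
    for candidate in model:
        if candidate.id == chain_id:
            chain = candidate
            break
    if chain is None:
        available = ", ".join(repr(c.id) for c in model)
        raise ChainNotFoundError(
            f"chain not found: {chain_id!r} (available: {available or 'none'})"
        )

    residues: list[tuple[int, str, str]] = []
    coords: list[np.ndarray] = []
    for residue in chain:
        hetfield, resseq, icode = residue.id
        if hetfield.strip():  # HETATM / water
            continue
        atom = _select_ca(residue)
        if atom is None:
            logger.warning(
                "chain %s residue %s%s has no CA atom; skipped", chain_id, resseq, icode.strip()
            )
            continue
        residues.append((resseq, icode.strip(), residue.get_resname().strip()))
        coords.append(np.asarray(atom.get_coord(), dtype=float))

    if len(coords) < 2:
        raise ChainTooShortError(
            f"chain too short: chain {chain_id!r} has {len(coords)} Cα residue(s), need at least 2"
        )
    return CaChain(chain_id=chain_id, residues=tuple(residues), coords=np.array(coords))


def _tokens(line: str) -> list[str]:
    return line.replace(",", " ").split()


def read_labels(label_source: Union[str, IO[str], Iterable[str]]) -> LabelSet:
    """Read a hot-spot label file.

    One residue per row: ``chain_id residue_number [insertion_code] label``,
    whitespace- or comma-delimited; lines starting with ``#`` are comments.
    """
    if isinstance(label_source, str):
        if "\n" in label_source or not label_source:
            lines: Iterable[str] = label_source.splitlines()
        else:
            with open(label_source) as fh:
                lines = fh.read().splitlines()
    elif hasattr(label_source, "read"):
        lines = label_source.read().splitlines()
    else:
        lines = list(label_source)

    labels = LabelSet()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = _tokens(line)
        if len(parts) == 3:
            chain_id, num_s, label_s = parts
            icode = ""
        elif len(parts) == 4:
            chain_id, num_s, icode, label_s = parts
            if icode in ("-", "."):  # placeholder for a blank insertion code
                icode = ""
        else:
            raise LabelFormatError(f"row {lineno}: expected 3 or 4 fields, got {len(parts)}")
        try:
            resnum = int(num_s)
        except ValueError as exc:
            raise LabelFormatError(f"row {lineno}: bad residue number {num_s!r}") from exc
        if label_s not in ("0", "1"):
            raise LabelFormatError(f"row {lineno}: label must be 0 or 1, got {label_s!r}")
        labels.labels[(chain_id, resnum, icode)] = int(label_s)
    return labels


def write_labels(labels: Union[LabelSet, Mapping[ResidueKey, int]], sink: Union[str, IO[str]]) -> None:
    """Write labels in the same delimited format :func:`read_labels` accepts."""
    mapping = labels.labels if isinstance(labels, LabelSet) else dict(labels)
    own = isinstance(sink, str)
    fh = open(sink, "w") if own else sink
    try:
        fh.write("# chain_id residue_number insertion_code label\n")
        for (chain_id, resnum, icode), y in sorted(mapping.items()):
            fh.write(f"{chain_id} {resnum} {icode or '-'} {y}\n")
    finally:
        if own:
            fh.close()
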