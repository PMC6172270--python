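"""Residue-residue contact extraction from protein complex structures.

A complex is split into two chain groups (the two interacting sides).  Each
standard residue is reduced to a single representative coordinate — its
C-beta atom, or C-alpha for glycine — and every cross-side residue pair is
labeled *positive* (in contact) when the Euclidean distance between the
representative atoms is strictly below a threshold (6 A by default),
*negative* otherwise.  Positive pairs accumulated over a training set form
the 20x20 residue-type contact frequency matrix that seeds the statistical
analysis downstream.

Conventions the source structures leave open are fixed here: only the first
model of a multi-model file is read; alternate locations are resolved to the
highest-occupancy conformer (ties broken by altloc identifier); HETATM and
non-standard residues are skipped; non-glycine residues lacking a C-beta are
skipped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .alphabet import ALPHABET, INDEX, THREE_TO_ONE

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_THRESHOLD = 6.0  # Angstrom, strict '<'

POSITIVE = "positive"
NEGATIVE = "negative"


class StructureFormatError(ValueError):
    """Raised when the input contains no parsable standard-residue records."""


class MissingChainError(ValueError):
    """Raised when a requested chain group is absent from the structure."""


@dataclass(frozen=True)
class ResidueSite:
    """One standard residue reduced to its representative atom.

    ``residue_number`` follows author numbering as deposited, together with
    an optional insertion code.
    """

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_type: str
    representative_coordinate: np.ndarray

    def __post_init__(self) -> None:
        if self.residue_type not in INDEX:
            raise ValueError(f"non-standard residue type {self.residue_type!r}")
        coord = np.asarray(self.representative_coordinate, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError("representative coordinate must be a finite 3-vector")
        object.__setattr__(self, "representative_coordinate", coord)

    @property
    def label(self) -> str:
        icode = self.insertion_code.strip()
        return f"{self.chain_id}{self.residue_number}{icode}"


@dataclass
class ComplexStructure:
    """A parsed complex: residue sites grouped into two interacting sides."""

    identifier: str
    sites: list[ResidueSite]
    chain_group_a: frozenset[str]
    chain_group_b: frozenset[str]

    def __post_init__(self) -> None:
        if self.chain_group_a & self.chain_group_b:
            raise ValueError("chain groups must be disjoint")

    def side(self, which: str) -> list[ResidueSite]:
        group = self.chain_group_a if which == "a" else self.chain_group_b
        return [s for s in self.sites if s.chain_id in group]

    def sequences(self) -> tuple[str, str]:
        """One-letter sequences of side A and side B in site order."""
        return (
            "".join(s.residue_type for s in self.side("a")),
            "".join(s.residue_type for s in self.side("b")),
        )


@dataclass(frozen=True)
class LabeledPair:
    """A cross-side residue pair with its distance and contact label."""

    site_a: ResidueSite
    site_b: ResidueSite
    distance: float
    label: str

    @property
    def type_pair(self) -> tuple[str, str]:
        return (self.site_a.residue_type, self.site_b.residue_type)


@dataclass
class ContactFrequencyMatrix:
    """20x20 symmetric counts of residue-type contacts (o_ij).

    Each unordered contact between distinct types increments both symmetric
    cells once; a same-type contact increments the diagonal once.  ``total``
    is the number of contacts the matrix was built from.
    """

    counts: np.ndarray
    total: int
    alphabet_order: str = ALPHABET

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.alphabet_order)
        if self.counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")

    @property
    def grand_total(self) -> int:
        """Sum of all cells (off-diagonal contacts are counted twice)."""
        return int(self.counts.sum())

    def n_contacts(self) -> int:
        """Number of unordered contacts recovered from the entries."""
        off = int(self.counts.sum() - np.trace(self.counts))
        if off % 2:
            raise ValueError("off-diagonal sum must be even for a mirrored matrix")
        return off // 2 + int(np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        letters = list(self.alphabet_order)
        return pd.DataFrame(self.counts, index=letters, columns=letters)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="")

    @classmethod
    def from_tsv(cls, path) -> "ContactFrequencyMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        order = "".join(frame.index)
        counts = frame.to_numpy(dtype=int)
        total = int(counts.sum() - np.trace(counts)) // 2 + int(np.trace(counts))
        return cls(counts=counts, total=total, alphabet_order=order)


def representative_coordinate(
    atoms: dict[str, np.ndarray], residue_type: str
) -> np.ndarray | None:
    """Representative coordinate of a residue: CB, or CA for glycine.

    Parameters
    ----------
    atoms
        Mapping from atom name to 3-vector coordinate.
    residue_type
        One-letter code of the residue.

    Returns
    -------
    The coordinate, or ``None`` when the required atom is absent (the
    residue is then skipped by the caller).
    """
    name = "CA" if residue_type == "G" else "CB"
    coord = atoms.get(name)
    if coord is None:
        logger.warning("residue type %s lacks required atom %s; skipped",
                       residue_type, name)
        return None
    return np.asarray(coord, dtype=float)


def _pick_altloc(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; equal occupancies fall back to altloc order
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


def parse_structure(
    pdb_text: str,
    chain_group_a: Iterable[str],
    chain_group_b: Iterable[str],
    identifier: str = "",
) -> ComplexStructure:
    """Parse PDB ATOM records into a two-sided :class:`ComplexStructure`.

    Only the first model is read.  HETATM records, non-standard residues and
    waters are ignored.  Alternate locations resolve to the conformer with
    the highest occupancy.  Chains outside the two groups are dropped.

    Raises
    ------
    MissingChainError
        If any requested chain id does not occur in the file.
    StructureFormatError
        If no standard residues can be parsed at all.
    """
    group_a = frozenset(chain_group_a)
    group_b = frozenset(chain_group_b)
    if not group_a or not group_b:
        raise ValueError("both chain groups must be non-empty")

    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise StructureFormatError("no models found in structure input")
    model = structure[0]

    seen_chains = {chain.name for chain in model}
    for group in (group_a, group_b):
        missing = group - seen_chains
        if missing:
            raise MissingChainError(
                f"chain(s) {sorted(missing)} not present; file has {sorted(seen_chains)}"
            )

    wanted = group_a | group_b
    sites: list[ResidueSite] = []
    for chain in model:
        if chain.name not in wanted:
            continue
        for residue in chain:
            if residue.het_flag == "H":
                continue
            one = THREE_TO_ONE.get(residue.name)
            if one is None:
                logger.info("skipping non-standard residue %s %s%d",
                            residue.name, chain.name, residue.seqid.num)
                continue
            target = "CA" if one == "G" else "CB"
            candidates = [a for a in residue if a.name == target]
            atoms = {}
            if candidates:
                atom = _pick_altloc(candidates)
                atoms[target] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            coord = representative_coordinate(atoms, one)
            if coord is None:
                continue
            icode = residue.seqid.icode.strip() or ""
            sites.append(
                ResidueSite(
                    chain_id=chain.name,
                    residue_number=residue.seqid.num,
                    insertion_code=icode,
                    residue_type=one,
                    representative_coordinate=coord,
                )
            )

    if not sites:
        raise StructureFormatError("no standard residues with ATOM records parsed")
    return ComplexStructure(
        identifier=identifier or structure.name or "complex",
        sites=sites,
        chain_group_a=group_a,
        chain_group_b=group_b,
    )


def extract_labeled_pairs(
    complex_structure: ComplexStructure,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
) -> list[LabeledPair]:
    """Label every cross-side residue pair by the strict-< distance rule.

    Returns exactly ``|side A| * |side B|`` pairs in row-major order (side A
    outer, side B inner).  A pair at exactly the threshold is negative.
    """
    side_a = complex_structure.side("a")
    side_b = complex_structure.side("b")
    if not side_a or not side_b:
        raise ValueError("both sides must contain at least one residue")

    coords_a = np.stack([s.representative_coordinate for s in side_a])
    coords_b = np.stack([s.representative_coordinate for s in side_b])
    diff = coords_a[:, None, :] - coords_b[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))

    pairs = []
    for i, sa in enumerate(side_a):
        for j, sb in enumerate(side_b):
            d = float(dist[i, j])
            pairs.append(
                LabeledPair(
                    site_a=sa,
                    site_b=sb,
                    distance=d,
                    label=POSITIVE if d < threshold else NEGATIVE,
                )
            )
    return pairs


def build_contact_frequency_matrix(
    pairs: Iterable[LabeledPair | tuple[str, str]],
) -> ContactFrequencyMatrix:
    """Accumulate positive contacts into the 20x20 frequency matrix.

    Accepts :class:`LabeledPair` objects (which must be positive) or bare
    ``(type_a, type_b)`` letter tuples.  Each unordered contact is counted
    once and mirrored into both symmetric cells; same-type contacts go to
    the diagonal.  An empty input yields the zero matrix.
    """
    n = len(ALPHABET)
    counts = np.zeros((n, n), dtype=int)
    total = 0
    for pair in pairs:
        if isinstance(pair, LabeledPair):
            if pair.label != POSITIVE:
                raise ValueError("contact matrix is built from positive pairs only")
            a, b = pair.type_pair
        else:
            a, b = pair
        ia, ib = INDEX[a], INDEX[b]
        if ia == ib:
            counts[ia, ia] += 1
        else:
            counts[ia, ib] += 1
            counts[ib, ia] += 1
        total += 1
    return ContactFrequencyMatrix(counts=counts, total=total)


def pairs_to_frame(pairs: Iterable[LabeledPair]) -> pd.DataFrame:
    """Tabulate labeled pairs for TSV export."""
    rows = [
        {
            "chain_a": p.site_a.chain_id,
            "resnum_a": p.site_a.residue_number,
            "icode_a": p.site_a.insertion_code,
            "restype_a": p.site_a.residue_type,
            "chain_b": p.site_b.chain_id,
            "resnum_b": p.site_b.residue_number,
            "icode_b": p.site_b.insertion_code,
            "restype_b": p.site_b.residue_type,
            "distance": round(p.distance, 4),
            "label": p.label,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows)
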