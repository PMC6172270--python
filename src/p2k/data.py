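"""Sequence-level training samples derived from labeled complexes."""

from __future__ import annotations

from dataclasses import dataclass, field

from .contacts import POSITIVE, ComplexStructure, LabeledPair


@dataclass
class ComplexSample:
    """One complex reduced to its two sequences and positive pair set.

    ``positives`` holds 0-based ``(i, j)`` index pairs into ``seq_a`` and
    ``seq_b``; every other cross pair is implicitly negative.  This is all
    the predictor needs — geometry is consumed upstream when the labels are
    derived.
    """

    identifier: str
    seq_a: str
    seq_b: str
    positives: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for i, j in self.positives:
            if not (0 <= i < len(self.seq_a) and 0 <= j < len(self.seq_b)):
                raise ValueError(f"positive pair ({i}, {j}) out of sequence bounds")

    @property
    def n_pairs(self) -> int:
        return len(self.seq_a) * len(self.seq_b)

    def positive_type_pairs(self) -> list[tuple[str, str]]:
        """Residue-type letter pairs of the positive contacts."""
        return [(self.seq_a[i], self.seq_b[j]) for i, j in sorted(self.positives)]

    def label(self, i: int, j: int) -> bool:
        return (i, j) in self.positives


def sample_from_structure(
    structure: ComplexStructure, pairs: list[LabeledPair]
) -> ComplexSample:
    """Collapse a parsed complex and its labeled pairs into a sample.

    ``pairs`` must be the row-major output of ``extract_labeled_pairs`` for
    this structure, so pair order maps directly onto sequence positions.
    """
    seq_a, seq_b = structure.sequences()
    n_b = len(seq_b)
    if len(pairs) != len(seq_a) * n_b:
        raise ValueError("pairs do not cover the full cross product of the sides")
    positives = frozenset(
        (idx // n_b, idx % n_b)
        for idx, pair in enumerate(pairs)
        if pair.label == POSITIVE
    )
    return ComplexSample(
        identifier=structure.identifier,
        seq_a=seq_a,
        seq_b=seq_b,
        positives=positives,
    )
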