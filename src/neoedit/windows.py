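"""Protein substitution variants and their 9-mer peptide windows.

A missense substitution at residue ``p`` of a protein can appear in any 9-mer
peptide whose span contains ``p``.  For an interior residue (at least nine
residues from both termini) there are exactly nine such windows, and the
minimal subsequence covering all of them is the 17-mer centred on the mutated
residue.  Near the termini fewer windows exist; they are kept, not discarded.

Coordinates are 1-based and inclusive on protein residues throughout, matching
conventional protein-variant notation (e.g. BRAF V600E means residue 600).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

EPITOPE_LENGTH = 9
#: flank needed so that every epitope containing the mutated residue is covered
CONTEXT_FLANK = EPITOPE_LENGTH - 1

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)


class VariantValidationError(ValueError):
    """A variant record is inconsistent with its protein sequence."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier matching the variant table."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def noncanonical_positions(self) -> tuple[int, ...]:
        """1-based positions holding letters outside the 20 canonical amino acids."""
        return tuple(
            i + 1 for i, aa in enumerate(self.sequence) if aa not in _CANONICAL_SET
        )


@dataclass(frozen=True)
class VariantRecord:
    """A single-residue protein substitution and its cohort occurrences.

    ``occurrences`` holds ``(patient_id, histology)`` pairs, one per tumor in
    which the variant was observed.
    """

    gene: str
    position: int  # 1-based residue index
    ref_aa: str
    alt_aa: str
    occurrences: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    @property
    def variant_id(self) -> str:
        return f"{self.gene}:{self.ref_aa}{self.position}{self.alt_aa}"

    @property
    def n_occurrences(self) -> int:
        return len(self.occurrences)


@dataclass(frozen=True)
class PeptideWindow:
    """One mutant/wild-type 9-mer pair covering a substitution.

    ``offset`` is the 1-based position of the mutated residue within the
    window (1..9); mutant and wild-type peptides differ exactly there.
    """

    variant_id: str
    start: int  # 1-based start on the protein
    mutant: str
    wildtype: str
    offset: int


def context_window(protein: ProteinRecord, position: int) -> str:
    """Minimal subsequence covering every 9-mer that contains ``position``.

    Spans residues ``max(1, position-8) .. min(L, position+8)``: 17 residues
    for interior positions, shorter when clipped by a terminus.
    """
    length = len(protein)
    if not 1 <= position <= length:
        raise VariantValidationError(
            f"position {position} outside protein {protein.id!r} of length {length}"
        )
    lo = max(1, position - CONTEXT_FLANK)
    hi = min(length, position + CONTEXT_FLANK)
    return protein.sequence[lo - 1 : hi]


def window_starts(position: int, length: int) -> range:
    """1-based start coordinates of all 9-mers containing ``position``."""
    return range(max(1, position - CONTEXT_FLANK), min(position, length - CONTEXT_FLANK) + 1)


def enumerate_9mers(protein: ProteinRecord, variant: VariantRecord) -> list[PeptideWindow]:
    """All mutant/wild-type 9-mer window pairs for a validated variant.

    Interior variants on proteins of length >= 17 yield exactly nine windows
    (offsets 9 down to 1); variants within eight residues of a terminus yield
    fewer.  Raises for proteins shorter than nine residues or on a reference
    mismatch.
    """
    length = len(protein)
    if length < EPITOPE_LENGTH:
        raise VariantValidationError(
            f"protein {protein.id!r} has length {length} < {EPITOPE_LENGTH}; no 9-mers exist"
        )
    pos = variant.position
    if not 1 <= pos <= length:
        raise VariantValidationError(
            f"{variant.variant_id}: position {pos} outside protein of length {length}"
        )
    observed = protein.sequence[pos - 1]
    if observed != variant.ref_aa:
        raise VariantValidationError(
            f"{variant.variant_id}: reference {variant.ref_aa!r} does not match "
            f"sequence {observed!r} at position {pos}"
        )
    mutated = protein.sequence[: pos - 1] + variant.alt_aa + protein.sequence[pos:]
    out = []
    for start in window_starts(pos, length):
        wt = protein.sequence[start - 1 : start - 1 + EPITOPE_LENGTH]
        mut = mutated[start - 1 : start - 1 + EPITOPE_LENGTH]
        out.append(
            PeptideWindow(
                variant_id=variant.variant_id,
                start=start,
                mutant=mut,
                wildtype=wt,
                offset=pos - start + 1,
            )
        )
    return out


def validate_variants(
    proteins: Mapping[str, ProteinRecord] | Iterable[ProteinRecord],
    variants: Iterable[VariantRecord],
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Partition variants into valid records and rejected rows with reasons.

    Rejection classes: ``unknown protein``, ``out of bounds``, ``ref mismatch``,
    ``not a substitution`` (ref == alt, or multi-letter / non-canonical
    alleles), ``non-canonical context`` (context window contains letters
    outside the canonical alphabet).  Returns ``(valid, rejected)`` where
    ``rejected`` is a DataFrame with columns ``variant_id`` and ``reason``.
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.id: p for p in proteins}
    valid: list[VariantRecord] = []
    rejected: list[tuple[str, str]] = []
    for v in variants:
        protein = proteins.get(v.gene)
        if protein is None:
            rejected.append((v.variant_id, "unknown protein"))
            continue
        if (
            len(v.ref_aa) != 1
            or len(v.alt_aa) != 1
            or v.ref_aa not in _CANONICAL_SET
            or v.alt_aa not in _CANONICAL_SET
            or v.ref_aa == v.alt_aa
        ):
            rejected.append((v.variant_id, "not a substitution"))
            continue
        if not 1 <= v.position <= len(protein):
            rejected.append((v.variant_id, "out of bounds"))
            continue
        if protein.sequence[v.position - 1] != v.ref_aa:
            rejected.append((v.variant_id, "ref mismatch"))
            continue
        context = context_window(protein, v.position)
        if any(aa not in _CANONICAL_SET for aa in context):
            rejected.append((v.variant_id, "non-canonical context"))
            continue
        valid.append(v)
    rejected_df = pd.DataFrame(rejected, columns=["variant_id", "reason"])
    return valid, rejected_df


def windows_frame(
    proteins: Mapping[str, ProteinRecord] | Iterable[ProteinRecord],
    variants: Sequence[VariantRecord],
) -> pd.DataFrame:
    """Tidy table of all peptide windows for a set of validated variants.

    Columns: variant_id, start, offset, mutant, wildtype.
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.id: p for p in proteins}
    rows = []
    for v in variants:
        for w in enumerate_9mers(proteins[v.gene], v):
            rows.append((w.variant_id, w.start, w.offset, w.mutant, w.wildtype))
    return pd.DataFrame(rows, columns=["variant_id", "start", "offset", "mutant", "wildtype"])
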