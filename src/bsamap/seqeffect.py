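"""Coding consequence of a deletion within a CDS.

Given a reference coding sequence, a deletion interval on it (1-based,
inclusive, the convention used when reporting indel coordinates on a CDS)
and protein domain annotations, this module decides whether the deletion
shifts the reading frame (length not divisible by 3), where translation of
the mutant stops, how long the truncated protein is, and which domains are
lost downstream of the new stop.

The deletion studied here is the canonical case: a 13 bp deletion is a
frameshift (13 mod 3 = 1) that typically exposes a premature stop codon in
the shifted frame and truncates the protein, deleting its C-terminal
domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Seq import Seq

__all__ = [
    "DomainAnnotation",
    "LostDomain",
    "CodingEffect",
    "apply_deletion",
    "translate_cds",
    "classify_effect",
]

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class DomainAnnotation:
    """A protein domain in 1-based inclusive residue coordinates."""

    name: str
    start_aa: int
    end_aa: int

    def __post_init__(self) -> None:
        if not (1 <= self.start_aa <= self.end_aa):
            raise ValueError(
                f"domain {self.name}: need 1 <= start_aa <= end_aa, "
                f"got {self.start_aa}..{self.end_aa}"
            )


@dataclass(frozen=True)
class LostDomain:
    """A domain truncated away in the mutant protein.

    ``partial`` is True when the truncation falls inside the domain
    (N-terminal part retained) rather than removing it entirely.
    """

    name: str
    partial: bool


@dataclass(frozen=True)
class CodingEffect:
    """Classification of a CDS deletion.

    ``stop_codon_position`` is the 1-based position on the mutant CDS of
    the first base of the stop codon that terminates translation, or None
    if the mutant has no in-frame stop.
    """

    deletion_start: int
    deletion_end: int
    deleted_length: int
    frameshift: bool
    stop_codon_position: int | None
    protein_length_ref: int
    protein_length_mut: int
    lost_domains: tuple[LostDomain, ...]


def _check_bases(seq: str, what: str) -> None:
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(
            f"{what} contains characters outside ACGT: {sorted(bad)} "
            "(ambiguity codes are rejected, not guessed)"
        )


def apply_deletion(cds: str, start: int, end: int) -> str:
    """Remove positions ``start..end`` (1-based, inclusive) from a sequence.

    >>> apply_deletion("ATGAAACCC", 4, 6)
    'ATGCCC'
    """
    if not (1 <= start <= end <= len(cds)):
        raise ValueError(
            f"deletion {start}..{end} out of range for a {len(cds)} bp sequence"
        )
    return cds[: start - 1] + cds[end:]


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard genetic code up to the first stop.

    Codons are read from position 1; the stop codon is not included in the
    returned protein; a trailing partial codon is ignored.  Sequences
    shorter than one codon translate to the empty protein (with a warning).
    """
    _check_bases(cds, "CDS")
    if len(cds) < 3:
        warnings.warn("CDS shorter than one codon; returning empty protein")
        return ""
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate(to_stop=True))


def _first_stop_position(cds: str) -> int | None:
    """1-based position of the first base of the first in-frame stop codon."""
    for i in range(0, len(cds) - len(cds) % 3, 3):
        if cds[i : i + 3] in _STOP_CODONS:
            return i + 1
    return None


def classify_effect(
    ref_cds: str,
    mutant_cds: str,
    deletion_start: int,
    deletion_end: int,
    domains: list[DomainAnnotation] | tuple[DomainAnnotation, ...] = (),
) -> CodingEffect:
    """Classify the coding consequence of a deletion.

    The mutant must equal the reference with ``deletion_start..deletion_end``
    removed; any inconsistency raises.  A domain is lost iff its last
    residue lies beyond the mutant protein's last residue; a domain whose
    start is still translated is reported lost with ``partial=True``.
    """
    _check_bases(ref_cds, "reference CDS")
    _check_bases(mutant_cds, "mutant CDS")
    deleted_length = deletion_end - deletion_start + 1
    expected = apply_deletion(ref_cds, deletion_start, deletion_end)
    if mutant_cds != expected:
        if len(mutant_cds) != len(ref_cds) - deleted_length:
            raise ValueError(
                f"mutant length {len(mutant_cds)} inconsistent with a "
                f"{deleted_length} bp deletion from a {len(ref_cds)} bp reference"
            )
        raise ValueError(
            "mutant CDS is not the reference with the stated deletion applied"
        )

    protein_ref = translate_cds(ref_cds)
    protein_mut = translate_cds(mutant_cds) if len(mutant_cds) >= 3 else ""
    len_mut = len(protein_mut)

    lost = []
    for dom in domains:
        if dom.end_aa > len(protein_ref):
            raise ValueError(
                f"domain {dom.name} ends at residue {dom.end_aa} beyond the "
                f"{len(protein_ref)}-residue reference protein"
            )
        if dom.end_aa > len_mut:
            lost.append(LostDomain(dom.name, partial=dom.start_aa <= len_mut))

    return CodingEffect(
        deletion_start=deletion_start,
        deletion_end=deletion_end,
        deleted_length=deleted_length,
        frameshift=deleted_length % 3 != 0,
        stop_codon_position=_first_stop_position(mutant_cds),
        protein_length_ref=len(protein_ref),
        protein_length_mut=len_mut,
        lost_domains=tuple(lost),
    )
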