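"""Marker-based fine mapping of a recessive locus and CAPS utilities.

After a genome-wide bulked-segregant scan points at a chromosome region,
the locus is narrowed by genotyping a segregating population at codominant
markers (CAPS or InDel) across the region.  Under a recessive model every
short-phenotype individual must be homozygous for the short-parent allele
(code B) at the causal position, and every long-phenotype individual must
not be; a marker contradicted by at least one individual therefore lies on
the far side of a crossover from the locus, and the nearest contradicted
markers on each side bound the causal interval.

CAPS (cleaved amplified polymorphic sequence) markers are scored by
restriction digestion of a PCR amplicon: a SNP that creates or destroys an
enzyme recognition site changes the fragment pattern on a gel.  The
in-silico digest here reproduces that fragment arithmetic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segregation import SegregationResult, chi_square_gof

__all__ = [
    "MarkerGenotypeTable",
    "IntervalResult",
    "CapsAssay",
    "CosegregationSummary",
    "caps_digest",
    "caps_polymorphic",
    "find_recombinants",
    "narrow_interval",
    "cosegregation_summary",
]

GENOTYPE_CODES = frozenset({"A", "H", "B", "-"})
MISSING = "-"
_VALID_BASES = frozenset("ACGT")


@dataclass
class MarkerGenotypeTable:
    """Individuals x ordered markers with codes {A, H, B, -} and phenotypes.

    ``genotypes``: DataFrame indexed by individual id, one column per
    marker name.  ``markers``: DataFrame with columns name, chromosome,
    position (sorted by chromosome then position).  ``phenotypes``:
    Series of "long"/"short" indexed like ``genotypes``.
    """

    genotypes: pd.DataFrame
    markers: pd.DataFrame
    phenotypes: pd.Series

    def __post_init__(self) -> None:
        self.markers = (
            self.markers.sort_values(["chromosome", "position"], kind="stable")
            .reset_index(drop=True)
        )
        if list(self.genotypes.columns) != list(self.markers["name"]):
            self.genotypes = self.genotypes[list(self.markers["name"])]
        if not self.phenotypes.index.equals(self.genotypes.index):
            raise ValueError("phenotypes must cover exactly the genotyped individuals")
        bad_pheno = set(self.phenotypes) - {"long", "short"}
        if bad_pheno:
            raise ValueError(f"unknown phenotypes: {sorted(bad_pheno)}")
        if len(self.genotypes.columns):
            bad = set(np.unique(self.genotypes.values)) - GENOTYPE_CODES
            if bad:
                raise ValueError(f"unknown genotype codes: {sorted(bad)}")

    @property
    def individuals(self) -> list[str]:
        return list(self.genotypes.index)

    def marker_row(self, name: str) -> pd.Series:
        rows = self.markers[self.markers["name"] == name]
        if rows.empty:
            raise KeyError(f"unknown marker {name}")
        return rows.iloc[0]

    def codes(self, marker: str) -> pd.Series:
        self.marker_row(marker)
        return self.genotypes[marker]


@dataclass(frozen=True)
class IntervalResult:
    """The narrowed causal interval between two flanking markers."""

    chromosome: str
    left_marker: str
    right_marker: str
    start: int
    end: int
    length: int
    n_recombinants_used: int


@dataclass(frozen=True)
class CapsAssay:
    """A CAPS marker: one enzyme, one amplicon per parent."""

    enzyme: str
    recognition: str
    cut_offset: int
    amplicon_a: str
    amplicon_b: str

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("recognition sequence must be non-empty")
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise ValueError("cut offset must lie within the recognition site")


@dataclass(frozen=True)
class CosegregationSummary:
    """Genotype class counts at one marker and their fit to the trait."""

    marker: str
    counts: dict[str, int]  # keys A, H, B
    concordance: float
    segregation: SegregationResult


def _check_seq(seq: str, what: str) -> None:
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"{what} contains invalid characters: {sorted(bad)}")


def caps_digest(amplicon: str, recognition: str, cut_offset: int) -> list[int]:
    """Fragment lengths after cutting at every recognition-site occurrence.

    Scanning is forward-strand, left to right on the uncut coordinate
    frame; overlapping occurrences are all cut.  Fragment lengths always
    sum to the amplicon length.

    >>> caps_digest("G" * 40 + "GAATTC" + "G" * 54, "GAATTC", 1)
    [41, 59]
    """
    _check_seq(amplicon, "amplicon")
    _check_seq(recognition, "recognition sequence")
    if len(recognition) >= len(amplicon):
        raise ValueError("recognition sequence must be shorter than the amplicon")
    if not (0 <= cut_offset <= len(recognition)):
        raise ValueError("cut offset must lie within the recognition site")

    cuts = sorted(
        {
            i + cut_offset
            for i in range(len(amplicon) - len(recognition) + 1)
            if amplicon[i : i + len(recognition)] == recognition
        }
    )
    bounds = [0] + [c for c in cuts if 0 < c < len(amplicon)] + [len(amplicon)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def caps_polymorphic(assay: CapsAssay) -> tuple[bool, list[int], list[int]]:
    """Whether the two parental amplicons give different fragment patterns.

    Returns (polymorphic, fragments_parent_a, fragments_parent_b); the
    comparison is on fragment-length multisets, as on a gel.
    """
    frag_a = caps_digest(assay.amplicon_a, assay.recognition, assay.cut_offset)
    frag_b = caps_digest(assay.amplicon_b, assay.recognition, assay.cut_offset)
    return Counter(frag_a) != Counter(frag_b), frag_a, frag_b


def find_recombinants(table: MarkerGenotypeTable, left: str, right: str) -> list[str]:
    """Individuals with different (non-missing) codes at the two markers."""
    a = table.codes(left)
    b = table.codes(right)
    mask = (a != MISSING) & (b != MISSING) & (a != b)
    return list(a.index[mask])


def _consistent_with_recessive(codes: pd.Series, phenotypes: pd.Series) -> bool:
    """True iff no individual contradicts 'short <=> B' at this marker.

    Individuals missing at the marker are excluded, not imputed.
    """
    present = codes != MISSING
    is_b = codes[present] == "B"
    is_short = phenotypes[present] == "short"
    return bool((is_b == is_short).all())


def narrow_interval(table: MarkerGenotypeTable, trait_model: str = "recessive") -> IntervalResult:
    """Bound the causal locus by the nearest contradicted flanking markers.

    A marker is consistent with being the causal position iff no
    individual violates the recessive model there (short phenotype => B;
    long => A or H).  The interval runs from the nearest contradicted
    marker left of the consistent stretch to the nearest contradicted
    marker right of it; a side with no contradicted marker falls back to
    the outermost marker (no information beyond it).  Violations are
    attributed to recombination, never to phenotyping error.
    """
    if trait_model != "recessive":
        raise ValueError("only the recessive trait model is supported")
    if len(table.markers) < 2:
        raise ValueError("need at least two markers to narrow an interval")

    consistent = {
        name: _consistent_with_recessive(table.genotypes[name], table.phenotypes)
        for name in table.markers["name"]
    }
    if not any(consistent.values()):
        raise ValueError("trait not linked to supplied markers")

    # restrict to the chromosome carrying consistent markers
    chrom_of = dict(zip(table.markers["name"], table.markers["chromosome"]))
    chroms = {chrom_of[m] for m, ok in consistent.items() if ok}
    if len(chroms) > 1:
        raise ValueError(
            f"consistent markers on multiple chromosomes ({sorted(chroms)}); "
            "marker coverage cannot localize the trait"
        )
    chrom = chroms.pop()
    sub = table.markers[table.markers["chromosome"] == chrom].reset_index(drop=True)
    names = list(sub["name"])
    ok = np.array([consistent[m] for m in names])
    first, last = int(np.argmax(ok)), len(ok) - 1 - int(np.argmax(ok[::-1]))

    left_idx = first - 1 if first > 0 else 0
    right_idx = last + 1 if last < len(ok) - 1 else len(ok) - 1
    left, right = names[left_idx], names[right_idx]
    start = int(sub.loc[left_idx, "position"])
    end = int(sub.loc[right_idx, "position"])
    if start >= end:
        raise ValueError("degenerate interval: flanking markers do not bracket a region")
    return IntervalResult(
        chromosome=chrom,
        left_marker=left,
        right_marker=right,
        start=start,
        end=end,
        length=end - start,
        n_recombinants_used=len(find_recombinants(table, left, right)),
    )


def cosegregation_summary(table: MarkerGenotypeTable, marker: str) -> CosegregationSummary:
    """Genotype class counts at a marker, concordance with the recessive
    phenotype, and a 1:2:1 goodness-of-fit test.

    Concordance is the fraction of (non-missing) individuals where
    'code == B' coincides with 'phenotype == short'; 1.0 means perfect
    co-segregation of marker and trait.
    """
    codes = table.codes(marker)
    present = codes != MISSING
    counts = {c: int((codes[present] == c).sum()) for c in ("A", "H", "B")}
    is_b = codes[present] == "B"
    is_short = table.phenotypes[present] == "short"
    concordance = float((is_b == is_short).mean()) if present.any() else float("nan")
    seg = chi_square_gof([counts["A"], counts["H"], counts["B"]], [1, 2, 1])
    return CosegregationSummary(
        marker=marker, counts=counts, concordance=concordance, segregation=seg
    )
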