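"""Synthetic F2 populations and the derived inputs of a BSA-seq study.

The mapping design emulated here is a classical bulked-segregant
experiment for a monogenic recessive trait: two inbred parents are
crossed, the F1 selfed, and an F2 population (hundreds of plants)
phenotyped.  Thirty plants of each phenotypic extreme are pooled and the
pools sequenced to ~30x depth; per-SNP allele depths in the two pools are
the input of the SNP-index scan.  Subsets of SNPs double as codominant
(CAPS-style) markers for fine mapping, and a CDS pair differing by a
short frameshift deletion stands in for the candidate gene.

Meiosis follows the Haldane model: the number of crossovers per
chromosome per gamete is Poisson with mean equal to the genetic length in
Morgans, breakpoints are uniform on the physical length, and there is no
interference.  The phenotype is a deterministic recessive function of the
causal genotype — no phenocopies, no missing data — so every test failure
points at the analysis, not the data.

All randomness flows from a single integer seed per operation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .finemap import MarkerGenotypeTable
from .seqeffect import DomainAnnotation, translate_cds

__all__ = [
    "ChromosomeSpec",
    "GeneticMapSpec",
    "CausalLocusSpec",
    "BulkSpec",
    "F2Individual",
    "F2Population",
    "DEPTH_COLUMNS",
    "default_map",
    "simulate_f2_population",
    "simulate_bulk_depths",
    "extract_marker_genotypes",
    "make_cds_fixture",
    "simulate_ct_table",
]

#: Column schema of the per-SNP per-bulk allele-depth table.
DEPTH_COLUMNS = ("chrom", "pos", "ref", "alt", "L_ref", "L_alt", "S_ref", "S_alt")

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = np.array([c for c in _CODONS if c not in _STOPS])


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length_bp: int
    length_morgans: float

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ConfigurationError(f"{self.name}: length_bp must be >= 1")
        if self.length_morgans < 0:
            raise ConfigurationError(f"{self.name}: genetic length must be >= 0")


@dataclass
class GeneticMapSpec:
    """Physical + genetic coordinate frame of the simulated genome."""

    chromosomes: list[ChromosomeSpec]
    snp_positions: dict[str, np.ndarray]
    marker_positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate chromosome names")
        lengths = {c.name: c.length_bp for c in self.chromosomes}
        for chrom, pos in self.snp_positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.snp_positions[chrom] = pos
            if chrom not in lengths:
                raise ConfigurationError(f"SNP positions for unknown chromosome {chrom}")
            if pos.size and (np.any(np.diff(pos) <= 0) or pos[0] < 1):
                raise ConfigurationError(f"{chrom}: SNP positions must be strictly increasing and >= 1")
            if pos.size and pos[-1] > lengths[chrom]:
                raise ConfigurationError(f"{chrom}: SNP position beyond chromosome end")
        for chrom, pos in self.marker_positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.marker_positions[chrom] = pos
            snps = self.snp_positions.get(chrom, np.empty(0, dtype=np.int64))
            if not np.isin(pos, snps).all():
                raise ConfigurationError(f"{chrom}: marker positions must be a subset of SNP positions")

    def chromosome(self, name: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise ConfigurationError(f"unknown chromosome {name}")


@dataclass(frozen=True)
class CausalLocusSpec:
    """The recessive causal locus: short phenotype iff homozygous for the
    short-parent allele.  Recessiveness is the only supported mode."""

    chromosome: str
    position: int
    mode: str = "recessive"

    def __post_init__(self) -> None:
        if self.mode != "recessive":
            raise ConfigurationError("only a recessive causal locus is supported")


@dataclass(frozen=True)
class BulkSpec:
    """Pooling/sequencing design of the two phenotype bulks."""

    bulk_size: int = 30
    mean_depth: float = 30.0
    depth_model: str = "poisson"  # or "fixed"

    def __post_init__(self) -> None:
        if self.bulk_size < 1:
            raise ConfigurationError("bulk_size must be >= 1")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be > 0")
        if self.depth_model not in ("poisson", "fixed"):
            raise ConfigurationError("depth_model must be 'poisson' or 'fixed'")


@dataclass
class F2Individual:
    """One F2 plant: genotype codes per SNP (0/1/2 short-parent alleles)
    per chromosome, and its deterministic recessive phenotype."""

    id: str
    genotypes: dict[str, np.ndarray]
    phenotype: str  # "long" | "short"


@dataclass
class F2Population:
    """A simulated F2 population together with its coordinate frame."""

    map_spec: GeneticMapSpec
    causal: CausalLocusSpec
    individuals: list[F2Individual]

    def genotype_matrix(self, chrom: str) -> np.ndarray:
        """Individuals x SNPs matrix of 0/1/2 codes for one chromosome."""
        return np.vstack([ind.genotypes[chrom] for ind in self.individuals])

    @property
    def phenotypes(self) -> list[str]:
        return [ind.phenotype for ind in self.individuals]


def default_map(
    n_chromosomes: int = 3,
    chromosome_length: int = 30_000_000,
    genetic_length_morgans: float = 1.2,
    snps_per_chromosome: int = 1500,
) -> GeneticMapSpec:
    """A small watermelon-like genome: a few ~30 Mb chromosomes of ~1.2
    Morgan with evenly spaced SNPs (deterministic, no seed needed)."""
    chroms = [
        ChromosomeSpec(f"Chr{i + 1}", chromosome_length, genetic_length_morgans)
        for i in range(n_chromosomes)
    ]
    spacing = chromosome_length // snps_per_chromosome
    positions = np.arange(spacing, spacing * snps_per_chromosome + 1, spacing, dtype=np.int64)
    return GeneticMapSpec(
        chromosomes=chroms,
        snp_positions={c.name: positions.copy() for c in chroms},
    )


def _gamete(rng: np.random.Generator, chrom: ChromosomeSpec, snp_pos: np.ndarray) -> np.ndarray:
    """One gamete's allele (0 = long parent, 1 = short parent) per SNP.

    Haldane model: Poisson crossover count, uniform breakpoints, random
    starting parent, no interference.
    """
    start = int(rng.integers(2))
    n_xo = int(rng.poisson(chrom.length_morgans))
    if n_xo == 0:
        return np.full(snp_pos.size, start, dtype=np.int8)
    breaks = np.sort(rng.uniform(0.0, float(chrom.length_bp), size=n_xo))
    segment = np.searchsorted(breaks, snp_pos.astype(float))
    return ((start + segment) % 2).astype(np.int8)


def simulate_f2_population(
    map_spec: GeneticMapSpec,
    causal: CausalLocusSpec,
    n: int,
    seed: int,
) -> F2Population:
    """Simulate ``n`` F2 individuals by drawing two independent gametes each.

    The phenotype is assigned recessively at the causal locus: short iff
    both alleles there are the short-parent allele.  Identical seeds give
    identical populations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    snps = map_spec.snp_positions.get(causal.chromosome)
    if snps is None or causal.position not in snps:
        raise ConfigurationError(
            f"causal locus {causal.chromosome}:{causal.position} is not a simulated SNP"
        )
    causal_idx = int(np.searchsorted(snps, causal.position))

    rng = np.random.default_rng(seed)
    width = len(str(n))
    individuals = []
    for i in range(n):
        genotypes: dict[str, np.ndarray] = {}
        for chrom in map_spec.chromosomes:
            pos = map_spec.snp_positions.get(chrom.name, np.empty(0, dtype=np.int64))
            genotypes[chrom.name] = _gamete(rng, chrom, pos) + _gamete(rng, chrom, pos)
        phenotype = "short" if genotypes[causal.chromosome][causal_idx] == 2 else "long"
        individuals.append(
            F2Individual(id=f"F2_{i + 1:0{width}d}", genotypes=genotypes, phenotype=phenotype)
        )
    return F2Population(map_spec=map_spec, causal=causal, individuals=individuals)


def simulate_bulk_depths(
    population: F2Population,
    bulk: BulkSpec,
    seed: int,
) -> pd.DataFrame:
    """Sequence the two phenotype bulks in silico.

    The long (L) bulk is the first ``bulk_size`` long-phenotype
    individuals in population order, likewise the short (S) bulk
    (deterministic membership; no hidden randomness).  At each SNP the
    bulk's short-parent allele frequency is f = sum(codes)/(2*bulk_size);
    read depth is drawn per the depth model and the alternate-read count
    is Binomial(depth, f).  The long parent's allele is written as the
    reference, the short parent's as the alternate.

    Returns a DataFrame with columns :data:`DEPTH_COLUMNS`.
    """
    longs = [ind for ind in population.individuals if ind.phenotype == "long"]
    shorts = [ind for ind in population.individuals if ind.phenotype == "short"]
    for name, pool in (("long", longs), ("short", shorts)):
        if len(pool) < bulk.bulk_size:
            raise ValueError(
                f"need {bulk.bulk_size} {name}-phenotype individuals for the bulk, "
                f"have only {len(pool)}"
            )
    pools = {"L": longs[: bulk.bulk_size], "S": shorts[: bulk.bulk_size]}

    rng = np.random.default_rng(seed)
    frames = []
    for chrom in population.map_spec.chromosomes:
        pos = population.map_spec.snp_positions.get(chrom.name)
        if pos is None or pos.size == 0:
            continue
        n_snp = pos.size
        ref_idx = rng.integers(0, 4, size=n_snp)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_snp)) % 4
        cols: dict[str, np.ndarray] = {
            "chrom": np.repeat(chrom.name, n_snp),
            "pos": pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
        for label, members in pools.items():
            geno_sum = np.sum([ind.genotypes[chrom.name] for ind in members], axis=0)
            freq = geno_sum / (2.0 * bulk.bulk_size)
            if bulk.depth_model == "fixed":
                depth = np.full(n_snp, int(round(bulk.mean_depth)), dtype=np.int64)
            else:
                depth = rng.poisson(bulk.mean_depth, size=n_snp)
            alt = rng.binomial(depth, freq)
            cols[f"{label}_ref"] = depth - alt
            cols[f"{label}_alt"] = alt
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)[list(DEPTH_COLUMNS)]


_CODE = {0: "A", 1: "H", 2: "B"}


def extract_marker_genotypes(
    population: F2Population,
    marker_positions: dict[str, np.ndarray] | None = None,
) -> MarkerGenotypeTable:
    """Read codominant marker genotypes off the simulated SNP matrix.

    Codes: A = homozygous long-parent, H = heterozygous, B = homozygous
    short-parent.  Marker names are generated as ``M_<chrom>_<pos>``.
    An empty marker set yields a phenotype-only table.
    """
    if marker_positions is None:
        marker_positions = population.map_spec.marker_positions
    ids = [ind.id for ind in population.individuals]
    phenos = pd.Series(population.phenotypes, index=ids, name="phenotype")

    names, chroms, positions, columns = [], [], [], {}
    for chrom in population.map_spec.chromosomes:
        pos_req = np.asarray(marker_positions.get(chrom.name, []), dtype=np.int64)
        if pos_req.size == 0:
            continue
        snps = population.map_spec.snp_positions[chrom.name]
        idx = np.searchsorted(snps, pos_req)
        ok = (idx < snps.size) & (snps[np.minimum(idx, snps.size - 1)] == pos_req)
        if not ok.all():
            missing = pos_req[~ok]
            raise ConfigurationError(
                f"{chrom.name}: marker positions {missing.tolist()} are not simulated SNPs"
            )
        geno = population.genotype_matrix(chrom.name)[:, idx]
        for j, p in enumerate(pos_req):
            name = f"M_{chrom.name}_{p}"
            names.append(name)
            chroms.append(chrom.name)
            positions.append(int(p))
            columns[name] = [_CODE[g] for g in geno[:, j]]

    genotypes = pd.DataFrame(columns, index=ids)
    markers = pd.DataFrame({"name": names, "chromosome": chroms, "position": positions})
    return MarkerGenotypeTable(genotypes=genotypes, markers=markers, phenotypes=phenos)


def make_cds_fixture(
    total_length: int = 1200,
    deletion_start: int = 502,
    deletion_length: int = 13,
    target_truncated_aa: int = 173,
    seed: int = 0,
    max_iterations: int = 10_000,
) -> tuple[str, str, list[DomainAnnotation]]:
    """Engineer a reference/mutant CDS pair with a prescribed truncation.

    The reference CDS starts with ATG, ends with a stop codon and has no
    internal in-frame stop.  The mutant is the reference with
    ``deletion_length`` bases removed starting at ``deletion_start``
    (1-based).  For frameshifting deletions the sequence downstream of the
    deletion is redrawn (rejection sampling over codon choices) until the
    first stop in the shifted frame truncates the mutant protein to
    exactly ``target_truncated_aa`` residues — mirroring a 13 bp deletion
    that truncates a two-domain oxygenase to 173 residues.

    Domain annotations place one domain fully upstream of the truncation
    point (retained) and one beyond it (lost).

    Returns ``(reference_cds, mutant_cds, domains)``.
    """
    if total_length % 3 != 0:
        raise ValueError("total_length must be divisible by 3")
    n_codons = total_length // 3
    deletion_end = deletion_start + deletion_length - 1
    if not (4 <= deletion_start <= deletion_end <= total_length):
        raise ValueError("deletion interval must lie inside the CDS, after the start codon")
    ref_protein_len = n_codons - 1
    if target_truncated_aa >= ref_protein_len:
        raise ValueError("target_truncated_aa must be below the reference protein length")

    rng = np.random.default_rng(seed)
    in_frame = deletion_length % 3 == 0
    # codons before the deletion never change between iterations
    head_codons = (deletion_start - 1) // 3
    head = "ATG" + "".join(rng.choice(_SENSE_CODONS, size=max(head_codons - 1, 0)))
    stop = str(rng.choice(list(_STOPS)))

    for _ in range(max_iterations):
        tail = "".join(rng.choice(_SENSE_CODONS, size=n_codons - 1 - head_codons))
        ref = head + tail + stop
        assert len(ref) == total_length
        mutant = ref[: deletion_start - 1] + ref[deletion_end:]
        # in-frame deletions must not create a junction stop codon;
        # frameshifts must stop at exactly the target residue count
        wanted = (
            ref_protein_len - deletion_length // 3 if in_frame else target_truncated_aa
        )
        if len(translate_cds(mutant)) == wanted:
            return ref, mutant, _fixture_domains(target_truncated_aa, ref_protein_len)
    raise RuntimeError(
        f"no CDS with a {target_truncated_aa}-residue truncation found in "
        f"{max_iterations} iterations"
    )


def _fixture_domains(truncated_aa: int, ref_protein_len: int) -> list[DomainAnnotation]:
    """One retained N-terminal domain, one lost C-terminal domain,
    mirroring the DIOX_N / 2OG-FeII_Oxy architecture of plant
    2-oxoglutarate/Fe(II) dioxygenases."""
    upstream_end = max(2, truncated_aa - 20)
    downstream_start = min(truncated_aa + 20, ref_protein_len - 1)
    return [
        DomainAnnotation("DIOX_N", start_aa=min(25, upstream_end - 1), end_aa=upstream_end),
        DomainAnnotation("2OG-FeII_Oxy", start_aa=downstream_start, end_aa=ref_protein_len - 5),
    ]


def simulate_ct_table(
    fold_changes: dict[str, float],
    calibrator: str,
    ct_reference_gene: float = 20.0,
    ct_target_calibrator: float = 24.0,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table whose 2^-ddCt estimate recovers the truth.

    ``fold_changes`` maps sample id -> true expression fold change
    relative to the calibrator (the calibrator itself is implicitly 1).
    The reference gene amplifies at a constant Ct; the target gene's Ct in
    sample s is shifted by -log2(fold_s) relative to the calibrator, so
    the Livak estimator is unbiased before noise.  Gaussian noise of sd
    ``noise_sd`` cycles is added independently to every replicate well.

    Returns a DataFrame with columns sample, tissue, gene, replicate, ct.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    folds = dict(fold_changes)
    folds.setdefault(calibrator, 1.0)
    if not math.isclose(folds[calibrator], 1.0):
        raise ValueError("the calibrator's fold change must be 1")

    rng = np.random.default_rng(seed)
    dct_cal = ct_target_calibrator - ct_reference_gene
    rows = []
    for sample in folds:
        ct_target = ct_reference_gene + dct_cal - math.log2(folds[sample])
        for gene, base_ct in (("target", ct_target), ("reference", ct_reference_gene)):
            for rep in range(1, replicates + 1):
                ct = base_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append((sample, sample, gene, rep, ct))
    return pd.DataFrame(rows, columns=["sample", "tissue", "gene", "replicate", "ct"])
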