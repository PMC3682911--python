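"""Published composition of the 12-gene squamate supermatrix.

These printed counts (per-gene aligned lengths, numbers of species with data
per gene, overall sampling tallies) are inputs to bookkeeping checks: the
functions below recompute derived percentages from the raw counts, so tests
can verify the arithmetic rather than restate it.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GeneEntry:
    name: str
    kind: str  # "nuclear" | "mitochondrial"
    length_bp: int
    n_species: int


#: gene table of the published matrix, in its concatenation order
GENES = (
    GeneEntry("12S", "mitochondrial", 1395, 2335),
    GeneEntry("16S", "mitochondrial", 1970, 2377),
    GeneEntry("BDNF", "nuclear", 714, 730),
    GeneEntry("c-mos", "nuclear", 903, 1671),
    GeneEntry("cyt-b", "mitochondrial", 1000, 1985),
    GeneEntry("NT3", "nuclear", 675, 437),
    GeneEntry("ND2", "mitochondrial", 960, 1860),
    GeneEntry("ND4", "mitochondrial", 696, 1556),
    GeneEntry("PDC", "nuclear", 395, 393),
    GeneEntry("R35", "nuclear", 768, 401),
    GeneEntry("RAG-1", "nuclear", 2700, 1379),
    GeneEntry("RAG-2", "nuclear", 720, 471),
)

N_TAXA = 4162          # terminals in the matrix (incl. 1 outgroup)
N_SQUAMATE_SPECIES = 4161
MEAN_PRESENT_BP = 2497
MEAN_GENES_PER_TAXON = 3.75
COMPLETENESS_RANGE_BP = (270, 11153)

# sampling against the taxonomic database
KNOWN_SQUAMATE_SPECIES = 9416
SAMPLED_GENERA, KNOWN_GENERA = 855, 1018
SAMPLED_LIZARDS, KNOWN_LIZARDS = 2847, 5799
SAMPLED_AMPHISBAENIANS, KNOWN_AMPHISBAENIANS = 52, 183
SAMPLED_SNAKES, KNOWN_SNAKES = 1262, 3434


def total_alignment_bp() -> int:
    return sum(g.length_bp for g in GENES)


def gene_lengths() -> list[int]:
    return [g.length_bp for g in GENES]


def per_gene_coverage_percent(rounded: bool = True) -> dict[str, float]:
    out = {g.name: 100.0 * g.n_species / N_TAXA for g in GENES}
    return {k: round(v) for k, v in out.items()} if rounded else out


def per_gene_coverage_fraction() -> dict[str, float]:
    """Fractions used as default gene presence probabilities in simulation."""
    return {g.name: g.n_species / N_TAXA for g in GENES}


def mean_completeness_percent(rounded: bool = True) -> float:
    v = 100.0 * MEAN_PRESENT_BP / total_alignment_bp()
    return round(v) if rounded else v


def percent_missing(rounded: bool = True) -> float:
    v = 100.0 - 100.0 * MEAN_PRESENT_BP / total_alignment_bp()
    return round(v) if rounded else v


def sampling_fractions_percent(rounded: bool = True) -> dict[str, float]:
    out = {
        "species": 100.0 * N_SQUAMATE_SPECIES / KNOWN_SQUAMATE_SPECIES,
        "genera": 100.0 * SAMPLED_GENERA / KNOWN_GENERA,
        "lizards": 100.0 * SAMPLED_LIZARDS / KNOWN_LIZARDS,
        "amphisbaenians": 100.0 * SAMPLED_AMPHISBAENIANS / KNOWN_AMPHISBAENIANS,
        "snakes": 100.0 * SAMPLED_SNAKES / KNOWN_SNAKES,
    }
    return {k: round(v) for k, v in out.items()} if rounded else out
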