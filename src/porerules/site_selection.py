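"""Genomic motif-site scanning and training-site selection.

To train a modified pore model one needs genomic sites whose surrounding
sequence contexts, once modified, cover a target fraction T of all possible
modified k-mers.  A site at which the motif occurs contributes the
k − |motif| + 1 k-mers that fully overlap the motif (e.g. the CpG context
``TTAACGAATT`` contributes ``TTAAMG`` … ``MGAATT`` at k = 6).  Sites are
drawn in seeded random order and kept only if they add at least one new
k-mer, giving a near-minimal site set for the requested coverage.

Coordinates are 0-based; a site records the forward-strand coordinate of
the modified base, with ``strand == "-"`` meaning the motif lies on the
reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .model_io import ModificationScheme, enumerate_modified_kmers

__all__ = [
    "MotifSite",
    "SiteSelection",
    "read_genome",
    "write_genome",
    "scan_motifs",
    "site_kmers",
    "coverage",
    "select_training_sites",
    "write_bed",
]

Genome = Mapping[str, str]


@dataclass(frozen=True)
class MotifSite:
    """One occurrence of the modification motif in a genome."""

    contig: str
    position: int  # 0-based forward-strand coordinate of the modified base
    strand: str = "+"


@dataclass
class SiteSelection:
    """A near-minimal training site set reaching a target k-mer coverage."""

    sites: list[MotifSite]
    covered_kmers: set[str]
    target_fraction: float
    achieved_fraction: float
    seed: int
    contributions: list[int] = field(default_factory=list)  # new k-mers per accepted site


def read_genome(path: str | Path) -> dict[str, str]:
    """Load a (multi-)FASTA into a contig → uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _find_occurrences(seq: str, motif: str) -> list[int]:
    """Start coordinates of all (overlapping) motif occurrences, skipping
    any window that touches an N."""
    out = []
    start = seq.find(motif)
    while start != -1:
        out.append(start)
        start = seq.find(motif, start + 1)
    return out


def scan_motifs(
    genome: Genome, scheme: ModificationScheme, both_strands: bool = True
) -> list[MotifSite]:
    """All motif occurrences in a genome.

    Reverse-strand occurrences are located by scanning for the reverse
    complement of the motif on the forward sequence; they are reported with
    ``strand="-"`` and the forward coordinate of the modified base.
    """
    sites: list[MotifSite] = []
    motif = scheme.motif
    rc_motif = str(Seq(motif).reverse_complement())
    for contig, seq in genome.items():
        for start in _find_occurrences(seq, motif):
            sites.append(MotifSite(contig, start + scheme.mod_offset, "+"))
        if both_strands:
            for start in _find_occurrences(seq, rc_motif):
                pos = start + len(motif) - 1 - scheme.mod_offset
                sites.append(MotifSite(contig, pos, "-"))
    return sites


def site_kmers(genome: Genome, site: MotifSite, k: int, scheme: ModificationScheme) -> list[str]:
    """Modified k-mers contributed by one motif site.

    These are the k − |motif| + 1 k-mers whose window contains the whole
    motif, with the modification code substituted at the modified base —
    fewer near contig ends, where short flanks truncate the list.  K-mers
    containing an N are dropped.
    """
    seq = genome[site.contig]
    L = len(scheme.motif)
    if site.strand == "+":
        motif_start = site.position - scheme.mod_offset
    else:
        motif_start = site.position - (L - 1 - scheme.mod_offset)
    lo = max(0, motif_start - (k - L))
    hi = min(len(seq), motif_start + L + (k - L))
    context = seq[lo:hi]
    offset = motif_start - lo  # motif start within context, forward strand
    if site.strand == "-":
        context = str(Seq(context).reverse_complement())
        offset = len(context) - offset - L
    mod_idx = offset + scheme.mod_offset
    modded = context[:mod_idx] + scheme.mod_code + context[mod_idx + 1 :]
    out = []
    for s in range(max(0, offset + L - k), min(offset, len(modded) - k) + 1):
        kmer = modded[s : s + k]
        if len(kmer) == k and "N" not in kmer:
            out.append(kmer)
    return out


def coverage(
    genome: Genome, scheme: ModificationScheme, k: int, both_strands: bool = True
) -> float:
    """Fraction of all complete-motif single-modification k-mers that occur
    around motif sites of the genome."""
    universe = enumerate_modified_kmers(k, scheme, include_incomplete=False)
    seen: set[str] = set()
    for site in scan_motifs(genome, scheme, both_strands):
        seen.update(site_kmers(genome, site, k, scheme))
    return len(seen & universe) / len(universe)


def select_training_sites(
    genome: Genome,
    scheme: ModificationScheme,
    k: int,
    target_fraction: float,
    seed: int = 0,
    both_strands: bool = True,
) -> SiteSelection:
    """Greedily pick motif sites until a target k-mer coverage is reached.

    Sites are visited in a seeded uniform-random order; a site is accepted
    only if it contributes at least one not-yet-covered k-mer, and selection
    stops at the first acceptance that reaches ``target_fraction`` of all
    complete-motif modified k-mers.  Deterministic given the seed; overshoot
    is at most one site's contribution.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    universe = enumerate_modified_kmers(k, scheme, include_incomplete=False)
    all_sites = scan_motifs(genome, scheme, both_strands)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(all_sites))
    chosen: list[MotifSite] = []
    contributions: list[int] = []
    covered: set[str] = set()
    target_count = target_fraction * len(universe)
    for idx in order:
        site = all_sites[idx]
        new = (set(site_kmers(genome, site, k, scheme)) & universe) - covered
        if not new:
            continue
        chosen.append(site)
        contributions.append(len(new))
        covered |= new
        if len(covered) >= target_count:
            break
    achieved = len(covered) / len(universe)
    if achieved < target_fraction:
        raise ValueError(
            f"coverage shortfall: genome supports at most {achieved:.4f} of modified "
            f"{k}-mers for scheme {scheme}, below target {target_fraction}"
        )
    return SiteSelection(
        sites=chosen,
        covered_kmers=covered,
        target_fraction=target_fraction,
        achieved_fraction=achieved,
        seed=seed,
        contributions=contributions,
    )


def write_bed(sites: list[MotifSite], path: str | Path) -> None:
    """BED (3 + strand) output of a site list."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.contig}\t{s.position}\t{s.position + 1}\t.\t0\t{s.strand}\n")
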