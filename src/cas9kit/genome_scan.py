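"""Enumeration of Cas9 target sites (NGG protospacer-adjacent motifs) in a genome.

An S. pyogenes Cas9 target site is a 20-nt protospacer lying immediately 5'
of an NGG PAM. The scanner reports every such site on the forward strand
(every ``GG`` dinucleotide with 21 nt of 5' context) and, in both-strand
mode, every reverse-strand site (every ``CC`` on the forward strand with 21
nt of 3' context, whose protospacer is the reverse complement of the 20 nt
3' of the CCN triplet). Coordinates are 0-based half-open on the forward
strand throughout; ``pam_start`` is the first base of the NGG (the N) in
forward coordinates for both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .errors import AlphabetError, CoordinateError, InputError, ParameterError

VALID_ALPHABET = frozenset("ACGTN")
PAM_ANCHOR_WIDTH = 3  # NGG trinucleotide
PROTOSPACER_LEN = 20
DEFAULT_FLANK = 30
DEFAULT_BACKGROUND_N = 10_000

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named contig over the alphabet {A, C, G, T, N}."""

    name: str
    residues: str

    def __post_init__(self):
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        bad = set(residues) - VALID_ALPHABET
        if bad:
            raise AlphabetError(
                f"contig {self.name!r} contains invalid characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


Genome = dict[str, GenomeSequence]


def as_genome(source) -> Genome:
    """Coerce a mapping of name -> sequence string (or GenomeSequence) to a Genome."""
    genome: Genome = {}
    for name, seq in dict(source).items():
        genome[name] = seq if isinstance(seq, GenomeSequence) else GenomeSequence(name, str(seq))
    if not genome:
        raise InputError("empty genome")
    return genome


def read_fasta(path) -> Genome:
    """Read a (possibly multi-contig, line-wrapped) FASTA file into a Genome."""
    genome: Genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise InputError(f"duplicate contig name {rec.id!r} in {path}")
        genome[rec.id] = GenomeSequence(rec.id, str(rec.seq).upper())
    if not genome:
        raise InputError(f"no FASTA records found in {path}")
    return genome


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, contig in genome.items():
            fh.write(f">{name}\n")
            s = contig.residues
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


@dataclass(frozen=True)
class Window:
    """Half-open interval around an anchor, clipped at contig ends."""

    start: int
    end: int
    clipped_left: bool = False
    clipped_right: bool = False

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains_interval(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


def window_around(
    position: int,
    flank: int = DEFAULT_FLANK,
    contig_length: int | None = None,
    anchor_width: int = PAM_ANCHOR_WIDTH,
) -> Window:
    """Interval covering `flank` nt on both sides of an anchor starting at `position`.

    The anchor (an NGG PAM, a variant base...) occupies
    ``[position, position + anchor_width)``; the window is
    ``[position - flank, position + anchor_width + flank)`` clipped to the contig.
    """
    if contig_length is None:
        raise ParameterError("contig_length is required")
    if not 0 <= position < contig_length:
        raise CoordinateError(
            f"position {position} outside contig of length {contig_length}"
        )
    start = position - flank
    end = position + anchor_width + flank
    return Window(
        start=max(0, start),
        end=min(contig_length, end),
        clipped_left=start < 0,
        clipped_right=end > contig_length,
    )


@dataclass(frozen=True)
class PamSite:
    """A located NGG occurrence with its protospacer and context window.

    ``pam_start`` is the 0-based forward-strand coordinate of the first base
    of the NGG triplet. On '+' the protospacer is the 20 nt immediately 5' of
    that coordinate; on '-' it is the reverse complement of the 20 nt
    immediately 3' of the forward-strand CCN triplet.
    """

    contig: str
    pam_start: int
    strand: str
    protospacer: str
    window: Window
    contains_n: bool = field(default=False, compare=False)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ParameterError(f"invalid strand {self.strand!r}")
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ParameterError("protospacer must be exactly 20 nt")

    @property
    def pam_interval(self) -> tuple[int, int]:
        return (self.pam_start, self.pam_start + PAM_ANCHOR_WIDTH)


def scan_pam_sites(genome, strand_mode: str = "both", flank: int = DEFAULT_FLANK) -> list[PamSite]:
    """Report every full-context NGG site in the genome.

    Forward sites require 20 nt of 5' context before the N of NGG (contigs
    shorter than 23 nt yield nothing); overlapping GG runs each yield a site.
    In ``both`` mode, forward-strand CC dinucleotides are reported as
    reverse-strand PAMs. Protospacers containing N are reported with
    ``contains_n=True``.
    """
    if strand_mode not in ("forward", "both"):
        raise ParameterError(f"strand_mode must be 'forward' or 'both', got {strand_mode!r}")
    genome = as_genome(genome)
    sites: list[PamSite] = []
    for name, contig in genome.items():
        seq = contig.residues
        L = contig.length
        # forward strand: GG at [i, i+2), PAM N at i-1, protospacer [i-21, i-1)
        i = seq.find("GG")
        while i != -1:
            pam_start = i - 1
            if pam_start - PROTOSPACER_LEN >= 0:
                proto = seq[pam_start - PROTOSPACER_LEN : pam_start]
                sites.append(
                    PamSite(
                        contig=name,
                        pam_start=pam_start,
                        strand="+",
                        protospacer=proto,
                        window=window_around(pam_start, flank, L),
                        contains_n="N" in proto,
                    )
                )
            i = seq.find("GG", i + 1)
        if strand_mode == "both":
            # reverse strand: CCN at [i, i+3), protospacer revcomp of [i+3, i+23)
            i = seq.find("CC")
            while i != -1:
                if i + PAM_ANCHOR_WIDTH + PROTOSPACER_LEN <= L:
                    proto = reverse_complement(seq[i + 3 : i + 3 + PROTOSPACER_LEN])
                    sites.append(
                        PamSite(
                            contig=name,
                            pam_start=i,
                            strand="-",
                            protospacer=proto,
                            window=window_around(i, flank, L),
                            contains_n="N" in proto,
                        )
                    )
                i = seq.find("CC", i + 1)
    sites.sort(key=lambda s: (s.contig, s.pam_start, s.strand))
    return sites


@dataclass(frozen=True)
class BackgroundTargetSet:
    """A random sample of genomic protospacers used as the empirical null."""

    targets: tuple[str, ...]
    sample_size: int
    seed: int
    shortfall: bool = False

    def __post_init__(self):
        if self.sample_size != len(self.targets):
            raise ParameterError("sample_size must equal the number of targets")


def sample_background_targets(
    sites: list[PamSite], n: int = DEFAULT_BACKGROUND_N, seed: int = 0
) -> BackgroundTargetSet:
    """Sample n protospacers without replacement from the scanned site pool.

    Protospacers containing N are excluded (the alignment matrix does not
    score them). If the eligible pool is smaller than n, all of it is
    returned with ``shortfall=True``.
    """
    if n <= 0:
        raise ParameterError(f"sample size must be positive, got {n}")
    pool = [s.protospacer for s in sites if not s.contains_n]
    if not pool:
        raise InputError("no eligible sites to sample from")
    rng = np.random.default_rng(seed)
    if len(pool) < n:
        return BackgroundTargetSet(tuple(pool), len(pool), seed, shortfall=True)
    idx = rng.choice(len(pool), size=n, replace=False)
    return BackgroundTargetSet(tuple(pool[i] for i in idx), n, seed, shortfall=False)


def write_sites_bed(sites: list[PamSite], path) -> None:
    """Write PAM intervals as BED6 (0-based half-open, protospacer in the name column)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.contig}\t{s.pam_start}\t{s.pam_start + PAM_ANCHOR_WIDTH}\t"
                f"{s.protospacer}\t0\t{s.strand}\n"
            )


def write_sites_tsv(sites: list[PamSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpam_start\tstrand\tprotospacer\twindow_start\twindow_end\n")
        for s in sites:
            fh.write(
                f"{s.contig}\t{s.pam_start}\t{s.strand}\t{s.protospacer}\t"
                f"{s.window.start}\t{s.window.end}\n"
            )
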