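"""Design of HDR donor DNAs and prediction of the edited allele.

Two donor classes are supported:

* **Barcoded knockout donors** — a 20-nt unique barcode flanked by common
  primer sequences and a 5' TAA stop codon, carried between two 50-bp
  homology arms. The arms sit 10 bp on either side of the Cas9 cleavage
  point (the blunt cut 3 bp 5' of the PAM), so integration deletes 20 nt of
  the target locus and replaces it with the barcode cassette.
* **Point-mutation repair oligos** — a short single-substitution oligo
  (59-nt core by default) optionally extended by 50 bp of additional
  homology on each side.

``apply_template`` performs the in-silico HDR, returning the predicted
edited contig; re-scanning an edited allele must no longer report the
original protospacer (the edit destroys the target site).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CoordinateError,
    GenerationError,
    ParameterError,
    ReferenceMismatchError,
)
from .genome_scan import (
    Genome,
    PamSite,
    as_genome,
    reverse_complement,
    scan_pam_sites,
)

ARM_LEN = 50
DELETION_LEN = 20
BARCODE_LEN = 20
STOP_CODON = "TAA"
CUT_OFFSET = 3  # blunt Cas9 cut, 3 bp 5' of the PAM

# Standard yeast barcode-flanking common primers (configurable on every call).
DEFAULT_FWD_PRIMER = "GATGTCCACGAGGTCTCT"
DEFAULT_REV_PRIMER = "CGGTGTCGGTCTCGTAG"


@dataclass(frozen=True)
class GuideSpec:
    """A named 20-nt sgRNA guide sequence, optionally tied to a scanned site."""

    name: str
    guide: str
    target: PamSite | None = None

    def __post_init__(self):
        if len(self.guide) != 20:
            raise ParameterError(f"guide {self.name!r} must be 20 nt, got {len(self.guide)}")
        if set(self.guide) - set("ACGT"):
            raise ParameterError(f"guide {self.name!r} contains non-ACGT characters")
        if self.target is not None and self.guide != self.target.protospacer:
            raise ParameterError(
                f"guide {self.name!r} does not equal its target protospacer"
            )


@dataclass(frozen=True)
class RepairTemplate:
    """A barcoded HDR donor: 50-bp arms around a 20-nt deletion, insert between them."""

    contig: str
    left_arm: str
    fwd_primer: str
    barcode: str
    rev_primer: str
    right_arm: str
    deletion_interval: tuple[int, int]
    strand: str = "+"
    stop_codon: str = STOP_CODON

    def __post_init__(self):
        if len(self.left_arm) != ARM_LEN or len(self.right_arm) != ARM_LEN:
            raise ParameterError("homology arms must be exactly 50 nt")
        if len(self.barcode) != BARCODE_LEN:
            raise ParameterError("barcode must be exactly 20 nt")
        start, end = self.deletion_interval
        if end - start != DELETION_LEN:
            raise ParameterError("deletion interval must span exactly 20 nt")

    @property
    def insert(self) -> str:
        """Payload on the protospacer strand: stop codon, fwd primer, barcode, rev primer."""
        return self.stop_codon + self.fwd_primer + self.barcode + self.rev_primer

    @property
    def insert_forward(self) -> str:
        """Payload in forward-strand genome coordinates."""
        return self.insert if self.strand == "+" else reverse_complement(self.insert)

    @property
    def donor_sequence(self) -> str:
        """Full donor molecule in forward coordinates: left arm + insert + right arm."""
        return self.left_arm + self.insert_forward + self.right_arm


@dataclass(frozen=True)
class PointMutationOligo:
    """A single-substitution repair oligo with optional extra homology."""

    contig: str
    sequence: str
    edit: tuple[int, str, str]  # (1-based position on the locus, ref_base, alt_base)
    core_start: int  # 0-based start of the oligo on the locus
    protospacer_disrupted: bool = field(default=False, compare=False)


@dataclass(frozen=True)
class EditedAllele:
    """Predicted post-HDR contig."""

    contig: str
    sequence: str
    length_delta: int


def cut_position(site: PamSite, cut_offset: int = CUT_OFFSET) -> int:
    """Forward-strand coordinate of the blunt cleavage point (between protospacer
    positions 17|18, 3 bp 5' of the PAM).

    For a reverse-strand site the PAM occupies [pam_start, pam_start+3) as CCN
    on the forward strand, so the cut lies 3 bp 3' of the CCN triplet.
    """
    if site.strand == "+":
        return site.pam_start - cut_offset
    return site.pam_start + 3 + cut_offset


def design_barcoded_repair(
    genome,
    site: PamSite,
    barcode: str,
    fwd_primer: str = DEFAULT_FWD_PRIMER,
    rev_primer: str = DEFAULT_REV_PRIMER,
    cut_offset: int = CUT_OFFSET,
) -> RepairTemplate:
    """Design a barcoded knockout donor for a scanned Cas9 site.

    The deleted 20-nt window is centred on the cleavage point (``cut_offset``
    bp 5' of the PAM); each homology arm is the 50 reference nt immediately
    flanking the deletion, so the donor carries "10 bp proximal to the PAM"
    of genomic sequence on each side of the insert.
    """
    genome = as_genome(genome)
    if set(barcode.upper()) - set("ACGT") or len(barcode) != BARCODE_LEN:
        raise ParameterError("barcode must be a 20-nt ACGT string")
    contig = genome[site.contig]
    cut = cut_position(site, cut_offset)
    del_start, del_end = cut - DELETION_LEN // 2, cut + DELETION_LEN // 2
    if del_start - ARM_LEN < 0 or del_end + ARM_LEN > contig.length:
        raise CoordinateError(
            f"homology arms overrun contig {site.contig!r} "
            f"(deletion [{del_start}, {del_end}), contig length {contig.length})"
        )
    seq = contig.residues
    return RepairTemplate(
        contig=site.contig,
        left_arm=seq[del_start - ARM_LEN : del_start],
        fwd_primer=fwd_primer,
        barcode=barcode.upper(),
        rev_primer=rev_primer,
        right_arm=seq[del_end : del_end + ARM_LEN],
        deletion_interval=(del_start, del_end),
        strand=site.strand,
    )


def generate_barcodes(
    k: int, length: int = BARCODE_LEN, min_hamming: int = 5, seed: int = 0,
    max_tries: int = 100_000,
) -> list[str]:
    """Issue k distinct random barcodes with pairwise Hamming distance >= min_hamming."""
    if k <= 0:
        raise ParameterError("k must be positive")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    out: list[str] = []
    arrs: list[np.ndarray] = []
    for _ in range(max_tries):
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != a).sum()) >= min_hamming for a in arrs):
            arrs.append(cand)
            out.append("".join(bases[cand]))
            if len(out) == k:
                return out
    raise GenerationError(
        f"could not find {k} barcodes at Hamming distance >= {min_hamming}"
    )


def design_point_mutation_oligo(
    locus,
    position: int,
    ref_base: str,
    alt_base: str,
    core_flank: int | tuple[int, int] = 29,
    extension: int = 50,
    guides: list[str] | None = None,
) -> PointMutationOligo:
    """Design a single-substitution repair oligo around a 1-based locus position.

    ``core_flank`` is the number of reference nt kept on each side of the
    edited base within the oligo core (an ``(left, right)`` pair allows the
    asymmetric layouts seen in practice); ``extension`` adds that many more
    reference nt of homology on both sides, clipped at the locus ends.
    ``protospacer_disrupted`` is True when a supplied guide matches the
    reference locus end-to-end (either strand) but no longer matches the
    edited locus.
    """
    genome = as_genome(locus if isinstance(locus, dict) else {getattr(locus, "name", "locus"): locus})
    (name, contig), = genome.items()
    seq = contig.residues
    pos0 = position - 1
    if not 0 <= pos0 < contig.length:
        raise CoordinateError(f"position {position} outside locus of length {contig.length}")
    if seq[pos0] != ref_base.upper():
        raise ReferenceMismatchError(
            f"locus has {seq[pos0]!r} at position {position}, expected {ref_base!r}"
        )
    left, right = (core_flank, core_flank) if isinstance(core_flank, int) else core_flank
    core_start, core_end = pos0 - left, pos0 + right + 1
    if core_start < 0 or core_end > contig.length:
        raise CoordinateError("oligo core overruns the locus")
    start = max(0, core_start - extension)
    end = min(contig.length, core_end + extension)
    oligo = seq[start:pos0] + alt_base.upper() + seq[pos0 + 1 : end]

    disrupted = False
    if guides:
        edited = seq[:pos0] + alt_base.upper() + seq[pos0 + 1 :]
        for g in guides:
            g = g.upper()
            in_ref = g in seq or reverse_complement(g) in seq
            in_edit = g in edited or reverse_complement(g) in edited
            if in_ref and not in_edit:
                disrupted = True
    return PointMutationOligo(
        contig=name,
        sequence=oligo,
        edit=(position, ref_base.upper(), alt_base.upper()),
        core_start=start,
        protospacer_disrupted=disrupted,
    )


def count_matching_positions(a: str, b: str) -> int:
    """Position-wise identity between two equal-length (or truncated) strings."""
    return sum(x == y for x, y in zip(a, b))


def apply_template(genome, template) -> EditedAllele:
    """Predict the post-HDR allele for a donor designed against this genome."""
    genome = as_genome(genome)
    if isinstance(template, RepairTemplate):
        contig = genome[template.contig]
        seq = contig.residues
        del_start, del_end = template.deletion_interval
        if seq[del_start - ARM_LEN : del_start] != template.left_arm:
            raise ReferenceMismatchError("left homology arm does not match the reference")
        if seq[del_end : del_end + ARM_LEN] != template.right_arm:
            raise ReferenceMismatchError("right homology arm does not match the reference")
        insert = template.insert_forward
        edited = seq[:del_start] + insert + seq[del_end:]
        return EditedAllele(
            contig=template.contig,
            sequence=edited,
            length_delta=len(insert) - DELETION_LEN,
        )
    if isinstance(template, PointMutationOligo):
        contig = genome[template.contig]
        seq = contig.residues
        position, ref_base, alt_base = template.edit
        pos0 = position - 1
        if seq[pos0] != ref_base:
            raise ReferenceMismatchError(
                f"reference has {seq[pos0]!r} at {position}, oligo expects {ref_base!r}"
            )
        edited = seq[:pos0] + alt_base + seq[pos0 + 1 :]
        return EditedAllele(contig=template.contig, sequence=edited, length_delta=0)
    raise ParameterError(f"unsupported template type {type(template).__name__}")


def protospacer_survives(edited: EditedAllele, protospacer: str) -> bool:
    """Check whether an intact target site for `protospacer` remains after the edit."""
    sites = scan_pam_sites({edited.contig: edited.sequence}, strand_mode="both")
    return any(s.protospacer == protospacer for s in sites)
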