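"""Alignment-based adjudication of sequencing variants as Cas9 off-target events.

The procedure, applied to each called variant:

1. collect every NGG site whose PAM trinucleotide lies within a ±30-nt
   window around the variant;
2. globally align each used guide to each candidate protospacer
   (Needleman–Wunsch, match +2, mismatch −1, affine gaps) and count perfect
   base-pair matches on the aligned columns — a candidate with fewer than 12
   matches cannot be cut by Cas9 and is dismissed;
3. locally align the guide to the candidate and compare the score with
   local alignments of the same guide against a large random sample of
   genomic protospacers: ``p_better`` is the fraction of background targets
   that align strictly better, an empirical null for "how unremarkable is
   this match genome-wide".

Gap costs follow the convention that a length-L gap costs
``gap_open + (L-1)·gap_extend`` (a single gapped column costs ``gap_open``).
The defaults (open 14, extend 4) reproduce the Biostrings
``pairwiseAlignment`` defaults (gap opening 10 plus extension 4 per gapped
column) and keep end-to-end alignments of 20-mers effectively gapless unless
a shifted register is strongly favoured; with cheaper gaps the
perfect-match-count rule fires spuriously on unrelated sequence pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .errors import (
    AlphabetError,
    ConsistencyError,
    CoordinateError,
    InputError,
    ParameterError,
    ParseError,
)
from .genome_scan import (
    BackgroundTargetSet,
    Genome,
    PamSite,
    as_genome,
    sample_background_targets,
    scan_pam_sites,
    window_around,
)

MATCH_SCORE = 2
MISMATCH_SCORE = -1
GAP_OPEN = 14  # cost of the first gapped column (Biostrings: opening 10 + extension 4)
GAP_EXTEND = 4  # cost of each additional gapped column
MATCH_THRESHOLD = 12  # minimum perfect base-pair matches for Cas9 activity

_NEG = float("-inf")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class VariantRecord:
    """One called variant (one ALT allele), 1-based position."""

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    var_class: str = ""

    def __post_init__(self):
        if set(self.ref_allele + self.alt_allele) - set("ACGT"):
            raise AlphabetError("variant alleles must be over {A,C,G,T}")
        cls = classify_variant(self.ref_allele, self.alt_allele)
        if self.var_class and self.var_class != cls:
            raise ParameterError(
                f"var_class {self.var_class!r} inconsistent with alleles "
                f"{self.ref_allele}>{self.alt_allele} ({cls})"
            )
        object.__setattr__(self, "var_class", cls)

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.position}:{self.ref_allele}>{self.alt_allele}"


def classify_variant(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "SNP" if len(ref) == 1 else "MNP"
    return "INDEL"


@dataclass(frozen=True)
class AlignmentResult:
    """An optimal pairwise alignment with per-column bookkeeping."""

    mode: str
    score: int
    aligned_guide: str
    aligned_target: str
    matches: int
    mismatches: int
    gaps: int  # gapped columns
    nonstandard_length: bool = field(default=False, compare=False)


def read_variants(vcf_source, genome: Genome | None = None) -> list[VariantRecord]:
    """Read a VCF into variant records, one per ALT allele (multi-allelics split)."""
    records: list[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(str(vcf_source))
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse VCF {vcf_source}: {exc}") from exc
    with vcf:
        for i, rec in enumerate(vcf.fetch(), start=1):
            if genome is not None and rec.contig not in genome:
                raise ConsistencyError(
                    f"VCF record {i}: contig {rec.contig!r} absent from genome"
                )
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if set(alt) - set("ACGT"):
                    raise ParseError(
                        f"VCF record {i} ({rec.contig}:{rec.pos}): "
                        f"unsupported ALT allele {alt!r}"
                    )
                records.append(
                    VariantRecord(
                        contig=rec.contig,
                        position=rec.pos,
                        ref_allele=rec.ref.upper(),
                        alt_allele=alt.upper(),
                    )
                )
    return records


def candidate_sites_near_variant(
    genome,
    variant: VariantRecord,
    flank: int = 30,
    sites: list[PamSite] | None = None,
) -> list[PamSite]:
    """PAM sites whose NGG trinucleotide lies within ±flank nt of the variant."""
    genome = as_genome(genome)
    if variant.contig not in genome:
        raise ConsistencyError(f"variant contig {variant.contig!r} absent from genome")
    contig = genome[variant.contig]
    pos0 = variant.position - 1
    win = window_around(
        pos0, flank=flank, contig_length=contig.length,
        anchor_width=len(variant.ref_allele),
    )
    if sites is None:
        sites = scan_pam_sites({variant.contig: contig})
    return [
        s
        for s in sites
        if s.contig == variant.contig and win.contains_interval(*s.pam_interval)
    ]


def _check_alphabet(*seqs: str) -> None:
    for s in seqs:
        if set(s) - set("ACGT"):
            raise AlphabetError(f"sequence contains non-ACGT characters: {s!r}")


def global_align(
    guide: str,
    target: str,
    match: int = MATCH_SCORE,
    mismatch: int = MISMATCH_SCORE,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> AlignmentResult:
    """Optimal end-to-end (Needleman–Wunsch) alignment with affine gaps.

    Ties among co-optimal alignments are broken by a fixed state preference
    (substitution column over a gap in the target over a gap in the guide),
    which is deterministic and keeps gaps out of the alignment whenever an
    equally scoring substitution path exists.
    """
    guide, target = guide.upper(), target.upper()
    _check_alphabet(guide, target)
    n, m = len(guide), len(target)
    if n == 0 or m == 0:
        raise InputError("cannot align an empty sequence")

    # Gotoh three-state DP. M: substitution column; X: guide base over a gap
    # (vertical); Y: gap in the guide (horizontal).
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        gi = guide[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = match if gi == target[j - 1] else mismatch
            Mi[j] = max(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + s
            Xi[j] = max(Mp[j] - gap_open, Xp[j] - gap_extend, Yp[j] - gap_open)
            Yi[j] = max(Mi[j - 1] - gap_open, Yi[j - 1] - gap_extend, Xi[j - 1] - gap_open)

    # traceback with preference M > X > Y on ties
    i, j = n, m
    finals = {"M": M[n][m], "X": X[n][m], "Y": Y[n][m]}
    top = max(finals.values())
    state = next(st for st in ("M", "X", "Y") if finals[st] == top)
    ag, at = [], []
    while i > 0 or j > 0:
        if state == "M":
            s = match if guide[i - 1] == target[j - 1] else mismatch
            ag.append(guide[i - 1])
            at.append(target[j - 1])
            prev = M[i][j] - s
            i, j = i - 1, j - 1
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if mat[i][j] == prev:
                    state = st
                    break
        elif state == "X":
            ag.append(guide[i - 1])
            at.append("-")
            val = X[i][j]
            i -= 1
            if M[i][j] - gap_open == val:
                state = "M"
            elif X[i][j] - gap_extend == val:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            ag.append("-")
            at.append(target[j - 1])
            val = Y[i][j]
            j -= 1
            if M[i][j] - gap_open == val:
                state = "M"
            elif Y[i][j] - gap_extend == val:
                state = "Y"
            else:
                state = "X"
    aligned_guide = "".join(reversed(ag))
    aligned_target = "".join(reversed(at))
    matches = sum(a == b for a, b in zip(aligned_guide, aligned_target) if a != "-" and b != "-")
    mismatches = sum(
        a != b for a, b in zip(aligned_guide, aligned_target) if a != "-" and b != "-"
    )
    gaps = sum(a == "-" or b == "-" for a, b in zip(aligned_guide, aligned_target))
    score = int(max(M[n][m], X[n][m], Y[n][m]))
    return AlignmentResult(
        mode="global",
        score=score,
        aligned_guide=aligned_guide,
        aligned_target=aligned_target,
        matches=matches,
        mismatches=mismatches,
        gaps=gaps,
        nonstandard_length=(n != 20 or m != 20),
    )


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))


def local_align_scores(
    guide: str,
    targets,
    match: int = MATCH_SCORE,
    mismatch: int = MISMATCH_SCORE,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> np.ndarray:
    """Optimal local (Smith–Waterman) scores of one guide vs many equal-length targets.

    Vectorised Gotoh DP across the target batch; returns an int array of
    best local scores, one per target.
    """
    guide = guide.upper()
    targets = [t.upper() for t in targets]
    if not targets:
        return np.zeros(0, dtype=int)
    _check_alphabet(guide, *targets)
    m = len(targets[0])
    if any(len(t) != m for t in targets):
        raise InputError("all targets in a batch must have equal length")
    n = len(guide)
    g = _encode(guide)
    T = np.stack([_encode(t) for t in targets])  # (N, m)
    N = T.shape[0]

    prev_H = np.zeros((N, m + 1))
    prev_F = np.full((N, m + 1), _NEG)
    best = np.zeros(N)
    for i in range(1, n + 1):
        cur_H = np.zeros((N, m + 1))
        cur_F = np.maximum(prev_H - gap_open, prev_F - gap_extend)
        E = np.full(N, _NEG)
        s_row = np.where(T == g[i - 1], match, mismatch)  # (N, m)
        for j in range(1, m + 1):
            E = np.maximum(cur_H[:, j - 1] - gap_open, E - gap_extend)
            h = prev_H[:, j - 1] + s_row[:, j - 1]
            h = np.maximum(h, E)
            h = np.maximum(h, cur_F[:, j])
            h = np.maximum(h, 0.0)
            cur_H[:, j] = h
            np.maximum(best, h, out=best)
        prev_H, prev_F = cur_H, cur_F
    return best.astype(int)


def local_align_score(guide: str, target: str, **kwargs) -> int:
    """Optimal Smith–Waterman score for a single guide/target pair."""
    return int(local_align_scores(guide, [target], **kwargs)[0])


def classify_plausible(result: AlignmentResult, match_threshold: int = MATCH_THRESHOLD) -> bool:
    """Cas9 activity requires at least `match_threshold` perfect base-pair matches."""
    return result.matches >= match_threshold


def empirical_better_match_probability(
    guide: str,
    candidate_score: int,
    background: BackgroundTargetSet,
    background_scores: np.ndarray | None = None,
) -> float:
    """Fraction of background targets whose local alignment to the guide scores
    strictly higher than the candidate's."""
    if background_scores is None:
        if not background.targets:
            raise ParameterError("background target set is empty")
        background_scores = local_align_scores(guide, background.targets)
    elif len(background_scores) == 0:
        raise ParameterError("background target set is empty")
    return float((background_scores > candidate_score).mean())


def adjudicate(
    genome,
    guides,
    variants: list[VariantRecord],
    flank: int = 30,
    n_background: int = 10_000,
    seed: int = 0,
    match_threshold: int = MATCH_THRESHOLD,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> tuple[pd.DataFrame, dict]:
    """Run the full off-target adjudication over all (variant, guide, site) triples.

    ``guides`` maps guide name -> 20-nt sequence (GuideSpec objects also
    accepted). Returns a report table (one row per candidate triple; variants
    with no adjacent PAM get a placeholder row) and a JSON-able summary.
    Deterministic given (inputs, seed).
    """
    genome = as_genome(genome)
    if hasattr(guides, "items"):
        guide_map = {k: str(v) for k, v in guides.items()}
    else:
        guide_map = {g.name: g.guide for g in guides}
    if not guide_map:
        raise InputError("no guides supplied")

    all_sites = scan_pam_sites(genome)
    background = sample_background_targets(all_sites, n=n_background, seed=seed)
    bg_scores = {
        name: local_align_scores(g, background.targets) for name, g in guide_map.items()
    }

    sites_by_contig: dict[str, list[PamSite]] = {}
    for s in all_sites:
        sites_by_contig.setdefault(s.contig, []).append(s)

    rows = []
    for variant in variants:
        cands = candidate_sites_near_variant(
            genome, variant, flank=flank, sites=sites_by_contig.get(variant.contig, [])
        )
        cands = [c for c in cands if not c.contains_n]
        if not cands:
            rows.append(
                dict(
                    variant=variant.key, var_class=variant.var_class, guide="",
                    site_contig=variant.contig, pam_start=-1, strand=".",
                    protospacer="", global_score=np.nan, matches=-1,
                    mismatches=-1, gaps=-1, plausible=False, local_score=np.nan,
                    p_better=np.nan, note="no adjacent PAM",
                )
            )
            continue
        for name, g in sorted(guide_map.items()):
            for site in cands:
                res = global_align(g, site.protospacer, gap_open=gap_open, gap_extend=gap_extend)
                loc = int(local_align_scores(g, [site.protospacer], gap_open=gap_open, gap_extend=gap_extend)[0])
                p = empirical_better_match_probability(
                    g, loc, background, background_scores=bg_scores[name]
                )
                rows.append(
                    dict(
                        variant=variant.key, var_class=variant.var_class, guide=name,
                        site_contig=site.contig, pam_start=site.pam_start,
                        strand=site.strand, protospacer=site.protospacer,
                        global_score=res.score, matches=res.matches,
                        mismatches=res.mismatches, gaps=res.gaps,
                        plausible=classify_plausible(res, match_threshold),
                        local_score=loc, p_better=p, note="",
                    )
                )
    report = pd.DataFrame(
        rows,
        columns=[
            "variant", "var_class", "guide", "site_contig", "pam_start", "strand",
            "protospacer", "global_score", "matches", "mismatches", "gaps",
            "plausible", "local_score", "p_better", "note",
        ],
    )
    summary = {
        "n_variants": len(variants),
        "n_candidate_rows": int((report["note"] != "no adjacent PAM").sum()),
        "n_no_adjacent_pam": int((report["note"] == "no adjacent PAM").sum()),
        "n_plausible": int(report["plausible"].sum()),
        "any_plausible_offtarget": bool(report["plausible"].any()),
        "max_matches": int(report["matches"].max()) if len(report) else 0,
        "match_threshold": match_threshold,
        "background_size": background.sample_size,
        "background_shortfall": background.shortfall,
        "gap_open": gap_open,
        "gap_extend": gap_extend,
        "seed": seed,
    }
    return report, summary


def write_report(report: pd.DataFrame, summary: dict, tsv_path, json_path=None) -> None:
    header = (
        f"# match=+{MATCH_SCORE} mismatch={MISMATCH_SCORE} "
        f"gap_open={summary['gap_open']} gap_extend={summary['gap_extend']} "
        f"match_threshold={summary['match_threshold']} "
        f"background={summary['background_size']} seed={summary['seed']}\n"
    )
    with open(tsv_path, "w") as fh:
        fh.write(header)
        report.to_csv(fh, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
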