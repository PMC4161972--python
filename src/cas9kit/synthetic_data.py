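"""Seeded generators for every input the pipeline consumes, with known truth.

Each generator is a pure function of (parameters, seed) and returns both the
dataset (in-memory and/or written to standard formats) and a ground-truth
ledger, so every downstream stage can be tested against planted truth
without any external data:

* a random genome with planted protospacer+PAM sites (and decoy
  near-guide protospacers at exact match counts),
* a sorted VCF of SNP/MNP/INDEL variants placed at known distances from
  planted sites,
* logistic growth curves with known ABC fold ratios and multiplicative
  log-normal noise,
* qPCR CT panels with a known expression ratio and Gaussian CT noise,
* binomially sampled colony counts with known targeting efficiency.

Decoy protospacers are built by mutating the guide at randomly chosen
positions, gapless by construction, so the planted global match count is
exactly 20 − (#mutated positions).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError, ParameterError
from .genome_scan import Genome, GenomeSequence, as_genome, reverse_complement
from .phenotype_stats import ColonyCounts
from .growth_fitness import GrowthCurve

BASES = "ACGT"

# Default study conditions: triplicate plate-reader curves over 3 days with
# ~1% multiplicative OD noise; qPCR in biological triplicate with ~0.1-cycle
# CT noise; fitness effect sizes {1.7, 2.6, 3.9}; sixfold sgRNA abundance.
DEFAULT_FOLDS = (("cdt1_wt", 1.0), ("cdt1_F262Y*", 1.7), ("cdt1_N209S*", 2.6), ("cdt1_quad", 3.9))
DEFAULT_LOGISTIC = (0.35, 0.15, 30.0)  # carrying capacity (OD), rate (1/hr), midpoint (hr)
DEFAULT_NOISE_CV = 0.01
DEFAULT_CT_SIGMA = 0.1
DEFAULT_REPLICATES = 3
MINUS_FRACTION = 0.15  # residual growth of the transporter-negative reference


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for a generated dataset."""

    seed: int
    planted_sites: list = field(default_factory=list)  # (contig, pam_start, strand, protospacer)
    planted_offtargets: list = field(default_factory=list)  # (variant_key, pam_start, true_match_count)
    true_efficiencies: dict = field(default_factory=dict)
    true_folds: dict = field(default_factory=dict)
    true_expression_ratio: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _random_seq(rng: np.random.Generator, length: int, gc_fraction: float) -> str:
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def make_genome(
    n_contigs: int = 1,
    lengths=(10_000,),
    gc_fraction: float = 0.38,
    planted: list | None = None,
    seed: int = 0,
) -> tuple[Genome, SyntheticTruth]:
    """Random genome with planted protospacer+PAM cassettes.

    ``planted`` entries are ``(protospacer, position, strand)`` or
    ``(contig_index, protospacer, position, strand)``; ``position`` is the
    0-based forward-strand start of the planted 23-mer (protospacer+NGG on
    '+', CCN+revcomp(protospacer) on '-'). Overlapping plants are an error.
    """
    if n_contigs != len(lengths):
        raise ParameterError("lengths must have one entry per contig")
    if not 0 < gc_fraction < 1:
        raise ParameterError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1:02d}" for i in range(n_contigs)]
    seqs = {name: list(_random_seq(rng, L, gc_fraction)) for name, L in zip(names, lengths)}
    truth = SyntheticTruth(seed=seed)
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in names}
    for entry in planted or []:
        if len(entry) == 3:
            idx, (proto, pos, strand) = 0, entry
        else:
            idx, proto, pos, strand = entry
        name = names[idx]
        proto = proto.upper()
        if len(proto) != 20 or set(proto) - set(BASES):
            raise GenerationError(f"planted protospacer must be 20-nt ACGT: {proto!r}")
        L = len(seqs[name])
        if pos < 0 or pos + 23 > L:
            raise GenerationError(f"planted cassette at {pos} does not fit contig {name}")
        for s, e in occupied[name]:
            if pos < e and pos + 23 > s:
                raise GenerationError(f"planted cassettes overlap on {name} at {pos}")
        n_base = BASES[rng.integers(0, 4)]
        if strand == "+":
            cassette = proto + n_base + "GG"
            pam_start = pos + 20
        elif strand == "-":
            cassette = "CC" + n_base + reverse_complement(proto)
            pam_start = pos
        else:
            raise GenerationError(f"invalid strand {strand!r}")
        seqs[name][pos : pos + 23] = cassette
        occupied[name].append((pos, pos + 23))
        truth.planted_sites.append((name, pam_start, strand, proto))
    genome = {name: GenomeSequence(name, "".join(chars)) for name, chars in seqs.items()}
    return genome, truth


def make_decoy_protospacer(guide: str, match_count: int, rng: np.random.Generator) -> str:
    """Mutate the guide at 20−match_count random positions (gapless by construction)."""
    if not 0 <= match_count <= 20:
        raise ParameterError("match_count must be in [0, 20]")
    guide = guide.upper()
    decoy = list(guide)
    positions = rng.choice(20, size=20 - match_count, replace=False)
    for p in positions:
        choices = [b for b in BASES if b != guide[p]]
        decoy[p] = choices[rng.integers(0, 3)]
    return "".join(decoy)


def plan_decoy_plants(
    guide: str,
    specs: list,
    contig_length: int,
    seed: int = 0,
    spacing: int = 200,
    margin: int = 100,
) -> list[tuple[str, int, str]]:
    """Lay out one planted decoy cassette per variant spec, evenly spaced.

    Returns ``(protospacer, position, strand)`` tuples for ``make_genome``;
    the i-th plant carries exactly ``specs[i].decoy_match_count`` gapless
    matches to the guide. All plants go on the forward strand so the planted
    match count is exact for the scanned protospacer.
    """
    rng = np.random.default_rng(seed)
    needed = margin + len(specs) * spacing + margin
    if needed > contig_length:
        raise GenerationError(
            f"contig of {contig_length} nt too short for {len(specs)} plants "
            f"at spacing {spacing}"
        )
    plants = []
    for i, spec in enumerate(specs):
        _, _, k = spec
        decoy = make_decoy_protospacer(guide, k, rng)
        plants.append((decoy, margin + i * spacing, "+"))
    return plants


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "{contigs}"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_vcf(records: list, genome: Genome, path) -> None:
    """Write (contig, pos_1based, ref, alt) records as a sorted plain-text VCF."""
    contigs = "".join(
        f"##contig=<ID={name},length={g.length}>\n" for name, g in genome.items()
    )
    recs = sorted(records, key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(contigs=contigs))
        for i, (contig, pos, ref, alt) in enumerate(recs, start=1):
            fh.write(f"{contig}\t{pos}\tvar{i:04d}\t{ref}\t{alt}\t100\tPASS\t.\n")


def make_variants(
    genome,
    specs: list,
    guide: str,
    seed: int = 0,
    planted_sites: list | None = None,
    truth: SyntheticTruth | None = None,
) -> tuple[list, SyntheticTruth]:
    """Place one variant per spec at a known distance from a planted decoy site.

    ``specs`` entries are ``(distance_to_site, var_class, decoy_match_count)``:
    the variant starts ``distance_to_site`` nt 3' of the PAM start of the
    spec's decoy site. ``planted_sites`` (``(contig, pam_start, strand,
    protospacer)``, e.g. from the make_genome truth) are consumed in order,
    matched to specs by decoy match count against the guide.

    Returns VCF-style records ``(contig, pos_1based, ref, alt)`` and a truth
    ledger listing each variant's paired site and true gapless match count.
    """
    genome = as_genome(genome)
    guide = guide.upper()
    rng = np.random.default_rng(seed)
    if planted_sites is None:
        raise ParameterError("planted_sites (from the genome truth) are required")
    available = list(planted_sites)
    truth = truth or SyntheticTruth(seed=seed)
    records = []
    for distance, var_class, k in specs:
        site = next(
            (
                s
                for s in available
                if sum(a == b for a, b in zip(s[3], guide)) == k
            ),
            None,
        )
        if site is None:
            raise GenerationError(f"no unused planted site with {k} matches to the guide")
        available.remove(site)
        contig_name, pam_start, strand, proto = site
        seq = genome[contig_name].residues
        pos0 = pam_start + distance  # 0-based variant start
        if var_class == "SNP":
            need = 1
        elif var_class == "MNP":
            need = 2
        elif var_class == "INDEL":
            need = 2
        else:
            raise GenerationError(f"unknown variant class {var_class!r}")
        if pos0 < 0 or pos0 + need > genome[contig_name].length:
            raise GenerationError(f"variant at distance {distance} falls off contig")
        ref = seq[pos0 : pos0 + need]
        if "N" in ref:
            raise GenerationError("variant overlaps an N base")
        if var_class == "SNP":
            alt = BASES[(BASES.index(ref) + 1 + rng.integers(0, 3)) % 4]
        elif var_class == "MNP":
            alt = "".join(
                BASES[(BASES.index(b) + 1 + rng.integers(0, 3)) % 4] for b in ref
            )
        else:  # INDEL: deletion of one base (REF 2 nt, ALT 1 nt) or 1-nt insertion
            if rng.integers(0, 2):
                alt = ref[0]
            else:
                ref = seq[pos0]
                alt = ref + BASES[rng.integers(0, 4)]
        pos1 = pos0 + 1
        records.append((contig_name, pos1, ref, alt))
        truth.planted_offtargets.append(
            (f"{contig_name}:{pos1}:{ref}>{alt}", pam_start, int(k))
        )
    records.sort(key=lambda r: (r[0], r[1]))
    return records, truth


def logistic(t: np.ndarray, K: float, r: float, t0: float) -> np.ndarray:
    return K / (1.0 + np.exp(-r * (t - t0)))


def make_growth_curves(
    strains=DEFAULT_FOLDS,
    baseline_logistic=DEFAULT_LOGISTIC,
    noise_cv: float = DEFAULT_NOISE_CV,
    replicates: int = DEFAULT_REPLICATES,
    grid: np.ndarray | None = None,
    seed: int = 0,
    minus_fraction: float = MINUS_FRACTION,
) -> tuple[list[GrowthCurve], SyntheticTruth]:
    """Triplicate logistic growth curves with exact pre-noise ABC fold ratios.

    The transporter-negative reference 'cdt1_minus' grows to ``minus_fraction``
    of the wild-type carrying capacity; each strain's noiseless curve is
    ``minus + fold·(wt − minus)``, so its true ABC ratio to the wild type is
    exactly its fold. Noise is per-point multiplicative log-normal with
    coefficient of variation ``noise_cv``.
    """
    K, r, t0 = baseline_logistic
    if K <= 0 or r <= 0:
        raise ParameterError("logistic K and r must be positive")
    if noise_cv < 0:
        raise ParameterError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 72.0 + 1e-9, 0.25) if grid is None else np.asarray(grid, dtype=float)
    wt = logistic(t, K, r, t0)
    minus = logistic(t, K * minus_fraction, r, t0)
    truth = SyntheticTruth(seed=seed, true_folds={name: f for name, f in strains})
    sigma = np.sqrt(np.log1p(noise_cv**2))  # log-normal with unit mean, CV = noise_cv
    curves = []

    def noisy(mean_od: np.ndarray) -> np.ndarray:
        if noise_cv == 0:
            return mean_od
        return mean_od * np.exp(rng.normal(-sigma**2 / 2, sigma, size=mean_od.shape))

    for rep in range(1, replicates + 1):
        curves.append(
            GrowthCurve(times=tuple(t), od=tuple(noisy(minus)), strain="cdt1_minus", replicate=rep)
        )
    for name, fold in strains:
        if fold < 0:
            raise ParameterError("true folds must be non-negative")
        mean_od = minus + fold * (wt - minus)
        for rep in range(1, replicates + 1):
            curves.append(
                GrowthCurve(times=tuple(t), od=tuple(noisy(mean_od)), strain=name, replicate=rep)
            )
    return curves, truth


def growth_curves_frame(curves: list[GrowthCurve]) -> pd.DataFrame:
    rows = [
        {"time_hr": t, "od": od, "strain": c.strain, "replicate": c.replicate}
        for c in curves
        for t, od in zip(c.times, c.od)
    ]
    return pd.DataFrame(rows, columns=["time_hr", "od", "strain", "replicate"])


def make_ct_panels(
    true_ratio: float = 6.0,
    sigma_ct: float = DEFAULT_CT_SIGMA,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    base_target_ct: float = 24.0,
    base_control_ct: float = 19.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """CT panels for test ('with_ribozyme') vs reference ('without_ribozyme').

    The test condition's target CT is shifted down by log2(true_ratio), so the
    noiseless ΔΔCT is −log2(true_ratio) and the recovered fold is true_ratio.
    """
    if true_ratio <= 0:
        raise ParameterError("true_ratio must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    shift = float(np.log2(true_ratio))
    for condition, target_mean in (
        ("without_ribozyme", base_target_ct),
        ("with_ribozyme", base_target_ct - shift),
    ):
        for rep in range(1, replicates + 1):
            rows.append(
                {
                    "condition": condition,
                    "replicate": rep,
                    "target_ct": target_mean + (rng.normal(0, sigma_ct) if sigma_ct else 0.0),
                    "control_ct": base_control_ct + (rng.normal(0, sigma_ct) if sigma_ct else 0.0),
                }
            )
    truth = SyntheticTruth(seed=seed, true_expression_ratio=float(true_ratio))
    return pd.DataFrame(rows), truth


def make_colony_counts(
    true_p: float, n: int, seed: int = 0, experiment: str = "targeting"
) -> tuple[ColonyCounts, SyntheticTruth]:
    """Binomially sampled colony counts with known targeting efficiency."""
    if not 0 <= true_p <= 1:
        raise ParameterError("true_p must be in [0, 1]")
    if n <= 0:
        raise ParameterError("n must be positive")
    rng = np.random.default_rng(seed)
    positives = int(rng.binomial(n, true_p))
    truth = SyntheticTruth(seed=seed, true_efficiencies={experiment: float(true_p)})
    return ColonyCounts(experiment, n, positives), truth
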