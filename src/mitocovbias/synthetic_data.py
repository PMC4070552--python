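"""Synthetic references, site profiles and reads with known ground truth.

The generator emulates the statistical structure of ultra-deep sequencing of
a circular mtDNA molecule across a cohort of individuals:

* a GC-dependent, quadratic-in-log-space coverage bias whose vertex sits
  near the lower end of the GC range, so the GC/coverage relationship is
  essentially negative over most windows;
* a lognormal site effect shared across individuals (making per-site
  coverage repeatable between libraries) plus independent lognormal
  individual noise, with Poisson counting noise on top;
* CCNGCC error-prone motifs planted on either strand, a subset of which is
  "active": the focal base directly upstream (in motif orientation) gets an
  elevated error rate and coverage dips linearly within a configurable
  range of the motif;
* a uniform low baseline of substitution errors (default 0.1% per base);
* a handful of heteroplasmic (site, individual) pairs carrying one specific
  alternative allele at an intermediate frequency.

Every draw flows from a single integer seed, so outputs are reproducible
byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .error_profile import MotifHit, reverse_complement
from .gc_bias import site_gc50
from .io_formats import (
    BASES,
    BASE_INDEX,
    AnnotatedReference,
    SiteProfile,
    write_fasta,
    write_pileup,
)

MOTIF = "CCNGCC"


def _uniform_substitution_matrix() -> np.ndarray:
    m = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(m, 0.0)
    return m


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror an ultra-deep mtDNA resequencing design: an ~16.5-kb
    circular genome at ~40% GC, eleven individuals at several-thousand-fold
    depth, 0.1% baseline per-base error, 22 planted CCNGCC motifs of which
    three are active error/coverage anomalies, and six heteroplasmic sites
    with allele frequencies between 1.3% and 67.9%.
    """

    seed: int = 0
    L_ref: int = 16_500
    gc_target: float = 0.40
    n_individuals: int = 11
    mean_depth: float = 4_000.0  # per individual (X); scalar applies to all
    vertex_gc: float = 0.27  # GC fraction at the log-mean coverage peak
    gc_curvature: float = -8.0  # quadratic coefficient in log mean coverage
    site_effect_sd: float = 0.25  # lognormal sigma, shared across individuals
    individual_noise_sd: float = 0.10  # lognormal sigma, per individual
    n_motifs: int = 22
    n_motifs_active: int = 3
    motif_dip_depth: float = 0.4  # fractional coverage loss at the motif edge
    motif_dip_range: int = 100  # bp over which the dip decays to zero
    e0: float = 0.001  # baseline per-base error rate
    e_motif: float = 0.02  # error rate at active motif focal sites
    n_heteroplasmic: int = 6
    het_freq_range: tuple[float, float] = (0.013, 0.679)
    substitution_matrix: np.ndarray = field(default_factory=_uniform_substitution_matrix)

    def __post_init__(self):
        self.substitution_matrix = np.asarray(self.substitution_matrix, dtype=float)
        for name in ("gc_target", "motif_dip_depth", "e0", "e_motif"):
            v = getattr(self, name)
            if not 0 <= v < 1 and name != "gc_target":
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0 <= self.gc_target <= 1:
            raise ValueError("gc_target must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        lo, hi = self.het_freq_range
        if not 0 < lo <= hi < 1:
            raise ValueError("het_freq_range must satisfy 0 < lo <= hi < 1")

    def mean_depths(self) -> np.ndarray:
        d = np.asarray(self.mean_depth, dtype=float)
        if d.ndim == 0:
            return np.full(self.n_individuals, float(d))
        if len(d) != self.n_individuals:
            raise ValueError("mean_depth list length != n_individuals")
        return d


@dataclass
class TruthTable:
    """Generating values the simulator committed to, for recovery tests."""

    site_multiplier: np.ndarray  # expected coverage multiplier, mean 1
    motifs: list[MotifHit]
    active_motifs: list[MotifHit]
    focal_sites: np.ndarray  # high-error base of each active motif
    heteroplasmies: list[dict]  # pos, individual_id, alt_base, freq
    error_rate: np.ndarray  # true per-site substitution error rate


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

_TILE = (  # (gene_type, length, strand) blocks, cycled over the genome
    ("protein_coding", 1_000, "+"),
    ("intergenic", 60, "+"),
    ("tRNA", 70, "+"),
    ("intergenic", 40, "+"),
    ("rRNA", 800, "-"),
    ("intergenic", 50, "+"),
)


def _tile_annotation(L: int) -> list:
    features = []
    pos = 0
    while pos < L:
        for gene_type, length, strand in _TILE:
            end = min(pos + length, L)
            if gene_type != "intergenic":  # gaps are filled implicitly
                features.append((pos, end, gene_type, strand))
            pos = end
            if pos >= L:
                break
    return features


def generate_reference(config: SimulationConfig) -> tuple[AnnotatedReference, list[MotifHit]]:
    """I.i.d. random circular reference with planted CCNGCC motifs.

    Bases are drawn at ``gc_target``; ``n_motifs`` motif copies (random N
    base, random strand) overwrite the sequence at non-overlapping positions
    away from the origin. A simple alternating gene annotation is attached.
    """
    if config.L_ref <= 200:
        raise ValueError("L_ref must exceed 200")
    rng = np.random.default_rng(config.seed)
    p = np.array(
        [
            (1 - config.gc_target) / 2,
            config.gc_target / 2,
            config.gc_target / 2,
            (1 - config.gc_target) / 2,
        ]
    )
    seq = np.array(list(BASES))[rng.choice(4, size=config.L_ref, p=p)]
    m = len(MOTIF)
    placed: list[tuple[int, str]] = []
    attempts = 0
    while len(placed) < config.n_motifs:
        attempts += 1
        if attempts > 100 * config.n_motifs + 1000:
            raise ValueError("could not place motifs without overlap")
        start = int(rng.integers(config.motif_dip_range + m, config.L_ref - m))
        if any(abs(start - s) < m for s, _ in placed):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        placed.append((start, strand))
    hits = []
    for start, strand in sorted(placed):
        concrete = MOTIF.replace("N", BASES[int(rng.integers(4))])
        if strand == "-":
            concrete = reverse_complement(concrete)
        seq[start : start + m] = list(concrete)
        hits.append(MotifHit(start=start, end=start + m, strand=strand, pattern=MOTIF))
    sequence = "".join(seq)
    ref = AnnotatedReference(
        name="synthetic_mtDNA",
        sequence=sequence,
        circular=True,
        features=_tile_annotation(config.L_ref),
    )
    return ref, hits


# ---------------------------------------------------------------------------
# Site profiles
# ---------------------------------------------------------------------------


def _binomial_split(rng, n: np.ndarray, probs: np.ndarray) -> list[np.ndarray]:
    """Vectorized multinomial via a chain of binomials (probs sum to 1)."""
    out = []
    remaining = n.copy()
    p_left = 1.0
    for p in probs[:-1]:
        frac = 0.0 if p_left <= 0 else min(1.0, p / p_left)
        draw = rng.binomial(remaining, frac)
        out.append(draw)
        remaining = remaining - draw
        p_left -= p
    out.append(remaining)
    return out


def simulate_site_profiles(
    reference: AnnotatedReference,
    config: SimulationConfig,
    motifs: list[MotifHit] | None = None,
) -> tuple[list[SiteProfile], TruthTable]:
    """Draw per-site, per-individual base counts from the generative model.

    Expected coverage at site i for individual j is
    ``mean_depth_j * mult_i * eta_ij`` where ``mult_i`` combines the
    GC-quadratic log-mean, the shared lognormal site effect and the motif
    dip (normalized to mean 1), and ``eta_ij`` is lognormal individual
    noise. Realized depth is Poisson; base counts are multinomial with the
    consensus base at probability ``1 - e_i`` and errors spread over the
    alternatives by the substitution matrix. Heteroplasmic (site,
    individual) pairs mix in one alternative allele at their drawn
    frequency.
    """
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))
    L = len(reference)
    seq = reference.sequence
    cons_idx = np.array([BASE_INDEX.get(b, 0) for b in seq])

    gc50 = site_gc50(seq, 50)
    q = np.exp(config.gc_curvature * (np.nan_to_num(gc50, nan=config.gc_target) - config.vertex_gc) ** 2)
    s = rng.lognormal(0.0, config.site_effect_sd, size=L) if config.site_effect_sd > 0 else np.ones(L)

    if motifs is None:
        motifs = []
    active = list(motifs[: config.n_motifs_active]) if config.n_motifs_active else []
    if config.n_motifs_active and motifs:
        idx = rng.choice(len(motifs), size=min(config.n_motifs_active, len(motifs)), replace=False)
        active = [motifs[i] for i in sorted(idx)]
    dip = np.ones(L)
    focal = []
    rng_range = config.motif_dip_range
    for h in active:
        if h.strand == "+":
            focal_site = (h.start - 1) % L
            dip[h.start : h.end] *= 1 - config.motif_dip_depth
            for d in range(1, rng_range + 1):
                pos = (h.start - d) % L
                dip[pos] *= 1 - config.motif_dip_depth * (rng_range - d + 1) / rng_range
        else:
            focal_site = h.end % L
            dip[h.start : h.end] *= 1 - config.motif_dip_depth
            for d in range(1, rng_range + 1):
                pos = (h.end - 1 + d) % L
                dip[pos] *= 1 - config.motif_dip_depth * (rng_range - d + 1) / rng_range
        focal.append(focal_site)
    focal = np.array(sorted(set(focal)), dtype=int)

    mult = q * s * dip
    mult = mult / mult.mean()

    e_site = np.full(L, config.e0)
    e_site[focal] = config.e_motif

    # heteroplasmies: distinct non-focal sites, random carrier and allele
    het = []
    if config.n_heteroplasmic:
        candidates = np.setdiff1d(np.arange(L), focal)
        sites = rng.choice(candidates, size=config.n_heteroplasmic, replace=False)
        lo, hi = config.het_freq_range
        for pos in sorted(int(x) for x in sites):
            carrier = int(rng.integers(config.n_individuals))
            alts = [b for b in range(4) if b != cons_idx[pos]]
            alt = int(alts[int(rng.integers(3))])
            freq = float(rng.uniform(lo, hi))
            het.append(
                {
                    "pos": pos,
                    "individual": carrier,
                    "alt_base": BASES[alt],
                    "freq": freq,
                }
            )

    depths_target = config.mean_depths()
    profiles = []
    sub = config.substitution_matrix
    for j in range(config.n_individuals):
        eta = (
            rng.lognormal(0.0, config.individual_noise_sd, size=L)
            if config.individual_noise_sd > 0
            else np.ones(L)
        )
        mu = depths_target[j] * mult * eta
        depth = rng.poisson(mu)
        n_err = rng.binomial(depth, e_site)
        n_cons = depth - n_err
        counts = np.zeros((L, 4), dtype=np.int64)
        counts[np.arange(L), cons_idx] += n_cons
        # distribute errors over the three alternatives per consensus base
        for ci in range(4):
            mask = cons_idx == ci
            if not mask.any():
                continue
            alts = [b for b in range(4) if b != ci]
            probs = sub[ci, alts]
            probs = probs / probs.sum()
            split = _binomial_split(rng, n_err[mask], probs)
            for b, cnt in zip(alts, split):
                counts[np.flatnonzero(mask), b] += cnt
        # overlay heteroplasmy for this individual
        for h in het:
            if h["individual"] != j:
                continue
            pos = h["pos"]
            d = int(depth[pos])
            alt_b = BASE_INDEX[h["alt_base"]]
            n_alt = rng.binomial(d, h["freq"])
            # replace a random subset of existing bases with the alt allele
            counts[pos] = 0
            counts[pos, cons_idx[pos]] = d - n_alt
            counts[pos, alt_b] = n_alt
        profiles.append(
            SiteProfile(
                individual_id=f"ind{j:02d}",
                positions=np.arange(L),
                ref_bases=np.array(list(seq)),
                counts=counts,
                n_del=np.zeros(L, dtype=np.int64),
            )
        )

    for h in het:
        h["individual_id"] = f"ind{h['individual']:02d}"

    truth = TruthTable(
        site_multiplier=mult,
        motifs=list(motifs),
        active_motifs=active,
        focal_sites=focal,
        heteroplasmies=het,
        error_rate=e_site,
    )
    return profiles, truth


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def simulate_reads(
    reference: AnnotatedReference,
    depth: float,
    read_len: int,
    e0: float,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Uniform reads from the circular reference with i.i.d. substitutions.

    Returns (name, sequence, quality) triples; read count is
    ``round(depth * L / read_len)`` so expected base coverage is ``depth``.
    """
    L = len(reference)
    if read_len > L:
        raise ValueError("read_len exceeds reference length")
    rng = np.random.default_rng(seed)
    n_reads = int(round(depth * L / read_len))
    doubled = reference.sequence + reference.sequence[: read_len - 1]
    reads = []
    starts = rng.integers(0, L, size=n_reads)
    for i, start in enumerate(starts):
        seq = np.array(list(doubled[start : start + read_len]))
        if e0 > 0:
            err_pos = np.flatnonzero(rng.random(read_len) < e0)
            for pos in err_pos:
                alts = [b for b in BASES if b != seq[pos]]
                seq[pos] = alts[int(rng.integers(len(alts)))]
        reads.append((f"read{i:07d}", "".join(seq), "I" * read_len))
    return reads


def write_fastq(reads: list[tuple[str, str, str]], dest) -> None:
    close = False
    if isinstance(dest, (str, Path)):
        dest, close = open(dest, "w"), True
    try:
        for name, seq, qual in reads:
            dest.write(f"@{name}\n{seq}\n+\n{qual}\n")
    finally:
        if close:
            dest.close()


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------


def emit_truth_and_pileups(
    profiles: list[SiteProfile],
    truth: TruthTable,
    reference: AnnotatedReference,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write one pileup per individual plus reference, BED and truth TSVs.

    Pileup emission is inverse-consistent with the pileup parser. Returns a
    name -> path map of everything written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    ref_path = out / "reference.fa"
    write_fasta([(reference.name, reference.sequence)], ref_path)
    written["reference"] = ref_path

    bed_path = out / "genes.bed"
    with open(bed_path, "w") as fh:
        for i, (start, end, gene_type, strand) in enumerate(reference.features):
            fh.write(
                f"{reference.name}\t{start}\t{end}\tg{i:03d}\t0\t{strand}\t{gene_type}\n"
            )
    written["annotation"] = bed_path

    for p in profiles:
        path = out / f"{p.individual_id}.pileup"
        write_pileup(p, path, chrom=reference.name)
        written[p.individual_id] = path

    het_path = out / "truth_heteroplasmy.tsv"
    with open(het_path, "w") as fh:
        fh.write("pos\tindividual\talt_base\tfreq\n")
        for h in truth.heteroplasmies:
            fh.write(f"{h['pos']}\t{h['individual_id']}\t{h['alt_base']}\t{h['freq']:.6f}\n")
    written["truth_heteroplasmy"] = het_path

    site_path = out / "truth_sites.tsv"
    with open(site_path, "w") as fh:
        fh.write("pos\tcoverage_multiplier\terror_rate\n")
        for i in range(len(truth.site_multiplier)):
            fh.write(f"{i}\t{truth.site_multiplier[i]:.6g}\t{truth.error_rate[i]:.6g}\n")
    written["truth_sites"] = site_path

    motif_path = out / "truth_motifs.tsv"
    with open(motif_path, "w") as fh:
        fh.write("start\tend\tstrand\tactive\n")
        active_starts = {h.start for h in truth.active_motifs}
        for h in truth.motifs:
            fh.write(f"{h.start}\t{h.end}\t{h.strand}\t{int(h.start in active_starts)}\n")
    written["truth_motifs"] = motif_path
    return written
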