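"""Site-specific sequencing errors, error-prone motifs, and heteroplasmy.

At ultra-deep coverage every site shows a low background of non-consensus
read bases; treated per site, the mismatch fraction is the site-specific
error rate. Its structure is profiled three ways: the substitution spectrum
and transition/transversion ratio (uniform random error gives ti/tv near
0.5, real variation is usually much higher), proximity of coverage dips to
sequence-specific-error motifs such as CCNGCC, and the rank correlation of
error rate with coverage. Sites where exactly one individual carries an
intermediate-frequency non-consensus allele while all others are clean are
classified as heteroplasmic rather than as errors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import BASES, BASE_INDEX, SiteProfile

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


# ---------------------------------------------------------------------------
# Rank correlation (shared by several analyses)
# ---------------------------------------------------------------------------


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns (r, df, p) with df = n - 2 and a t-approximation p-value.
    A constant input vector leaves r undefined (NaN), reported as such.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("input lengths differ")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    df = n - 2
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), df, float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if abs(r) >= 1.0:
        return float(np.sign(r)), df, 0.0
    t = r * np.sqrt(df / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), df)
    return r, df, float(p)


# ---------------------------------------------------------------------------
# Consensus and per-site error rates
# ---------------------------------------------------------------------------


def consensus_from_counts(
    profiles: list[SiteProfile], ref_bases: np.ndarray | None = None
) -> str:
    """Majority-vote consensus from pooled base counts across individuals.

    Ties break toward the provided reference base when it is among the tied
    maxima, else alphabetically. Zero pooled depth gives 'N'.
    """
    if not profiles:
        raise ValueError("no profiles given")
    pooled = np.zeros_like(profiles[0].counts)
    for p in profiles:
        if p.counts.shape != pooled.shape:
            raise ValueError("profiles cover different site sets")
        pooled = pooled + p.counts
    out = []
    for i, row in enumerate(pooled):
        total = row.sum()
        if total == 0:
            out.append("N")
            continue
        best = row.max()
        tied = [BASES[j] for j in range(4) if row[j] == best]
        if ref_bases is not None and ref_bases[i] in tied:
            out.append(str(ref_bases[i]))
        else:
            out.append(tied[0])
    return "".join(out)


@dataclass
class SiteErrorRates:
    """Per-site mismatch fraction e = (depth - n_consensus)/depth."""

    positions: np.ndarray
    rates: np.ndarray  # NaN where depth == 0
    consensus: str

    def summary(self) -> dict:
        ok = ~np.isnan(self.rates)
        if not ok.any():
            return {"mean": float("nan"), "min": float("nan"), "max": float("nan"), "n": 0}
        r = self.rates[ok]
        return {
            "mean": float(r.mean()),
            "min": float(r.min()),
            "max": float(r.max()),
            "n": int(ok.sum()),
        }


def site_error_rates(profile: SiteProfile, consensus: str) -> SiteErrorRates:
    """Per-site error rate of one individual against a consensus sequence.

    Deletions are excluded from both numerator and depth; sites with zero
    depth or an 'N' consensus get NaN.
    """
    if len(consensus) != len(profile):
        raise ValueError("consensus length does not match profile")
    depth = profile.depth.astype(float)
    cons_idx = np.array([BASE_INDEX.get(b, -1) for b in consensus])
    n_cons = np.where(
        cons_idx >= 0,
        profile.counts[np.arange(len(profile)), np.clip(cons_idx, 0, 3)],
        0,
    ).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where((depth > 0) & (cons_idx >= 0), (depth - n_cons) / depth, np.nan)
    return SiteErrorRates(profile.positions.copy(), rates, consensus)


def substitution_spectrum(
    profiles: list[SiteProfile], consensus: str
) -> tuple[pd.DataFrame, float]:
    """Pooled 4x4 substitution-rate table and transition/transversion ratio.

    Entry (x, y) is the pooled count of read base y at consensus-x sites
    divided by pooled depth at those sites; diagonal entries are match
    rates. Rows for consensus bases never observed are NaN (undefined, not
    zero). ti/tv pools A<->G and C<->T mismatch counts against all others.
    """
    counts = np.zeros((4, 4), dtype=np.int64)  # rows consensus, cols read base
    cons_idx = np.array([BASE_INDEX.get(b, -1) for b in consensus])
    for p in profiles:
        if len(p) != len(consensus):
            raise ValueError("consensus length does not match profile")
        for xi in range(4):
            mask = cons_idx == xi
            counts[xi] += p.counts[mask].sum(axis=0)
    depth_per_row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(depth_per_row > 0, counts / depth_per_row, np.nan)
    table = pd.DataFrame(rates, index=list(BASES), columns=list(BASES))
    ti = sum(counts[BASE_INDEX[x], BASE_INDEX[y]] for x, y in TRANSITIONS)
    tv = counts.sum() - np.trace(counts) - ti
    titv = float(ti / tv) if tv > 0 else float("nan")
    return table, titv


# ---------------------------------------------------------------------------
# IUPAC motif scanning and proximity analysis
# ---------------------------------------------------------------------------


@dataclass
class MotifHit:
    """One motif occurrence; the error-prone flank sits upstream of a
    +-strand hit (equivalently downstream of the reverse complement)."""

    start: int
    end: int  # start + pattern length; exceeds L for origin-spanning hits
    strand: str
    pattern: str

    def flank_sites(
        self, flank: int, region_length: int, circular: bool = False
    ) -> list[tuple[int, int]]:
        """(position, 1-based distance to the motif edge) pairs for the
        error-prone flank, clipped at region edges or wrapped if circular."""
        if self.strand == "+":
            raw = [(p, self.start - p) for p in range(self.start - flank, self.start)]
        else:
            raw = [(p, p - self.end + 1) for p in range(self.end, self.end + flank)]
        if circular:
            return [(p % region_length, d) for p, d in raw]
        return [(p, d) for p, d in raw if 0 <= p < region_length]


def reverse_complement(pattern: str) -> str:
    return pattern.translate(_COMPLEMENT)[::-1]


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r}")
        alts = IUPAC[ch]
        parts.append(alts if len(alts) == 1 else f"[{alts}]")
    return re.compile("(?=" + "".join(parts) + ")")  # lookahead: overlapping hits


def scan_iupac_motifs(sequence: str, pattern: str, circular: bool = False) -> list[MotifHit]:
    """All overlapping hits of ``pattern`` (+ strand) and of its reverse
    complement (reported as strand -) on the given sequence.

    With ``circular=True`` matches spanning the origin are also found; their
    ``start`` is wrapped into [0, L) while ``end`` stays ``start + len``.
    """
    sequence = sequence.upper()
    L = len(sequence)
    m = len(pattern)
    search_space = sequence + (sequence[: m - 1] if circular and m > 1 else "")
    hits = []
    for strand, pat in (("+", pattern), ("-", reverse_complement(pattern))):
        rx = _iupac_regex(pat)
        for match in rx.finditer(search_space):
            s = match.start()
            if s >= L:  # duplicate of an unwrapped hit
                continue
            hits.append(MotifHit(start=s, end=s + m, strand=strand, pattern=pattern))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def motif_proximity_analysis(
    coverage: np.ndarray,
    hits: list[MotifHit],
    flank: int = 100,
    circular: bool = False,
) -> tuple[pd.DataFrame, float, int, float]:
    """Coverage vs distance to the nearest error-prone motif flank.

    Each site inside any hit's ``flank``-bp error-prone window (upstream of
    + hits, downstream of - hits) enters once with its minimum 1-based
    distance to a motif edge. Returns (per-site table, Spearman r, df, p);
    r > 0 means coverage rises with distance from the motif.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if not hits:
        raise ValueError("no motif hits supplied")
    coverage = np.asarray(coverage, dtype=float)
    L = len(coverage)
    dist: dict[int, int] = {}
    for h in hits:
        for pos, d in h.flank_sites(flank, L, circular=circular):
            if pos not in dist or d < dist[pos]:
                dist[pos] = d
    positions = np.array(sorted(dist), dtype=int)
    distances = np.array([dist[p] for p in positions], dtype=int)
    table = pd.DataFrame(
        {"pos": positions, "distance": distances, "coverage": coverage[positions]}
    )
    r, df, p = spearman(table["coverage"].to_numpy(), table["distance"].to_numpy())
    if np.isnan(r):  # constant coverage: all ranks tie -> no association
        r, p = 0.0, 1.0
    return table, r, df, p


def error_coverage_correlation(
    error_rates: np.ndarray, coverage: np.ndarray
) -> tuple[float, int, float]:
    """Spearman correlation of site error rate with site coverage (df = n-2)."""
    error_rates = np.asarray(error_rates, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    ok = ~(np.isnan(error_rates) | np.isnan(coverage))
    return spearman(error_rates[ok], coverage[ok])


# ---------------------------------------------------------------------------
# Heteroplasmy
# ---------------------------------------------------------------------------


@dataclass
class HeteroplasmyCall:
    pos: int
    carrier_individual: str
    alt_base: str
    alt_freq: float
    max_other_freq: float


def call_heteroplasmy(
    profiles: list[SiteProfile],
    consensus: str,
    high_freq: float = 0.01,
    low_freq: float = 0.001,
    min_depth: int = 100,
    others_rule: str = "pooled",
) -> tuple[list[HeteroplasmyCall], list[dict]]:
    """Flag sites where exactly one individual carries an intermediate-
    frequency non-consensus allele.

    A site is heteroplasmic iff one individual shows a specific non-consensus
    base at frequency >= ``high_freq`` (at depth >= ``min_depth``) while the
    remaining individuals carry that base only at background level. With
    ``others_rule='pooled'`` (default) the background check is on the pooled
    frequency of that base across all other individuals, <= ``low_freq``;
    pooling keeps a single few-read fluctuation in one shallow individual
    from vetoing a true call when ``low_freq`` sits at the baseline error rate.
    ``others_rule='each'`` instead requires every other individual's own
    frequency to be <= ``low_freq``. Sites where two or more individuals
    exceed ``high_freq`` are returned separately as shared variants, not
    heteroplasmy.
    """
    if len(profiles) < 2:
        raise ValueError("heteroplasmy criterion needs at least 2 individuals")
    if others_rule not in ("pooled", "each"):
        raise ValueError("others_rule must be 'pooled' or 'each'")
    n_sites = len(consensus)
    for p in profiles:
        if len(p) != n_sites:
            raise ValueError("consensus length does not match profile")
    cons_idx = np.array([BASE_INDEX.get(b, -1) for b in consensus])

    depth = np.stack([p.depth for p in profiles])  # (n_ind, n_sites)
    freqs = np.stack(
        [
            np.divide(
                p.counts.T,
                np.maximum(p.depth, 1),
                dtype=float,
            )
            for p in profiles
        ]
    )  # (n_ind, 4, n_sites)

    calls: list[HeteroplasmyCall] = []
    shared: list[dict] = []
    for site in np.flatnonzero(cons_idx >= 0):
        alt_idx = [b for b in range(4) if b != cons_idx[site]]
        exceed = [
            (i, b)
            for i in range(len(profiles))
            for b in alt_idx
            if freqs[i, b, site] >= high_freq and depth[i, site] >= min_depth
        ]
        carriers = sorted({i for i, _ in exceed})
        if len(carriers) >= 2:
            shared.append(
                {
                    "pos": int(site),
                    "individuals": [profiles[i].individual_id for i in carriers],
                    "bases": sorted({BASES[b] for _, b in exceed}),
                }
            )
            continue
        if len(carriers) != 1:
            continue
        carrier = carriers[0]
        # the carrier's specific alternative allele: its highest exceeding base
        b = max((b for i, b in exceed), key=lambda b: freqs[carrier, b, site])
        others = [i for i in range(len(profiles)) if i != carrier]
        other_freqs = freqs[others, b, site]
        if others_rule == "pooled":
            pooled_depth = depth[others, site].sum()
            pooled_count = sum(profiles[i].counts[site, b] for i in others)
            low_ok = pooled_depth > 0 and pooled_count / pooled_depth <= low_freq
        else:
            low_ok = bool(np.all(other_freqs <= low_freq))
        if low_ok:
            calls.append(
                HeteroplasmyCall(
                    pos=int(site),
                    carrier_individual=profiles[carrier].individual_id,
                    alt_base=BASES[b],
                    alt_freq=float(freqs[carrier, b, site]),
                    max_other_freq=float(other_freqs.max()) if others else 0.0,
                )
            )
    return calls, shared
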