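"""Within-species repeatability and cross-species conservation of coverage.

If coverage heterogeneity is driven by the sequence itself rather than by
library-to-library noise, independently sequenced individuals should show
rank-correlated per-site profiles, and homologous regions of two distant
species should correlate at the nucleotide level once mapped through a
pairwise alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage_profile import CoverageProfile
from .error_profile import spearman
from .io_formats import PathOrStream, read_fasta_records


def pairwise_profile_correlation(profiles: list[CoverageProfile]) -> pd.DataFrame:
    """Spearman correlation for every unordered pair of coverage profiles.

    Returns a long-form DataFrame (individual_a, individual_b, r, df, p)
    including the unit diagonal; a constant profile yields NaN entries.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    n_sites = {len(p) for p in profiles}
    if len(n_sites) != 1:
        raise ValueError("profiles have different lengths")
    if n_sites.pop() < 3:
        raise ValueError("need at least 3 sites")
    rows = []
    for i, a in enumerate(profiles):
        for b in profiles[i:]:
            if a is b:
                r, df, p = 1.0, len(a) - 2, 0.0
            else:
                r, df, p = spearman(a.values, b.values)
            rows.append((a.individual_id, b.individual_id, r, df, p))
    return pd.DataFrame(rows, columns=["individual_a", "individual_b", "r", "df", "p"])


def correlation_matrix(pairs: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-form pair table into a symmetric matrix of r values."""
    ids = list(dict.fromkeys(pairs["individual_a"]))
    mat = pd.DataFrame(np.nan, index=ids, columns=ids)
    for _, row in pairs.iterrows():
        mat.loc[row["individual_a"], row["individual_b"]] = row["r"]
        mat.loc[row["individual_b"], row["individual_a"]] = row["r"]
    return mat


def concordance_windows(profiles: list[CoverageProfile], window: int) -> pd.DataFrame:
    """Cross-individual coefficient of variation of window-mean coverage.

    Profiles must be scaled to a common mean first. Returns one row per
    window, sorted ascending by CV (most concordant first), with columns
    window_start, cv, mean_cov.
    """
    if not profiles:
        raise ValueError("no profiles")
    L = len(profiles[0])
    if any(len(p) != L for p in profiles):
        raise ValueError("profiles have different lengths")
    if window > L:
        raise ValueError("window exceeds profile length")
    starts = np.arange(0, L - window + 1, window)
    rows = []
    for s in starts:
        means = np.array([p.values[s : s + window].mean() for p in profiles])
        mu = means.mean()
        cv = float(means.std(ddof=1) / mu) if mu > 0 else float("nan")
        rows.append((int(s), cv, float(mu)))
    out = pd.DataFrame(rows, columns=["window_start", "cv", "mean_cov"])
    return out.sort_values("cv", kind="mergesort").reset_index(drop=True)


@dataclass
class AlignmentColumnMap:
    """Column-wise coordinate map of a pairwise alignment.

    ``columns`` has one row per alignment column: block id, column index,
    pos_a, pos_b (species coordinates, -1 at a gap). ``identity`` is the
    fraction of matching bases over columns ungapped in both species.
    """

    columns: pd.DataFrame
    identity: float
    block_ids: list = field(default_factory=list)

    def paired_positions(self) -> pd.DataFrame:
        """Rows for columns ungapped in both species."""
        return self.columns[(self.columns["pos_a"] >= 0) & (self.columns["pos_b"] >= 0)]


def alignment_column_map(source: PathOrStream) -> AlignmentColumnMap:
    """Build a coordinate map from a two-rows-per-block aligned multi-FASTA.

    Records are paired in file order (block i = records 2i, 2i+1); gap
    character is '-'. Species coordinates advance only on non-gap columns;
    identity is computed over columns where both rows are ungapped.
    """
    records = read_fasta_records(source)
    if len(records) % 2 != 0:
        raise ValueError("alignment input needs two records per block")
    rows = []
    match = total = 0
    block_ids = []
    for b in range(len(records) // 2):
        (name_a, row_a), (name_b, row_b) = records[2 * b], records[2 * b + 1]
        if len(row_a) != len(row_b):
            raise ValueError(
                f"block {b}: aligned rows {name_a!r}/{name_b!r} have unequal lengths"
            )
        block_ids.append((name_a, name_b))
        pos_a = pos_b = 0
        for col, (ca, cb) in enumerate(zip(row_a, row_b)):
            pa = pos_a if ca != "-" else -1
            pb = pos_b if cb != "-" else -1
            rows.append((b, col, pa, pb))
            if ca != "-" and cb != "-":
                total += 1
                match += ca == cb
            pos_a += ca != "-"
            pos_b += cb != "-"
    columns = pd.DataFrame(rows, columns=["block", "column", "pos_a", "pos_b"])
    identity = match / total if total else float("nan")
    return AlignmentColumnMap(columns=columns, identity=identity, block_ids=block_ids)


def cross_species_site_correlation(
    profile_a: CoverageProfile,
    profile_b: CoverageProfile,
    column_map: AlignmentColumnMap,
) -> dict:
    """Coverage correlation between two species over homologous sites.

    Uses only alignment columns ungapped in BOTH species, pooled across
    blocks (per-block r is reported alongside). df = n_sites - 2.
    """
    paired = column_map.paired_positions()
    if len(paired) < 3:
        raise ValueError("fewer than 3 usable alignment columns")
    pa = paired["pos_a"].to_numpy()
    pb = paired["pos_b"].to_numpy()
    if pa.max() >= len(profile_a) or pb.max() >= len(profile_b):
        raise ValueError("alignment positions fall outside a profile's retained span")
    cov_a = profile_a.values[pa]
    cov_b = profile_b.values[pb]
    r, df, p = spearman(cov_a, cov_b)
    per_block = {}
    for block, grp in paired.groupby("block"):
        if len(grp) >= 3:
            rb, dfb, pb_ = spearman(
                profile_a.values[grp["pos_a"].to_numpy()],
                profile_b.values[grp["pos_b"].to_numpy()],
            )
            per_block[int(block)] = {"r": rb, "df": dfb, "p": pb_, "n_sites": len(grp)}
    return {"r": r, "df": df, "p": p, "n_sites": len(paired), "per_block": per_block}
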