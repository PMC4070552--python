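"""From raw site profiles to analysis-ready circular coverage profiles.

Circular mtDNA is mapped against a linearized reference extended by an
``o``-bp copy of its start, so reads spanning the origin still map; the
extension is folded back before analysis. The ends of the folded profile
(and the repeat-rich control region) remain unreliable and are trimmed to a
configured retained span. Profiles from different individuals are brought to
a common mean before comparison, and coverage is summarized with GC content
in sliding windows for the regression stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CoverageProfile:
    """Per-site depth for one individual over the retained region.

    ``retained_span`` is (first_kept, last_kept), 1-based inclusive, in the
    coordinates of the folded, untrimmed reference.
    """

    individual_id: str
    values: np.ndarray
    retained_span: tuple[int, int]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        first, last = self.retained_span
        if len(self.values) != last - first + 1:
            raise ValueError(
                f"values length {len(self.values)} != span length {last - first + 1}"
            )
        if np.any(self.values < 0):
            raise ValueError("negative coverage")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def fold_circular_overlap(extended_values: np.ndarray, ref_length: int, overlap: int) -> np.ndarray:
    """Fold depth mapped onto a linearized circle back onto the circle.

    The mapping reference is the circular sequence of length ``ref_length``
    extended by a copy of its first ``overlap`` bases; coverage landing on
    the extension belongs to positions 0..overlap-1. Total mass is conserved.
    """
    extended_values = np.asarray(extended_values, dtype=float)
    if overlap < 0 or overlap >= ref_length:
        raise ValueError(f"overlap {overlap} must satisfy 0 <= o < L_ref")
    if len(extended_values) != ref_length + overlap:
        raise ValueError(
            f"extended length {len(extended_values)} != L_ref + o = {ref_length + overlap}"
        )
    out = extended_values[:ref_length].copy()
    if overlap:
        out[:overlap] += extended_values[ref_length:]
    return out


def trim_retained_region(
    values: np.ndarray, first_kept: int, last_kept: int
) -> tuple[np.ndarray, int]:
    """Keep the 1-based inclusive span [first_kept, last_kept]; report bp trimmed."""
    values = np.asarray(values)
    L = len(values)
    if not (1 <= first_kept <= last_kept <= L):
        raise ValueError(
            f"retained span [{first_kept}, {last_kept}] invalid for length {L}"
        )
    retained = values[first_kept - 1 : last_kept]
    return retained, L - len(retained)


def mapped_read_fraction(n_mapped: int, n_total: int) -> float:
    """Percentage of reads mapping to the target, 100*n_mapped/n_total."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_mapped <= n_total):
        raise ValueError("need 0 <= n_mapped <= n_total")
    return 100.0 * n_mapped / n_total


def scale_to_reference_mean(
    profiles: list[CoverageProfile], reference_id: str
) -> list[CoverageProfile]:
    """Rescale every profile to the mean coverage of the reference individual.

    The reference profile is returned unchanged; every other profile is
    multiplied by mean(reference)/mean(self), so all post-scaling means agree.
    """
    by_id = {p.individual_id: p for p in profiles}
    if reference_id not in by_id:
        raise ValueError(f"reference individual {reference_id!r} not among profiles")
    spans = {p.retained_span for p in profiles}
    if len(spans) != 1:
        raise ValueError("profiles cover different retained spans")
    ref_mean = by_id[reference_id].mean
    out = []
    for p in profiles:
        if p.mean <= 0:
            raise ValueError(f"profile {p.individual_id!r} has non-positive mean")
        factor = 1.0 if p.individual_id == reference_id else ref_mean / p.mean
        out.append(
            CoverageProfile(p.individual_id, p.values * factor, p.retained_span)
        )
    return out


def window_profile(
    sequence: str, coverage: np.ndarray, window: int, step: int | None = None
) -> pd.DataFrame:
    """Windowed GC fraction and mean coverage over a region.

    Windows start at the region's first site and advance by ``step``
    (``step == window`` gives non-overlapping windows, the default); a
    trailing partial window is discarded. GC is (#G + #C)/(#non-N bases);
    an all-N window gets gc = NaN.

    Returns a DataFrame with columns window_start (0-based), gc, mean_cov.
    """
    coverage = np.asarray(coverage, dtype=float)
    if len(sequence) != len(coverage):
        raise ValueError("sequence and coverage lengths differ")
    if step is None:
        step = window
    if window > len(sequence):
        raise ValueError(f"window {window} exceeds region length {len(sequence)}")
    if step < 1:
        raise ValueError("step must be >= 1")
    seq = np.frombuffer(sequence.upper().encode(), dtype="S1")
    is_gc = (seq == b"G") | (seq == b"C")
    is_n = seq == b"N"
    starts = np.arange(0, len(sequence) - window + 1, step)
    rows = []
    for s in starts:
        sl = slice(s, s + window)
        denom = window - int(is_n[sl].sum())
        gc = float(is_gc[sl].sum()) / denom if denom else float("nan")
        rows.append((int(s), gc, float(coverage[sl].mean())))
    return pd.DataFrame(rows, columns=["window_start", "gc", "mean_cov"])


def n_windows(region_length: int, window: int, step: int) -> int:
    """Number of full windows of width ``window`` advancing by ``step``."""
    if window > region_length:
        raise ValueError("window exceeds region length")
    return (region_length - window) // step + 1
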