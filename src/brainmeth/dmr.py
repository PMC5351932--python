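"""Spatially-correlated region detection from per-probe p-values.

Pipeline (comb-p-style): estimate the distance-binned autocorrelation of
the probe-level association signal, pre-adjust each probe's p by a
Stouffer-Liptak combination over its +/- window neighbours, call maximal
runs of adjusted p below the seed threshold with inter-probe gaps at most
``max_gap`` bp and at least ``min_probes`` members, re-score each region
on the raw member p-values, and apply the Sidak correction
p_sidak = 1 - (1 - p)^(n_a / n_r) where n_a is the total number of
probes tested and n_r the region size.

The z-transform uses the one-sided convention z = Phi^-1(1 - p);
p = 1 is clamped just below 1 before transforming.  Correlations beyond
the largest ACF bin are 0; within a bin the bin estimate is used (a step
function, no interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AcfEstimate",
    "estimate_acf",
    "stouffer_liptak",
    "smooth_adjust",
    "find_regions",
    "score_region",
    "sidak_correct",
    "call_dmrs",
]

_P_CLAMP = 1.0 - 1e-16

DEFAULT_BINS: Tuple[Tuple[int, int], ...] = (
    (0, 50), (50, 100), (100, 150), (150, 200), (200, 250), (250, 300),
)


@dataclass
class AcfEstimate:
    """Distance-binned autocorrelation of the association z-scores.

    Bins are half-open (lo, hi]; correlations are truncated at 0 from
    below (negative spatial correlation carries no region signal).
    """

    bins: Tuple[Tuple[int, int], ...]
    correlations: np.ndarray

    def __post_init__(self) -> None:
        self.correlations = np.asarray(self.correlations, dtype=float)
        if len(self.bins) != len(self.correlations):
            raise ValueError("one correlation per bin required")
        if ((self.correlations < 0) | (self.correlations > 1)).any():
            raise ValueError("correlations must lie in [0, 1]")
        los = [b[0] for b in self.bins]
        if los != sorted(los):
            raise ValueError("bins must be ordered")

    @property
    def max_distance(self) -> int:
        return self.bins[-1][1]

    def rho(self, distances: np.ndarray) -> np.ndarray:
        """Step-function correlation at the given pairwise distances."""
        d = np.asarray(distances, dtype=float)
        out = np.zeros_like(d)
        for (lo, hi), r in zip(self.bins, self.correlations):
            out[(d > lo) & (d <= hi)] = r
        out[d <= 0] = 1.0
        return out


def _z_from_p(p: np.ndarray) -> np.ndarray:
    p = np.minimum(np.asarray(p, dtype=float), _P_CLAMP)
    return stats.norm.isf(p)


def estimate_acf(
    p_values: Sequence[float],
    chroms: Sequence[str],
    positions: Sequence[int],
    bins: Tuple[Tuple[int, int], ...] = DEFAULT_BINS,
    min_pairs: int = 50,
) -> AcfEstimate:
    """Pearson correlation of z = Phi^-1(1-p) over probe pairs per distance bin.

    Pairs are same-chromosome only; bins with fewer than ``min_pairs``
    usable pairs carry 0 with a warning.  Negative estimates are
    truncated to 0.
    """
    import warnings

    p = np.asarray(p_values, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        bad = p[(p <= 0) | (p >= 1)][:3]
        raise ValueError(f"p-values must lie strictly in (0, 1); got {bad}")
    z = _z_from_p(p)
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=int)
    max_d = bins[-1][1]
    pair_d: List[int] = []
    pair_a: List[float] = []
    pair_b: List[float] = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        j_start = 0
        for i in range(len(idx)):
            j = i + 1
            while j < len(idx) and pos[j] - pos[i] <= max_d:
                pair_d.append(pos[j] - pos[i])
                pair_a.append(z[idx[i]])
                pair_b.append(z[idx[j]])
                j += 1
    pair_d = np.asarray(pair_d)
    pair_a = np.asarray(pair_a)
    pair_b = np.asarray(pair_b)
    corr = np.zeros(len(bins))
    for bi, (lo, hi) in enumerate(bins):
        sel = (pair_d > lo) & (pair_d <= hi)
        if sel.sum() < min_pairs:
            warnings.warn(f"bin ({lo},{hi}]: only {int(sel.sum())} pairs; using 0")
            continue
        a, b = pair_a[sel], pair_b[sel]
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        # symmetrized pair correlation (each pair contributes both ways)
        aa = np.concatenate([a, b])
        bb = np.concatenate([b, a])
        corr[bi] = max(0.0, float(np.corrcoef(aa, bb)[0, 1]))
    return AcfEstimate(bins=bins, correlations=corr)


def stouffer_liptak(p_values: Sequence[float], sigma: np.ndarray) -> float:
    """Correlation-adjusted Stouffer-Liptak combination of p-values.

    z_i = Phi^-1(1 - p_i); C = sum(z) / sqrt(1' Sigma 1); combined
    p = 1 - Phi(C).  A single p is returned unchanged; a perfectly
    correlated set of equal p's is a no-op.
    """
    p = np.asarray(p_values, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (len(p), len(p)):
        raise ValueError("sigma shape must match the number of p-values")
    if not np.allclose(sigma, sigma.T):
        raise ValueError("sigma must be symmetric")
    if not np.allclose(np.diag(sigma), 1.0):
        raise ValueError("sigma must have unit diagonal")
    total = float(np.sum(sigma))
    if total <= 0:
        raise ValueError("1' Sigma 1 must be positive")
    z = _z_from_p(p)
    C = z.sum() / np.sqrt(total)
    return float(stats.norm.sf(C))


def _sigma_from_acf(positions: np.ndarray, acf: AcfEstimate) -> np.ndarray:
    d = np.abs(positions[:, None] - positions[None, :])
    sigma = acf.rho(d)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def smooth_adjust(
    p_values: Sequence[float],
    chroms: Sequence[str],
    positions: Sequence[int],
    acf: AcfEstimate,
    window: int = 300,
) -> np.ndarray:
    """Replace each probe's p by the Stouffer-Liptak combination of its
    +/- ``window`` bp same-chromosome neighbourhood (itself included)."""
    p = np.asarray(p_values, dtype=float)
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=int)
    out = np.empty_like(p)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        order = np.argsort(positions[idx], kind="stable")
        idx = idx[order]
        pos = positions[idx]
        lo = np.searchsorted(pos, pos - window, side="left")
        hi = np.searchsorted(pos, pos + window, side="right")
        for k in range(len(idx)):
            members = idx[lo[k] : hi[k]]
            if len(members) == 1:
                out[idx[k]] = p[idx[k]]
                continue
            sigma = _sigma_from_acf(positions[members], acf)
            out[idx[k]] = stouffer_liptak(p[members], sigma)
    return out


def find_regions(
    adjusted_p: Sequence[float],
    chroms: Sequence[str],
    positions: Sequence[int],
    probe_ids: Sequence[str],
    seed_p: float = 1.0e-03,
    max_gap: int = 300,
    min_probes: int = 2,
) -> List[dict]:
    """Maximal runs of sub-seed probes with consecutive gaps <= max_gap.

    Runs with fewer than ``min_probes`` members are discarded.  Positions
    must be sorted within each chromosome.
    """
    p = np.asarray(adjusted_p, dtype=float)
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=int)
    probe_ids = np.asarray(probe_ids)
    regions: List[dict] = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        if (np.diff(pos) < 0).any():
            raise ValueError(f"positions not sorted on {chrom}")
        current: List[int] = []
        for k in idx:
            if p[k] >= seed_p:
                continue
            if current and positions[k] - positions[current[-1]] > max_gap:
                if len(current) >= min_probes:
                    regions.append(_region_record(current, chroms, positions, probe_ids))
                current = []
            current.append(k)
        if len(current) >= min_probes:
            regions.append(_region_record(current, chroms, positions, probe_ids))
    return regions


def _region_record(members, chroms, positions, probe_ids) -> dict:
    return {
        "chrom": str(chroms[members[0]]),
        "start": int(positions[members[0]]),
        "end": int(positions[members[-1]]),
        "probe_ids": [str(probe_ids[m]) for m in members],
        "n_probes": len(members),
        "indices": list(members),
    }


def score_region(
    region: dict, raw_p: Sequence[float], positions: Sequence[int], acf: AcfEstimate
) -> float:
    """Stouffer-Liptak over the region's raw member p-values with the
    ACF-derived member correlation matrix."""
    members = np.asarray(region["indices"], dtype=int)
    p = np.asarray(raw_p, dtype=float)[members]
    if len(members) == 1:
        return float(p[0])
    pos = np.asarray(positions, dtype=int)[members]
    sigma = _sigma_from_acf(pos, acf)
    return stouffer_liptak(p, sigma)


def sidak_correct(p_combined: float, n_a: int, n_r: int) -> float:
    """Sidak correction of a region p for n_a/n_r effective tests.

    Computed in log space: p_sidak = 1 - exp((n_a/n_r) * log(1 - p)).
    """
    if not (0.0 <= p_combined <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if n_r < 1 or n_a < n_r:
        raise ValueError("need n_a >= n_r >= 1")
    if p_combined == 0.0:
        return 0.0
    ratio = n_a / n_r
    return float(-np.expm1(ratio * np.log1p(-p_combined)))


def call_dmrs(
    assoc: pd.DataFrame,
    manifest,
    seed_p: float = 1.0e-03,
    max_gap: int = 300,
    min_probes: int = 2,
    window: int = 300,
    smooth: bool = True,
    bins: Tuple[Tuple[int, int], ...] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Full region pipeline over an association table.

    ``assoc`` carries a ``p`` column indexed by probe id; ``manifest``
    supplies coordinates.  Returns one row per candidate region with
    p_combined and p_sidak, sorted by (chrom, start).
    """
    mani = manifest.sorted_by_position().table
    common = mani.index.intersection(assoc.index)
    mani = mani.loc[common]
    p = assoc.loc[common, "p"].to_numpy(dtype=float)
    ok = np.isfinite(p)
    mani, p = mani[ok], np.clip(p[ok], np.nextafter(0, 1), _P_CLAMP)
    chroms = mani["chrom"].to_numpy()
    positions = mani["pos"].to_numpy()
    probe_ids = mani.index.to_numpy()
    n_a = len(p)
    acf = estimate_acf(p, chroms, positions, bins=bins)
    seed_input = smooth_adjust(p, chroms, positions, acf, window) if smooth else p
    regions = find_regions(
        seed_input, chroms, positions, probe_ids, seed_p, max_gap, min_probes
    )
    rows = []
    for r in regions:
        p_comb = score_region(r, p, positions, acf)
        rows.append(
            {
                "chrom": r["chrom"],
                "start": r["start"],
                "end": r["end"],
                "n_probes": r["n_probes"],
                "probe_ids": ";".join(r["probe_ids"]),
                "p_combined": p_comb,
                "p_sidak": sidak_correct(p_comb, n_a, r["n_probes"]),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_probes", "probe_ids", "p_combined", "p_sidak"],
    )
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)
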