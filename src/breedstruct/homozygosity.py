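"""Runs of homozygosity (RoH) and length of homozygosity (LnH).

Two calling modes cover the two marker densities the analysis targets:

* ``snp`` mode (chip-like panels, ~14 kb spacing): a region is five or
  more consecutive homozygous calls; missing or heterozygous calls break
  the run. With 14 kb average spacing, 5 consecutive SNPs are expected to
  span at least ~70 kb.
* ``wgs`` mode (dense sequencing panels): maximal segments spanning at
  least ``min_length`` bp while containing at most ``max_het``
  heterozygous calls, found by a leftmost-maximal greedy scan; missing
  calls are non-informative (neither break a segment nor count).

Shared homozygosity over a cohort reduces the cohort to a single pseudo
genotype vector per marker (homozygous when every non-missing member is
homozygous and the missing fraction is below the tolerance) and reuses
the same segmentation, so a cohort of one reproduces the individual call
exactly. The module also provides the method-of-moments genotype
inbreeding coefficient and sliding-window variance-inflation-factor (VIF)
pruning of linked markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MarkerMap

__all__ = [
    "RoHParams",
    "HomozygosityProfile",
    "call_roh",
    "shared_homozygosity",
    "incremental_shared_curve",
    "genotype_inbreeding",
    "vif_prune",
    "segment_codes",
    "segment_codes_oracle",
]

HOM = 0
HET = 1
MISS = -1


@dataclass
class RoHParams:
    """Calling parameters.

    ``mode`` selects the rule set: "snp" uses the consecutive-marker count
    (``min_snps``); "wgs" uses the physical span (``min_length`` bp) with a
    heterozygote budget (``max_het``). ``shared_missing_fraction`` is the
    exclusive missingness tolerance for cohort calls (default < 0.20).
    ``min_span`` optionally adds a physical-span filter to snp mode
    (off by default). ``same_allele`` requires cohort homozygosity to be
    for the same allele rather than any homozygous state.
    """

    mode: str = "snp"
    min_snps: int = 5
    min_length: int = 70_000
    max_het: int = 0
    shared_missing_fraction: float = 0.20
    min_span: int | None = None
    same_allele: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("snp", "wgs"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.min_snps < 2:
            raise ValueError("min_snps must be >= 2")
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if self.max_het < 0:
            raise ValueError("max_het must be >= 0")


@dataclass
class HomozygosityProfile:
    """RoH interval set for one individual or a shared cohort."""

    intervals: pd.DataFrame   # chrom, start, end, n_markers (bp, 1-based inclusive ends)
    cohort: list[str] = field(default_factory=list)

    @property
    def roh(self) -> int:
        return len(self.intervals)

    @property
    def lnh(self) -> int:
        if not len(self.intervals):
            return 0
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def to_bed(self, path, cohort_size: int | None = None) -> None:
        out = self.intervals.copy()
        out["cohort_size"] = cohort_size or len(self.cohort) or 1
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# segmentation cores (these are what the exhaustive oracle checks)
# ---------------------------------------------------------------------------

def segment_codes(
    codes: np.ndarray, positions: np.ndarray, params: RoHParams
) -> list[tuple[int, int, int]]:
    """Segment one chromosome; returns (first_idx, last_idx, n_markers).

    ``codes``: -1 missing, 0/2 homozygous, 1 heterozygous-or-broken.
    """
    codes = np.asarray(codes)
    positions = np.asarray(positions)
    if params.mode == "snp":
        return _segment_snp(codes, positions, params)
    return _segment_wgs(codes, positions, params)


def _segment_snp(codes, positions, params) -> list[tuple[int, int, int]]:
    hom = (codes == 0) | (codes == 2)
    out = []
    i = 0
    m = len(codes)
    while i < m:
        if not hom[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and hom[j + 1]:
            j += 1
        n_markers = j - i + 1
        if n_markers >= params.min_snps:
            span = int(positions[j] - positions[i])
            if params.min_span is None or span >= params.min_span:
                out.append((i, j, n_markers))
        i = j + 1
    return out


def _segment_wgs(codes, positions, params) -> list[tuple[int, int, int]]:
    # informative markers only; missing neither counts nor breaks
    info = np.flatnonzero(codes != MISS)
    c = codes[info]
    p = positions[info]
    het = (c == 1).astype(np.int64)
    chet = np.concatenate(([0], np.cumsum(het)))
    m = len(info)
    out = []
    i = 0
    while i < m:
        # longest window starting at i with <= max_het heterozygous calls
        lo, hi = i, m - 1
        # binary search over j for het count
        j = int(
            np.searchsorted(chet, chet[i] + params.max_het, side="right") - 1
        ) - 1
        j = min(max(j, i), m - 1)
        span = int(p[j] - p[i])
        if span >= params.min_length:
            out.append((int(info[i]), int(info[j]),
                        j - i + 1))
            i = j + 1
        else:
            i += 1
    return out


def segment_codes_oracle(
    codes: np.ndarray, positions: np.ndarray, params: RoHParams
) -> list[tuple[int, int, int]]:
    """Brute-force reference segmentation (quadratic enumeration).

    Enumerates every candidate interval satisfying the mode's rule, then
    repeatedly selects the leftmost-starting (longest on ties) candidate
    and discards overlaps. Used only as a test oracle.
    """
    codes = np.asarray(codes)
    positions = np.asarray(positions)
    m = len(codes)
    candidates = []
    if params.mode == "snp":
        hom = (codes == 0) | (codes == 2)
        for i in range(m):
            for j in range(i, m):
                if not all(hom[i:j + 1]):
                    continue
                if (i > 0 and hom[i - 1]) or (j < m - 1 and hom[j + 1]):
                    continue  # not maximal
                if j - i + 1 < params.min_snps:
                    continue
                if (
                    params.min_span is not None
                    and positions[j] - positions[i] < params.min_span
                ):
                    continue
                candidates.append((i, j))
    else:
        info = [k for k in range(m) if codes[k] != MISS]
        for a in range(len(info)):
            for b in range(a, len(info)):
                i, j = info[a], info[b]
                window = [codes[k] for k in info[a:b + 1]]
                if sum(1 for c in window if c == 1) > params.max_het:
                    continue
                if positions[j] - positions[i] < params.min_length:
                    continue
                candidates.append((i, j))
    chosen: list[tuple[int, int, int]] = []
    while candidates:
        start = min(i for i, _ in candidates)
        pool = [(i, j) for i, j in candidates if i == start]
        i, j = max(pool, key=lambda ij: ij[1])
        n_markers = sum(1 for k in range(i, j + 1) if codes[k] != MISS)
        chosen.append((i, j, n_markers))
        candidates = [(a, b) for a, b in candidates if a > j]
    return chosen


# ---------------------------------------------------------------------------
# public calling API
# ---------------------------------------------------------------------------

def _profile_from_codes(
    g: GenotypeMatrix, codes: np.ndarray, params: RoHParams, cohort: list[str]
) -> HomozygosityProfile:
    rows = []
    mapdf = g.markers.df
    pos_all = mapdf["pos"].to_numpy()
    for chrom in g.markers.chroms:
        sl = g.markers.chrom_slice(chrom)
        segs = segment_codes(codes[sl], pos_all[sl], params)
        for i, j, n_markers in segs:
            rows.append(
                (chrom, int(pos_all[sl][i]), int(pos_all[sl][j]), n_markers)
            )
    intervals = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_markers"]
    )
    return HomozygosityProfile(intervals=intervals, cohort=cohort)


def call_roh(
    g: GenotypeMatrix, individual: str, params: RoHParams | None = None
) -> HomozygosityProfile:
    """RoH profile of a single individual."""
    params = params or RoHParams()
    codes = g.row(individual)
    return _profile_from_codes(g, codes, params, [str(individual)])


def _cohort_codes(
    g: GenotypeMatrix, cohort: Sequence[str], params: RoHParams
) -> np.ndarray:
    idx = [g.sample_index(i) for i in cohort]
    sub = g.calls[idx]
    n = len(idx)
    n_missing = (sub == MISS).sum(axis=0)
    n_het = (sub == 1).sum(axis=0)
    if params.same_allele:
        has0 = ((sub == 0).sum(axis=0) > 0)
        has2 = ((sub == 2).sum(axis=0) > 0)
        conflict = has0 & has2
    else:
        conflict = np.zeros(sub.shape[1], dtype=bool)
    miss_ok = n_missing / n < params.shared_missing_fraction
    hom_ok = (n_het == 0) & ~conflict
    codes = np.where(
        hom_ok & miss_ok,
        HOM,
        np.where(n_het > 0, HET, np.where(~miss_ok & hom_ok, MISS, HET)),
    ).astype(np.int8)
    return codes


def shared_homozygosity(
    g: GenotypeMatrix, cohort: Sequence[str], params: RoHParams | None = None
) -> HomozygosityProfile:
    """RoH intervals homozygous across a whole cohort.

    A marker is cohort-homozygous when fewer than
    ``shared_missing_fraction`` of members are missing and every
    non-missing call is homozygous. A cohort of one reduces exactly to
    :func:`call_roh`.
    """
    params = params or RoHParams()
    cohort = [str(i) for i in cohort]
    if not cohort:
        raise ValueError("empty cohort")
    codes = _cohort_codes(g, cohort, params)
    return _profile_from_codes(g, codes, params, cohort)


def incremental_shared_curve(
    g: GenotypeMatrix,
    ids: Sequence[str],
    params: RoHParams | None = None,
    order_seed: int | None = None,
) -> pd.DataFrame:
    """Shared RoH/LnH as same-breed individuals are added one at a time.

    ``ids`` are permuted under ``order_seed``; row t holds the shared
    profile of the first t individuals. Returns columns (t, roh, lnh).
    """
    params = params or RoHParams()
    ids = [str(i) for i in ids]
    if len(ids) < 2:
        raise ValueError("need at least 2 individuals for a shared curve")
    rng = np.random.default_rng(order_seed)
    order = [ids[k] for k in rng.permutation(len(ids))]
    rows = []
    for t in range(1, len(order) + 1):
        prof = shared_homozygosity(g, order[:t], params)
        rows.append((t, prof.roh, prof.lnh))
    return pd.DataFrame(rows, columns=["t", "roh", "lnh"])


# ---------------------------------------------------------------------------
# genotype-based inbreeding
# ---------------------------------------------------------------------------

def genotype_inbreeding(g: GenotypeMatrix) -> pd.Series:
    """Method-of-moments F per individual from observed vs expected
    homozygosity.

    F = (O_hom − E_hom)/(m_used − E_hom), with the expected homozygous
    count using the unbiased small-sample correction
    E_hom = Σ_j [1 − 2 p_j (1 − p_j) n_j/(n_j − 1)] over the individual's
    non-missing markers; p_j is the alternate-allele frequency and n_j the
    non-missing allele count in the input matrix. Individuals whose
    denominator vanishes (e.g. only monomorphic markers) get NaN.
    """
    if len(g.samples) < 2:
        raise ValueError("need >= 2 individuals to estimate frequencies")
    calls = g.calls
    obs = calls >= 0
    n_alleles = 2 * obs.sum(axis=0)
    alt = np.where(obs, calls, 0).sum(axis=0)
    usable = n_alleles >= 4  # frequency needs n_j >= 2 genotypes
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(usable, alt / np.maximum(n_alleles, 1), np.nan)
        e_het = 2 * p * (1 - p) * n_alleles / np.maximum(n_alleles - 1, 1)
    out = {}
    for i, ind in enumerate(g.samples):
        use = obs[i] & usable
        m_used = int(use.sum())
        o_hom = int(((calls[i] == 0) | (calls[i] == 2))[use].sum())
        e_hom = float((1.0 - e_het[use]).sum())
        denom = m_used - e_hom
        out[ind] = (o_hom - e_hom) / denom if abs(denom) > 1e-12 else np.nan
    return pd.Series(out, name="F_genotype")


# ---------------------------------------------------------------------------
# VIF pruning
# ---------------------------------------------------------------------------

def vif_prune(
    g: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    vif_threshold: float = 2.0,
) -> list[str]:
    """Sliding-window variance-inflation-factor pruning of linked markers.

    Within each window the marker with the largest VIF = 1/(1 − R²)
    against the other retained window markers is removed until all VIFs
    are at or below the threshold; removal in any window is global.
    VIF 2 corresponds to R² = 0.5. Missing calls are mean-imputed per
    marker before the window correlation matrix is formed. Returns the
    ids of retained markers in map order.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    mapdf = g.markers.df
    removed = np.zeros(len(mapdf), dtype=bool)
    x = g.calls.astype(float)
    x[g.calls < 0] = np.nan
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(x), col_mean[None, :], x)
    sd = inds.std(axis=0)
    for chrom in g.markers.chroms:
        sl = g.markers.chrom_slice(chrom)
        start = sl.start
        stop = sl.stop
        s = start
        while s < stop:
            win = np.arange(s, min(s + window_snps, stop))
            win = win[~removed[win] & (sd[win] > 0)]
            _prune_window(inds, win, vif_threshold, removed)
            if s + window_snps >= stop:
                break
            s += step_snps
    keep = ~removed
    return list(mapdf["id"][keep])


def _prune_window(inds, win, threshold, removed) -> None:
    while len(win) >= 2:
        sub = inds[:, win]
        corr = np.corrcoef(sub, rowvar=False)
        corr = np.atleast_2d(corr)
        try:
            inv = np.linalg.inv(corr)
            vifs = np.diag(inv).copy()
        except np.linalg.LinAlgError:
            vifs = np.full(len(win), np.nan)
        # a VIF is >= 1 by construction; anything else signals a singular
        # window (perfectly collinear markers) and is treated as infinite
        bad = ~np.isfinite(vifs) | (vifs < 1.0 - 1e-6) | (vifs > 1e12)
        if bad.any():
            vifs = np.where(bad, np.inf, vifs)
            for a in np.flatnonzero(np.isinf(vifs)):
                r = np.delete(corr[a], a)
                if not np.any(np.abs(r) > 1 - 1e-9):
                    vifs[a] = 1.0  # not actually collinear; be conservative
        worst = float(np.nanmax(vifs))
        if not (worst > threshold):
            return
        ties = np.flatnonzero(
            np.isinf(vifs) if np.isinf(worst) else vifs >= worst - 1e-9
        )
        drop = int(ties[-1])  # later marker removed on ties
        removed[win[drop]] = True
        win = np.delete(win, drop)
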