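"""Per-window population-genetic statistics.

Implements the three per-window quantities of a sweep scan — nucleotide
diversity (pi), Tajima's D, and the Weir–Cockerham (1984) Fst estimator for
two populations — together with site-frequency-spectrum containers and the
hypergeometric projection used to change haploid sample size.

Conventions
-----------
* Per-site heterozygosity for a biallelic site with derived (or minor) count
  ``j`` of ``n`` haploid samples is ``2 j (n - j) / (n (n - 1))`` — the
  unbiased pairwise-difference estimator.  Windowed pi divides the sum of
  site values by the window length in bp.
* Windowed Fst is the ratio of summed variance components ``sum(a) /
  sum(a + b + c)`` (weighted estimator), not a mean of per-site ratios.
* Windows with no segregating site report Tajima's D as missing (NaN), never
  as zero, so genome-wide quantiles are not diluted.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import hypergeom

from .core import GenotypeMatrix, MISSING, SampleGroups


@dataclass
class SiteFrequencySpectrum:
    """Counts or probabilities over derived-allele classes 0..n.

    ``values[j]`` is the weight of class ``j``.  ``includes_monomorphic``
    records whether the 0 and n classes are meaningful (they are kept in the
    array either way, possibly as zeros).
    """

    n: int
    values: np.ndarray
    includes_monomorphic: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n + 1,):
            raise ValueError(f"SFS for n={self.n} needs {self.n + 1} classes")
        if np.any(self.values < 0):
            raise ValueError("negative SFS class weight")

    def normalized(self) -> "SiteFrequencySpectrum":
        total = self.values.sum()
        if total == 0:
            raise ValueError("cannot normalize an empty SFS")
        return SiteFrequencySpectrum(self.n, self.values / total, self.includes_monomorphic)

    def polymorphic(self) -> "SiteFrequencySpectrum":
        """Zero the monomorphic classes and renormalize over 1..n-1."""
        vals = self.values.copy()
        vals[0] = vals[self.n] = 0.0
        out = SiteFrequencySpectrum(self.n, vals, includes_monomorphic=False)
        return out.normalized()


def project_sfs(sfs: SiteFrequencySpectrum, m: int) -> SiteFrequencySpectrum:
    """Down-project an SFS from haploid size n to m by hypergeometric expectation."""
    if m < 1:
        raise ValueError("target size must be >= 1")
    if m > sfs.n:
        raise ValueError(f"cannot project n={sfs.n} up to m={m}")
    if m == sfs.n:
        return SiteFrequencySpectrum(sfs.n, sfs.values.copy(), sfs.includes_monomorphic)
    j = np.arange(sfs.n + 1)
    k = np.arange(m + 1)
    # P[k_row, j_col] = P(Hypergeom(N=n, K=j, draws=m) = k)
    pmat = hypergeom.pmf(k[:, None], sfs.n, j[None, :], m)
    return SiteFrequencySpectrum(m, pmat @ sfs.values, includes_monomorphic=True)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------


def site_pi(j, n):
    """Per-site heterozygosity 2j(n-j)/(n(n-1)); vectorized over j, n."""
    j = np.asarray(j, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 2):
        raise ValueError("site_pi requires n >= 2")
    if np.any((j < 0) | (j > n)):
        raise ValueError("derived count j must satisfy 0 <= j <= n")
    out = 2.0 * j * (n - j) / (n * (n - 1.0))
    return float(out) if out.ndim == 0 else out


def _alt_counts(gm: GenotypeMatrix, sample_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt allele count, haploid n) over the given samples."""
    calls = gm.calls[:, sample_idx]
    called = calls != MISSING
    n = 2 * called.sum(axis=1)
    j = np.where(called, calls, 0).sum(axis=1)
    return j.astype(np.int64), n.astype(np.int64)


def diversity_profile(
    gm: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    window: int = 100_000,
    step: int = 500,
    samples: Optional[Sequence[str]] = None,
    chrom_length: Optional[int] = None,
) -> tuple[pd.DataFrame, float]:
    """Sliding-window pi across a region, plus the single-window region mean.

    Windows of ``window`` bp are anchored at ``start`` every ``step`` bp; the
    last window ends at or before ``end``.  Coordinates are 0-based half-open.
    """
    if end <= start:
        raise ValueError("empty region")
    if window > end - start:
        raise ValueError("window longer than region")
    if step < 1:
        raise ValueError("step must be >= 1")
    if start < 0 or (chrom_length is not None and end > chrom_length):
        raise ValueError(f"region [{start}, {end}) outside chromosome bounds")
    idx = gm.site_index(chrom)
    sample_idx = (
        gm.sample_indices(samples) if samples is not None else np.arange(gm.n_samples)
    )
    sub = gm.calls[np.ix_(idx, sample_idx)]
    pos0 = np.array([gm.sites[i].pos - 1 for i in idx], dtype=np.int64)
    in_region = (pos0 >= start) & (pos0 < end)
    pos0 = pos0[in_region]
    sub = sub[in_region]
    called = sub != MISSING
    n = 2 * called.sum(axis=1)
    j = np.where(called, sub, 0).sum(axis=1)
    ok = n >= 2
    pi_vals = np.zeros(len(pos0))
    pi_vals[ok] = 2.0 * j[ok] * (n[ok] - j[ok]) / (n[ok] * (n[ok] - 1.0))

    csum = np.concatenate([[0.0], np.cumsum(pi_vals)])
    ccount = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
    n_windows = (end - start - window) // step + 1
    starts = start + step * np.arange(n_windows)
    lo = np.searchsorted(pos0, starts)
    hi = np.searchsorted(pos0, starts + window)
    values = (csum[hi] - csum[lo]) / window
    n_sites = ccount[hi] - ccount[lo]
    df = pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + window,
        "n_sites": n_sites, "value": values,
    })
    mean_pi = float(pi_vals.sum() / (end - start))
    return df, mean_pi


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


def tajima_constants(n: int) -> dict:
    """The standard normalization constants of Tajima's D for haploid size n."""
    if n < 3:
        raise ValueError("Tajima's D variance requires n >= 3")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(js: Sequence[int], ns: Sequence[int]) -> float:
    """Tajima's D for the segregating sites of one window.

    All sites must share one haploid size ``n``; windows with sites at mixed
    ``n`` (missing data) are first down-projected to the window minimum via
    hypergeometric expectation: per-site pi is invariant under down-projection,
    while each site contributes its probability of remaining polymorphic to an
    expected segregating-site count.  Returns NaN when no site segregates.
    """
    js = np.asarray(js, dtype=np.int64)
    ns = np.asarray(ns, dtype=np.int64)
    if js.shape != ns.shape:
        raise ValueError("js and ns must align")
    poly = (js > 0) & (js < ns)
    js, ns = js[poly], ns[poly]
    if len(js) == 0:
        return float("nan")
    n = int(ns.min())
    if n < 3:
        raise ValueError("Tajima's D requires n >= 3 at every used site")
    pi_sum = float(np.sum(2.0 * js * (ns - js) / (ns * (ns - 1.0))))
    if np.all(ns == n):
        s = float(len(js))
    else:
        # expected number of sites still polymorphic after projection to n
        logc = lambda a, b: gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
        p_lost0 = np.exp(logc(ns - js, n) - logc(ns, n))          # all-ancestral draw
        p_lostn = np.where(js >= n, np.exp(logc(js, n) - logc(ns, n)), 0.0)
        s = float(np.sum(1.0 - p_lost0 - p_lostn))
    k = tajima_constants(n)
    var = k["e1"] * s + k["e2"] * s * (s - 1.0)
    if var <= 0:
        return float("nan")
    return (pi_sum - s / k["a1"]) / np.sqrt(var)


def windowed_tajimas_d(
    gm: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    bin_size: int = 50_000,
    samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Tajima's D in consecutive ``bin_size`` windows over [start, end)."""
    idx = gm.site_index(chrom)
    sample_idx = (
        gm.sample_indices(samples) if samples is not None else np.arange(gm.n_samples)
    )
    pos0 = np.array([gm.sites[i].pos - 1 for i in idx], dtype=np.int64)
    j, n = _alt_counts(gm.subset_sites(idx), sample_idx)
    rows = []
    for ws in range(start, end, bin_size):
        we = min(ws + bin_size, end)
        sel = (pos0 >= ws) & (pos0 < we)
        poly = sel & (j > 0) & (j < n)
        value = tajimas_d(j[sel], n[sel]) if sel.any() else float("nan")
        rows.append((chrom, ws, we, int(poly.sum()), value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "value"])


# ---------------------------------------------------------------------------
# Weir–Cockerham Fst
# ---------------------------------------------------------------------------


def wc_fst_components(n1, n2, p1, p2, h1, h2):
    """Per-site Weir–Cockerham (1984) variance components (a, b, c) for r=2.

    ``n1, n2`` are diploid sample counts; ``p1, p2`` alternate-allele
    frequencies; ``h1, h2`` observed heterozygote frequencies.
    """
    n1 = np.asarray(n1, float); n2 = np.asarray(n2, float)
    p1 = np.asarray(p1, float); p2 = np.asarray(p2, float)
    h1 = np.asarray(h1, float); h2 = np.asarray(h2, float)
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("each population needs >= 1 genotyped diploid per site")
    r = 2.0
    nbar = (n1 + n2) / 2.0
    nc = (2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
    c = hbar / 2.0
    return a, b, c


def wc_fst_window(n1, n2, p1, p2, h1, h2) -> float:
    """Windowed Fst as ratio of sums over per-site components; NaN if denominator 0."""
    a, b, c = wc_fst_components(n1, n2, p1, p2, h1, h2)
    denom = np.sum(a + b + c)
    if denom == 0 or not np.isfinite(denom):
        return float("nan")
    return float(np.sum(a) / denom)


def _pop_site_stats(calls: np.ndarray):
    """(n diploids, alt freq, het freq) per site for one population's calls."""
    called = calls != MISSING
    n = called.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(called, calls, 0).sum(axis=1) / (2.0 * n)
        h = (calls == 1).sum(axis=1) / n
    return n, p, h


def windowed_fst(
    gm: GenotypeMatrix,
    groups: SampleGroups,
    pop1_labels: Sequence[str],
    pop2_labels: Sequence[str],
    chrom: str,
    start: int,
    end: int,
    bin_size: int = 50_000,
) -> pd.DataFrame:
    """Weir–Cockerham Fst in consecutive bins between two label-defined populations."""
    idx = gm.site_index(chrom)
    i1 = gm.sample_indices(groups.members(*pop1_labels))
    i2 = gm.sample_indices(groups.members(*pop2_labels))
    if len(i1) == 0 or len(i2) == 0:
        raise ValueError("both populations must be non-empty")
    pos0 = np.array([gm.sites[i].pos - 1 for i in idx], dtype=np.int64)
    c1 = gm.calls[np.ix_(idx, i1)]
    c2 = gm.calls[np.ix_(idx, i2)]
    n1, p1, h1 = _pop_site_stats(c1)
    n2, p2, h2 = _pop_site_stats(c2)
    usable = (n1 >= 1) & (n2 >= 1)
    rows = []
    for ws in range(start, end, bin_size):
        we = min(ws + bin_size, end)
        sel = usable & (pos0 >= ws) & (pos0 < we)
        if sel.any():
            value = wc_fst_window(n1[sel], n2[sel], p1[sel], p2[sel], h1[sel], h2[sel])
        else:
            value = float("nan")
        rows.append((chrom, ws, we, int(sel.sum()), value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "value"])


def write_window_tsv(df: pd.DataFrame, path) -> None:
    """One row per window: chrom, start(0-based), end, n_sites, value."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
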