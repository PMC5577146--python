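"""Composite-likelihood-ratio sweep scan and three-statistic evidence combination.

The sweep model is the star-like hitchhiking approximation: at distance ``d``
from the selected site, each of the ``n`` sampled lineages independently
escapes the sweep via recombination with probability ``p_e = 1 - exp(-alpha
d)``; all non-escaped lineages coalesce instantly on the beneficial
haplotype.  Conditional on ``e`` escapees, the sample's ancestry just before
the sweep consists of ``m = e + 1`` exchangeable lineages — the escapees plus
one lineage carrying the swept class of size ``n - e`` — whose derived-allele
configuration follows the genome-wide background SFS projected down to ``m``.

The scan statistic at a test position is twice the log ratio of the maximized
composite likelihood under this model (over a grid of ``alpha``) to the
likelihood under the background spectrum alone; the background is the
``alpha -> infinity`` limit, so the ratio is clipped at zero.

Candidate regions combine three signals in 50 kb bins: high CLR, high
between-population Fst, and low Tajima's D, each thresholded at its empirical
genome-wide top-5% quantile, intersected.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .annotation import GenomeAnnotation
from .core import PolarizedSite
from .popgen import SiteFrequencySpectrum, project_sfs

logger = logging.getLogger(__name__)

DEFAULT_RADIUS = 100_000
DEFAULT_GRID_STEP = 10_000
DEFAULT_BIN = 50_000
DEFAULT_SMOOTHING = 0.5


@dataclass(frozen=True)
class SweepModelParams:
    """Sweep intensity ``alpha`` (per bp) and distance ``d`` (bp) to the test site."""

    alpha: float
    d: float

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.d < 0:
            raise ValueError("distance must be >= 0")

    @property
    def p_escape(self) -> float:
        return float(-np.expm1(-self.alpha * self.d))


def background_sfs(
    polarized: Sequence[PolarizedSite],
    n: Optional[int] = None,
    smoothing: float = DEFAULT_SMOOTHING,
) -> SiteFrequencySpectrum:
    """Empirical background SFS over polymorphic classes 1..n-1.

    Sites are taken at their polarized (n_i, b_i); sites with ``n_i > n`` are
    down-projected to the common size ``n`` (default: the minimum n over
    usable sites) by hypergeometric expectation, and mass that projects onto
    the monomorphic classes is dropped.  Empty polymorphic classes receive a
    ``smoothing`` pseudo-count before normalization so the scan never takes
    ``log 0``.
    """
    usable = [p for p in polarized if p.polarized and p.b is not None
              and 0 < p.b < p.n]
    if not usable:
        raise ValueError("no polarized polymorphic sites to build a background SFS")
    if n is None:
        n = min(p.n for p in usable)
    counts = np.zeros(n + 1)
    from scipy.stats import hypergeom
    for p in usable:
        if p.n < n:
            continue  # cannot up-project
        if p.n == n:
            counts[p.b] += 1.0
        else:
            k = np.arange(n + 1)
            counts += hypergeom.pmf(k, p.n, p.b, n)
    counts[0] = counts[n] = 0.0
    empty = counts[1:n] == 0
    counts[1:n][empty] += smoothing
    sfs = SiteFrequencySpectrum(n, counts, includes_monomorphic=False)
    return sfs.normalized()


class SweepModel:
    """Precomputed star-like sweep site-probability machinery for one background.

    The conditional configuration matrix ``M[e, b] = P(b | e escapees)`` is
    built once; per-(alpha, distance) site probabilities are then a binomial
    mixture ``P(b) = sum_e Binom(e | n, p_e) M[e, b]``.
    """

    def __init__(self, background: SiteFrequencySpectrum):
        bg = background.polymorphic()
        self.n = bg.n
        self.q = bg.values  # zero mass on classes 0 and n
        n = self.n
        self.projections = {m: project_sfs(bg, m).values for m in range(1, n + 1)}
        M = np.zeros((n + 1, n + 1))
        for e in range(n):
            m = e + 1
            qm = self.projections[m]
            for j in range(m + 1):
                w = qm[j]
                if w == 0.0:
                    continue
                share = j / m  # probability the swept ancestor carries the derived allele
                M[e, j] += w * (1.0 - share)
                if j >= 1:
                    M[e, (n - e) + (j - 1)] += w * share
        M[n, :] = self.q  # all lineages escaped: plain background
        self._M = M
        with np.errstate(divide="ignore"):
            self._logq = np.log(self.q)

    def site_prob_matrix(self, alpha: float, d: np.ndarray) -> np.ndarray:
        """P(b) for each distance; shape (len(d), n+1)."""
        if alpha <= 0:
            raise ValueError("alpha must be > 0")
        d = np.asarray(d, dtype=float)
        pe = -np.expm1(-alpha * d)
        e = np.arange(self.n + 1)
        B = binom.pmf(e[None, :], self.n, pe[:, None])
        return B @ self._M

    def site_probability(self, b: int, d: float, alpha: float) -> float:
        if not 0 <= b <= self.n:
            raise ValueError(f"b must lie in 0..{self.n}")
        return float(self.site_prob_matrix(alpha, np.array([d]))[0, b])

    def log_background(self, b: np.ndarray) -> np.ndarray:
        return self._logq[np.asarray(b, dtype=int)]


def sweep_site_probability(
    b: int, n: int, d: float, alpha: float, background: SiteFrequencySpectrum
) -> float:
    """P(derived count b | sweep at distance d with intensity alpha).

    Convenience wrapper over :class:`SweepModel`; for repeated evaluation
    build the model once.
    """
    if background.n != n:
        raise ValueError(f"background SFS is at n={background.n}, data at n={n}")
    return SweepModel(background).site_probability(b, d, alpha)


def default_alpha_grid(
    radius: int = DEFAULT_RADIUS,
    n_points: int = 15,
    pe_range: tuple[float, float] = (0.001, 0.999),
) -> np.ndarray:
    """Log-spaced alpha grid spanning escape probabilities ``pe_range`` at radius/2."""
    d_mid = radius / 2.0
    lo = -np.log1p(-pe_range[0]) / d_mid
    hi = -np.log1p(-pe_range[1]) / d_mid
    return np.geomspace(lo, hi, n_points)


def clr_scan(
    polarized: Sequence[PolarizedSite],
    grid_positions: Sequence[int],
    alpha_grid: Optional[np.ndarray] = None,
    radius: int = DEFAULT_RADIUS,
    background: Optional[SiteFrequencySpectrum] = None,
    n: Optional[int] = None,
) -> pd.DataFrame:
    """Scan test positions for sweep signal against the genome-wide background.

    Only polarized polymorphic sites at the common haploid size enter the
    composite likelihood (monomorphic classes have no background mass).
    Returns one row per test position: position, clr, alpha_hat, n_sites;
    positions with no site within ``radius`` report NaN.
    """
    usable = [p for p in polarized
              if p.polarized and p.b is not None and 0 < p.b < p.n]
    if not usable:
        raise ValueError("no polarized polymorphic sites to scan")
    if n is None:
        n = max(p.n for p in usable)
    usable = [p for p in usable if p.n == n]
    if not usable:
        raise ValueError(f"no usable sites at haploid size n={n}")
    if background is None:
        background = background_sfs(usable, n=n)
    model = SweepModel(background)
    pos = np.array([p.site.pos for p in usable], dtype=np.int64)
    b = np.array([p.b for p in usable], dtype=np.int64)
    order = np.argsort(pos)
    pos, b = pos[order], b[order]
    if alpha_grid is None:
        alpha_grid = default_alpha_grid(radius)

    rows = []
    for x in grid_positions:
        lo = np.searchsorted(pos, x - radius)
        hi = np.searchsorted(pos, x + radius, side="right")
        if hi == lo:
            rows.append((int(x), float("nan"), float("nan"), 0))
            continue
        d = np.abs(pos[lo:hi] - x).astype(float)
        bb = b[lo:hi]
        bg_ll = float(model.log_background(bb).sum())
        best_ll, best_alpha = -np.inf, float("nan")
        for alpha in alpha_grid:
            P = model.site_prob_matrix(alpha, d)
            # condition on polymorphism: the data contain no monomorphic sites,
            # so the sweep model must be renormalized over classes 1..n-1
            poly_mass = 1.0 - P[:, 0] - P[:, model.n]
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = float(np.sum(np.log(P[np.arange(len(bb)), bb])
                                  - np.log(poly_mass)))
            if not np.isfinite(ll):
                ll = -np.inf
            if ll > best_ll:
                best_ll, best_alpha = ll, float(alpha)
        clr = max(0.0, 2.0 * (best_ll - bg_ll))
        rows.append((int(x), clr, best_alpha, int(hi - lo)))
    return pd.DataFrame(rows, columns=["position", "clr", "alpha_hat", "n_sites"])


# ---------------------------------------------------------------------------
# evidence combination
# ---------------------------------------------------------------------------


@dataclass
class CandidateBin:
    """A 50 kb bin with its three statistics and per-statistic top-5% flags."""

    chrom: str
    start: int
    end: int
    clr_max: float
    fst: float
    tajimas_d: float
    pass_clr: bool
    pass_fst: bool
    pass_tajd: bool
    genes: list[str]

    @property
    def candidate(self) -> bool:
        return self.pass_clr and self.pass_fst and self.pass_tajd


def _top_threshold(values: np.ndarray, q: float, low: bool) -> float:
    """Order-statistic quantile: the k-th most extreme value, k = max(1, floor(q N)).

    Ties at the threshold are admitted by the >= / <= comparisons downstream,
    so with distinct values exactly k bins pass.
    """
    k = max(1, int(np.floor(q * len(values))))
    vals = np.sort(values)
    return float(vals[k - 1] if low else vals[-k])


def combine_evidence(
    clr_track: pd.DataFrame,
    fst_windows: pd.DataFrame,
    tajd_windows: pd.DataFrame,
    bin_size: int = DEFAULT_BIN,
    q: float = 0.05,
    mode: str = "intersection",
    chrom: Optional[str] = None,
) -> tuple[list[CandidateBin], dict]:
    """Intersect per-bin top-5% CLR, top-5% Fst and bottom-5% Tajima's D.

    ``fst_windows``/``tajd_windows`` must already be binned at ``bin_size``
    (columns chrom/start/end/value); the CLR track (columns position/clr) is
    reduced to a per-bin maximum.  Bins with any undefined statistic are
    excluded from both quantile estimation and candidacy.
    """
    if mode not in ("intersection", "union"):
        raise ValueError("mode must be 'intersection' or 'union'")
    fst = fst_windows.set_index(["chrom", "start"])
    tajd = tajd_windows.set_index(["chrom", "start"])
    clr_pos = clr_track["position"].to_numpy()
    clr_val = clr_track["clr"].to_numpy(dtype=float)
    if chrom is None:
        chroms = tajd_windows["chrom"].unique()
        if len(chroms) != 1 and "chrom" not in clr_track.columns:
            raise ValueError("multi-chromosome input needs a chrom column in the CLR track")
    records = []
    for (c, ws), row in tajd.iterrows():
        we = int(row["end"])
        if ("chrom" in clr_track.columns) and len(clr_track):
            sel = (clr_track["chrom"].to_numpy() == c) & (clr_pos >= ws) & (clr_pos < we)
        else:
            sel = (clr_pos >= ws) & (clr_pos < we)
        vals = clr_val[sel]
        vals = vals[np.isfinite(vals)]
        clr_max = float(vals.max()) if len(vals) else float("nan")
        try:
            fst_v = float(fst.loc[(c, ws), "value"])
        except KeyError:
            fst_v = float("nan")
        records.append((c, int(ws), we, clr_max, fst_v, float(row["value"])))
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "clr_max", "fst", "tajd"])
    defined = df[["clr_max", "fst", "tajd"]].notna().all(axis=1).to_numpy()
    n_excluded = int((~defined).sum())
    if n_excluded:
        logger.info("combine_evidence: %d bins with undefined statistics excluded", n_excluded)
    if defined.sum() == 0:
        return [], {"n_bins": len(df), "n_defined": 0}
    sub = df[defined]
    thresholds = {
        "clr": _top_threshold(sub["clr_max"].to_numpy(), q, low=False),
        "fst": _top_threshold(sub["fst"].to_numpy(), q, low=False),
        "tajimas_d": _top_threshold(sub["tajd"].to_numpy(), q, low=True),
        "q": q, "n_bins": len(df), "n_defined": int(defined.sum()),
    }
    bins: list[CandidateBin] = []
    for rec, ok in zip(df.itertuples(index=False), defined):
        if not ok:
            continue
        p_clr = rec.clr_max >= thresholds["clr"]
        p_fst = rec.fst >= thresholds["fst"]
        p_d = rec.tajd <= thresholds["tajimas_d"]
        passed = (p_clr and p_fst and p_d) if mode == "intersection" else (p_clr or p_fst or p_d)
        if passed:
            bins.append(CandidateBin(rec.chrom, rec.start, rec.end, rec.clr_max,
                                     rec.fst, rec.tajd, p_clr, p_fst, p_d, []))
    return bins, thresholds


def genes_in_bins(
    bins: Sequence[CandidateBin], annotation: GenomeAnnotation
) -> tuple[list[CandidateBin], list[str]]:
    """Attach genes overlapping each bin by >= 1 bp; return bins + deduplicated union."""
    union: set[str] = set()
    for b in bins:
        b.genes = annotation.genes_overlapping(b.chrom, b.start, b.end)
        union.update(b.genes)
    return list(bins), sorted(union)


def bins_to_frame(bins: Sequence[CandidateBin]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.chrom, b.start, b.end, b.clr_max, b.fst, b.tajimas_d,
          b.pass_clr, b.pass_fst, b.pass_tajd, ",".join(b.genes)) for b in bins],
        columns=["chrom", "start", "end", "clr_max", "fst", "tajimas_d",
                 "pass_clr", "pass_fst", "pass_tajd", "genes"],
    )


def write_scan_outputs(clr_track: pd.DataFrame, bins: Sequence[CandidateBin],
                       thresholds: dict, outdir) -> None:
    from pathlib import Path
    outdir = Path(outdir)
    clr_track.to_csv(outdir / "clr_track.tsv", sep="\t", index=False, float_format="%.6g")
    bins_to_frame(bins).to_csv(outdir / "candidate_bins.tsv", sep="\t", index=False,
                               float_format="%.6g")
    with open(outdir / "scan_thresholds.json", "w") as fh:
        json.dump(thresholds, fh, indent=2, sort_keys=True)
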