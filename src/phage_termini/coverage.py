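"""Per-strand coverage profiles, the tau statistic, and terminus peak calling.

The central quantity is ``tau = SPC / COV``: the number of reads *starting*
at a position divided by the number of fragments (paired data) or reads
(single-end data) *covering* it.  At a position that is not a DNA terminus,
read starts come only from random fragmentation, so the expected tau is 1/F
where F is the mean fragment size.  At a fixed terminus every packaged
molecule contributes a start, so tau rises to 1 (3' cohesive ends), 0.5
(5' cohesive ends or direct terminal repeats, where end-repair makes the
opposite terminal fragments cover the position too) or 1/(1+C) at the pac
site of a headful phage packaging concatemers of C genome copies.

Significance of a candidate terminus is assessed against a gamma null fitted
to the SPC values of a coverage-homogeneous genome segment; segmentation by
a regression tree makes the null robust to uneven coverage (collapsed
repeats, bad assemblies).  Candidate positions passing a Benjamini-Hochberg
(default) threshold are called, and candidates that also pass an adjusted
p < 1/G gate are merged within a small window to absorb imprecise terminase
cleavage, summing their read starts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.tree import DecisionTreeRegressor
from statsmodels.stats.multitest import multipletests

from .seqmap import Alignment, Fragment

logger = logging.getLogger(__name__)

STRANDS = ("forward", "reverse")


@dataclass
class StrandProfiles:
    """Per-position, per-strand read-start and coverage arrays of length G."""

    SPC_fwd: np.ndarray
    SPC_rev: np.ndarray
    COV_fwd: np.ndarray
    COV_rev: np.ndarray
    FCOV: np.ndarray  # fragment coverage; zeros for single-end input
    G: int

    def spc(self, strand: str) -> np.ndarray:
        return self.SPC_fwd if strand == "forward" else self.SPC_rev

    def cov(self, strand: str) -> np.ndarray:
        return self.COV_fwd if strand == "forward" else self.COV_rev


@dataclass
class TauProfile:
    tau_fwd: np.ndarray
    tau_rev: np.ndarray
    F: float
    R_fwd: float  # mean SPC over covered positions, forward strand
    R_rev: float
    background_tau: float  # 1/F
    paired: bool
    F_is_approximate: bool = False

    def tau(self, strand: str) -> np.ndarray:
        return self.tau_fwd if strand == "forward" else self.tau_rev

    def R(self, strand: str) -> float:
        return self.R_fwd if strand == "forward" else self.R_rev


@dataclass
class GenomeSegment:
    """A coverage-homogeneous interval ``[start, end)`` of the genome."""

    start: int
    end: int
    gamma_shape: float | None = None
    gamma_scale: float | None = None


@dataclass
class PeakCall:
    """A significant terminus candidate (possibly merged over a window)."""

    position: int  # 0-based; argmax SPC among members
    strand: str
    tau: float  # recomputed with SPC_merged
    SPC_merged: int
    pvalue: float
    adjusted_pvalue: float
    members: list[int] = field(default_factory=list)


@dataclass
class PeakResult:
    peaks_fwd: list[PeakCall]
    peaks_rev: list[PeakCall]
    pvalues: dict
    adjusted_pvalues: dict

    def peaks(self, strand: str) -> list[PeakCall]:
        return self.peaks_fwd if strand == "forward" else self.peaks_rev

    @property
    def all_peaks(self) -> list[PeakCall]:
        return self.peaks_fwd + self.peaks_rev


def _interval_coverage(starts, ends, G) -> np.ndarray:
    d = np.zeros(G + 1, dtype=np.int64)
    np.add.at(d, np.clip(starts, 0, G), 1)
    np.add.at(d, np.clip(ends, 0, G), -1)
    return np.cumsum(d[:G])


def build_profiles(
    alignments: list[Alignment], fragments: list[Fragment], G: int
) -> StrandProfiles:
    """Accumulate SPC/COV per strand and fragment coverage over ``[0, G)``.

    A forward read of length L starting at s covers ``[s, s+L)``; a reverse
    read (start = rightmost top-strand position) covers ``[s-L+1, s+1)``,
    clipped to the reference.  A fragment ``[left, right)`` covers every
    base between its two reads, ends included.
    """
    prof = StrandProfiles(
        SPC_fwd=np.zeros(G, dtype=np.int64),
        SPC_rev=np.zeros(G, dtype=np.int64),
        COV_fwd=np.zeros(G, dtype=np.int64),
        COV_rev=np.zeros(G, dtype=np.int64),
        FCOV=np.zeros(G, dtype=np.int64),
        G=G,
    )
    for strand in STRANDS:
        alns = [a for a in alignments if a.strand == strand]
        if not alns:
            continue
        starts = np.array([a.start for a in alns], dtype=np.int64)
        lens = np.array([a.read_length for a in alns], dtype=np.int64)
        spc = np.bincount(starts, minlength=G)[:G]
        if strand == "forward":
            prof.SPC_fwd += spc
            prof.COV_fwd += _interval_coverage(starts, starts + lens, G)
        else:
            prof.SPC_rev += spc
            prof.COV_rev += _interval_coverage(starts - lens + 1, starts + 1, G)
    if fragments:
        lefts = np.array([f.left for f in fragments], dtype=np.int64)
        rights = np.array([f.right for f in fragments], dtype=np.int64)
        prof.FCOV += _interval_coverage(lefts, rights, G)
    return prof


def compute_tau(
    profiles: StrandProfiles,
    paired: bool,
    F: float,
    F_is_approximate: bool = False,
) -> TauProfile:
    """tau = SPC / denominator, with fragment coverage as the denominator for
    paired data and strand read coverage for single-end data.

    Positions with a zero denominator get tau = 0 and are excluded from the
    background statistics R (mean SPC over covered positions per strand).
    """
    if profiles.COV_fwd.sum() + profiles.COV_rev.sum() == 0:
        raise ValueError("no mapped reads: cannot compute tau")
    if F <= 0:
        raise ValueError(f"mean fragment size must be positive, got {F}")

    taus = {}
    Rs = {}
    for strand in STRANDS:
        spc = profiles.spc(strand)
        denom = profiles.FCOV if paired else profiles.cov(strand)
        with np.errstate(divide="ignore", invalid="ignore"):
            tau = np.where(denom > 0, spc / np.maximum(denom, 1), 0.0)
        taus[strand] = np.clip(tau, 0.0, 1.0)
        covered = profiles.cov(strand) > 0
        Rs[strand] = float(spc[covered].mean()) if covered.any() else 0.0

    return TauProfile(
        tau_fwd=taus["forward"],
        tau_rev=taus["reverse"],
        F=F,
        R_fwd=Rs["forward"],
        R_rev=Rs["reverse"],
        background_tau=1.0 / F,
        paired=paired,
        F_is_approximate=F_is_approximate,
    )


def segment_by_coverage(
    profiles: StrandProfiles,
    min_segment: int = 500,
    max_depth: int = 4,
) -> list[GenomeSegment]:
    """Partition ``[0, G)`` into coverage-homogeneous segments.

    Fits a piecewise-constant regression of total coverage against position
    (binary recursive squared-error splits) and returns the leaves.  Flat
    coverage yields a single segment; a step (e.g. a collapsed duplication)
    is split near the breakpoint, so the gamma null is fitted separately on
    each side and the step does not masquerade as a terminus.
    """
    G = profiles.G
    y = profiles.FCOV if profiles.FCOV.sum() > 0 else profiles.COV_fwd + profiles.COV_rev
    if G < 2 * min_segment:
        return [GenomeSegment(0, G)]
    X = np.arange(G, dtype=np.float64).reshape(-1, 1)
    tree = DecisionTreeRegressor(
        max_depth=max_depth, min_samples_leaf=min_segment, random_state=0
    )
    tree.fit(X, y.astype(np.float64))
    pred = tree.predict(X)
    boundaries = np.flatnonzero(np.diff(pred) != 0) + 1
    edges = [0, *boundaries.tolist(), G]
    return [GenomeSegment(a, b) for a, b in zip(edges[:-1], edges[1:])]


def fit_gamma_null(values, trim: float = 1e-3) -> tuple[float, float]:
    """Method-of-moments gamma fit (shape, scale) on SPC values.

    The top ``trim`` fraction of values is excluded so that genuine terminus
    peaks do not inflate the null.  A degenerate (zero-variance) sample falls
    back to a Poisson-like parameterisation shape = mean, scale = 1.
    """
    vals = np.asarray(values, dtype=np.float64)
    if vals.size == 0:
        raise ValueError("cannot fit a gamma null to an empty sample")
    if trim > 0 and vals.size > 10:
        cutoff = np.quantile(vals, 1.0 - trim)
        vals = vals[vals <= cutoff]
    mean = float(vals.mean())
    var = float(vals.var())
    if var <= 1e-12 or mean <= 0:
        return max(mean, 1e-6), 1.0
    return mean * mean / var, var / mean


_MIN_NULL_POSITIONS = 30


def _segment_null_params(
    profiles: StrandProfiles, segments: list[GenomeSegment], strand: str
) -> list[tuple[float, float]]:
    """Gamma null per segment; small segments inherit the whole-genome fit."""
    spc = profiles.spc(strand)
    covered = profiles.cov(strand) > 0
    if covered.sum() >= 1:
        global_fit = fit_gamma_null(spc[covered])
    else:
        global_fit = (1e-6, 1.0)
    params = []
    for seg in segments:
        mask = covered[seg.start : seg.end]
        if mask.sum() >= _MIN_NULL_POSITIONS:
            fit = fit_gamma_null(spc[seg.start : seg.end][mask])
        else:
            fit = global_fit
        seg.gamma_shape, seg.gamma_scale = fit
        params.append(fit)
    return params


def _cluster(positions: np.ndarray, window: int) -> list[np.ndarray]:
    """Group sorted positions whose consecutive gaps are <= window."""
    if positions.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > window) + 1
    return np.split(positions, breaks)


def call_peaks(
    tau_profile: TauProfile,
    profiles: StrandProfiles,
    segments: list[GenomeSegment],
    alpha: float = 0.01,
    merge_window: int = 20,
    adjust: str = "bh",
) -> PeakResult:
    """Call significant terminus peaks per strand.

    Per covered position, p = upper-tail gamma probability of the observed
    SPC under its segment's null; p-values are adjusted across covered
    positions of the strand (Benjamini-Hochberg by default).  Positions with
    adjusted p < alpha are candidates; candidates whose adjusted p is also
    below 1/G are merged when within ``merge_window`` bases of each other,
    summing SPC, reporting the position of the highest member and
    recomputing tau with the summed SPC.
    """
    if adjust not in ("bh", "bonferroni"):
        raise ValueError(f"unknown adjustment method {adjust!r}")
    method = "fdr_bh" if adjust == "bh" else "bonferroni"
    G = profiles.G
    out = {"forward": [], "reverse": []}
    pvalues = {}
    adjusted = {}

    for strand in STRANDS:
        spc = profiles.spc(strand)
        covered = profiles.cov(strand) > 0
        pvals = np.ones(G)
        params = _segment_null_params(profiles, segments, strand)
        for seg, (shape, scale) in zip(segments, params):
            sl = slice(seg.start, seg.end)
            mask = covered[sl]
            if not mask.any():
                continue
            seg_p = np.ones(seg.end - seg.start)
            seg_p[mask] = stats.gamma.sf(spc[sl][mask], a=shape, scale=scale)
            pvals[sl] = np.where(mask, seg_p, 1.0)
        adj = np.ones(G)
        idx = np.flatnonzero(covered)
        if idx.size:
            adj[idx] = multipletests(pvals[idx], method=method)[1]
        pvalues[strand] = pvals
        adjusted[strand] = adj

        cand = np.flatnonzero(covered & (adj < alpha))
        strong = cand[adj[cand] < 1.0 / G]
        weak = cand[adj[cand] >= 1.0 / G]
        denom = profiles.FCOV if tau_profile.paired else profiles.cov(strand)

        def _mk(members: np.ndarray) -> PeakCall:
            top = members[np.argmax(spc[members])]
            spc_merged = int(spc[members].sum())
            tau = min(1.0, spc_merged / denom[top]) if denom[top] > 0 else 0.0
            return PeakCall(
                position=int(top),
                strand=strand,
                tau=float(tau),
                SPC_merged=spc_merged,
                pvalue=float(pvals[members].min()),
                adjusted_pvalue=float(adj[members].min()),
                members=[int(m) for m in members],
            )

        peaks = [_mk(cl) for cl in _cluster(strong, merge_window)]
        peaks += [_mk(np.array([w])) for w in weak]
        peaks.sort(key=lambda p: p.position)
        out[strand] = peaks

    return PeakResult(
        peaks_fwd=out["forward"],
        peaks_rev=out["reverse"],
        pvalues=pvalues,
        adjusted_pvalues=adjusted,
    )


def peak_size_diagnostic(
    peak: PeakCall, R: float, F: float
) -> tuple[float, bool]:
    """Signal size T/R (reads at the terminus over background read starts).

    For a fixed terminus T/R is expected to equal F; a ratio below F/2 flags
    inefficient end capture (e.g. poor adapter ligation at cohesive ends) or
    the presence of alternative termini.
    """
    if R <= 0:
        raise ValueError("background start rate R must be positive")
    ratio = peak.SPC_merged / R
    return ratio, bool(ratio < 0.5 * F)
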